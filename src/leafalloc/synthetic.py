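"""Synthetic observation sets with the statistical structure the
calibration assumes.

Observations are generated by running the forward allocation model along a
leaf-nitrogen grid under known ``(D_ns, f_s)`` and multiplying the
capacities by lognormal noise, ``exp(N(0, noise_sd^2))``, so values stay
positive and the relative error is homogeneous on the log scale. Every
draw is reproducible from the mandatory seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allocation import LeafNitrogenModel
from .calibration import ObservationSet
from .kinetics import COLLATZ, KineticConstants
from .photosynthesis import Environment
from .traits import DEFAULT_NUE, NitrogenUseEfficiencies, PlantTraits

__all__ = ["GeneratorConfig", "generate_observation_set"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for the synthetic observation generator.

    ``true_d_ns``/``true_f_s`` are the generating parameters; leaf N is
    swept linearly from ``leaf_n_min`` to ``leaf_n_max`` with ``n_obs``
    points; ``noise_sd`` is the relative (log-scale) Gaussian sd applied to
    Vcmax25 and Jmax25. The seed is mandatory.
    """

    true_d_ns: float
    true_f_s: float
    seed: int
    traits: PlantTraits
    env: Environment
    leaf_n_min: float = 0.01
    leaf_n_max: float = 0.03
    n_obs: int = 12
    noise_sd: float = 0.05
    nue: NitrogenUseEfficiencies = field(default_factory=lambda: DEFAULT_NUE)
    kinetics: KineticConstants = field(default_factory=lambda: COLLATZ)

    def __post_init__(self) -> None:
        errors = []
        if self.noise_sd < 0:
            errors.append(f"noise_sd must be >= 0; got {self.noise_sd}")
        if self.n_obs < 3:
            errors.append(f"n_obs must be >= 3; got {self.n_obs}")
        if not 0 < self.leaf_n_min <= self.leaf_n_max:
            errors.append(
                f"need 0 < leaf_n_min <= leaf_n_max; got "
                f"({self.leaf_n_min}, {self.leaf_n_max})"
            )
        if self.seed is None:
            errors.append("seed is mandatory")
        if errors:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(errors))


def generate_observation_set(config: GeneratorConfig) -> ObservationSet:
    """Produce an :class:`ObservationSet` from the forward model plus noise.

    Grid points whose solve is degenerate (no feasible photosynthesis) are
    dropped with a warning reporting the remaining count.
    """
    rng = np.random.default_rng(config.seed)
    base = replace(config.traits, d_ns=config.true_d_ns, f_s=config.true_f_s)
    leaf_n_grid = np.linspace(config.leaf_n_min, config.leaf_n_max, config.n_obs)

    records = []
    dropped = 0
    for leaf_n in leaf_n_grid:
        sol = LeafNitrogenModel(
            base.with_leaf_n(float(leaf_n)),
            config.env,
            nue=config.nue,
            kinetics=config.kinetics,
        ).solve()
        if sol.degenerate:
            dropped += 1
            continue
        noise_v = math.exp(rng.normal(0.0, config.noise_sd))
        noise_j = math.exp(rng.normal(0.0, config.noise_sd))
        records.append(
            {
                "leaf_n": float(leaf_n),
                "vcmax25": sol.vcmax25 * noise_v,
                "jmax25": sol.jmax25 * noise_j,
                "measurement_t": 25.0,
            }
        )
    if dropped:
        warnings.warn(
            f"{dropped} grid point(s) had no feasible photosynthesis and were "
            f"dropped; {len(records)} observation(s) remain",
            RuntimeWarning,
            stacklevel=2,
        )
    table = pd.DataFrame.from_records(records)
    return ObservationSet(
        table=table,
        traits=config.traits,
        env=config.env,
        nue=config.nue,
        kinetics=config.kinetics,
    )
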