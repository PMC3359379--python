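"""Metropolis-Hastings calibration of the storage strategy parameters.

The two unknowns of the allocation model — the nitrogen storage duration
``D_ns`` and the leaf share of storage nitrogen ``f_s`` — are estimated
from observed Vcmax25 across leaf nitrogen levels under the control
environment. Only Vcmax is fitted; Jmax observations, when present, are
held out for evaluation.

Sampler: single-chain Gaussian random-walk Metropolis with uniform priors
(``f_s`` in [0, 1], ``D_ns`` in [0, 365] days). Proposal scales adapt
toward a target acceptance rate during burn-in only and are frozen
afterwards, so the post-burn-in chain is a valid MH chain. Identical seed
and configuration reproduce the sample sequence bit-for-bit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allocation import LeafNitrogenModel
from .kinetics import COLLATZ, KineticConstants
from .photosynthesis import Environment
from .traits import DEFAULT_NUE, NitrogenUseEfficiencies, PlantTraits

__all__ = [
    "ObservationSet",
    "ChainConfig",
    "FitResult",
    "log_likelihood",
    "metropolis_sample",
    "metropolis_fit",
    "VcmaxCalibration",
    "gelman_rubin",
]

logger = logging.getLogger(__name__)

D_NS_BOUNDS = (0.0, 365.0)
F_S_BOUNDS = (0.0, 1.0)


@dataclass(frozen=True)
class ObservationSet:
    """Observed (leaf N, Vcmax25) records with their shared context.

    ``table`` columns: ``leaf_n`` (g N g-1 leaf), ``vcmax25`` (umol CO2
    m-2 s-1, standardized to the stated kinetic convention at 25 C), and
    optionally ``jmax25`` and ``measurement_t`` (C). ``traits`` is the
    trait template whose leaf N is swept; ``env`` the control environment.
    """

    table: pd.DataFrame
    traits: PlantTraits | None = None
    env: Environment | None = None
    nue: NitrogenUseEfficiencies = field(default_factory=lambda: DEFAULT_NUE)
    kinetics: KineticConstants = field(default_factory=lambda: COLLATZ)

    def __post_init__(self) -> None:
        missing = {"leaf_n", "vcmax25"} - set(self.table.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        if (self.table["leaf_n"] <= 0).any():
            raise ValueError("leaf_n must be strictly positive for every record")

    def __len__(self) -> int:
        return len(self.table)

    def require_context(self) -> tuple[PlantTraits, Environment]:
        if self.traits is None or self.env is None:
            raise ValueError(
                "ObservationSet has no trait/environment context; supply "
                "traits and env before fitting"
            )
        return self.traits, self.env


def predict_vcmax25(
    params: tuple[float, float],
    obs: ObservationSet,
) -> np.ndarray:
    """Model Vcmax25 at each observed leaf N for ``params = (d_ns, f_s)``."""
    d_ns, f_s = params
    traits, env = obs.require_context()
    base = replace(traits, d_ns=d_ns, f_s=f_s)
    out = np.empty(len(obs))
    for i, leaf_n in enumerate(obs.table["leaf_n"].to_numpy()):
        sol = LeafNitrogenModel(
            base.with_leaf_n(float(leaf_n)), env, nue=obs.nue, kinetics=obs.kinetics
        ).solve()
        out[i] = sol.vcmax25
    return out


def log_likelihood(
    params: tuple[float, float],
    obs: ObservationSet,
    sigma: float | None = None,
) -> float:
    """Gaussian log likelihood of observed Vcmax25 given ``(d_ns, f_s)``.

    With ``sigma`` given, the usual fixed-variance Gaussian density (one
    additive term per record). With ``sigma=None`` the residual variance is
    profiled at its conditional MLE, ``sigma^2 = mean(residual^2)``.
    Out-of-support parameters and non-finite predictions return ``-inf``;
    no exception escapes.
    """
    d_ns, f_s = params
    if not (D_NS_BOUNDS[0] <= d_ns <= D_NS_BOUNDS[1]):
        return -math.inf
    if not (F_S_BOUNDS[0] <= f_s <= F_S_BOUNDS[1]):
        return -math.inf
    try:
        pred = predict_vcmax25(params, obs)
    except Exception:  # solver failures are treated as zero support
        return -math.inf
    if not np.all(np.isfinite(pred)):
        return -math.inf
    resid = obs.table["vcmax25"].to_numpy() - pred
    n = resid.size
    if sigma is not None:
        return float(
            -0.5 * n * math.log(2.0 * math.pi * sigma**2)
            - 0.5 * np.sum(resid**2) / sigma**2
        )
    s2 = max(float(np.mean(resid**2)), 1e-12)
    return float(-0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0))


def metropolis_sample(
    log_target,
    x0: np.ndarray,
    scales: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    adapt_until: int = 0,
    target_accept: float = 0.3,
    adapt_window: int = 50,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Gaussian random-walk Metropolis on an arbitrary log density.

    Proposal scales are multiplicatively adapted every ``adapt_window``
    steps while ``i < adapt_until`` and frozen afterwards. Returns
    (samples, log densities, overall acceptance rate, final scales).
    """
    x = np.array(x0, dtype=float)
    scales = np.array(scales, dtype=float)
    dim = x.size
    lp = float(log_target(x))
    samples = np.empty((n_iter, dim))
    logps = np.empty(n_iter)
    accepted = 0
    window_accepted = 0
    for i in range(n_iter):
        prop = x + rng.normal(0.0, scales, size=dim)
        lp_prop = float(log_target(prop))
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
            window_accepted += 1
        samples[i] = x
        logps[i] = lp
        if i < adapt_until and (i + 1) % adapt_window == 0:
            rate = window_accepted / adapt_window
            scales *= math.exp(rate - target_accept)
            window_accepted = 0
    return samples, logps, accepted / n_iter, scales


@dataclass(frozen=True)
class ChainConfig:
    """Metropolis-Hastings chain settings (seed is mandatory)."""

    seed: int
    n_iter: int = 50_000
    burn_in_frac: float = 0.2
    initial_scales: tuple[float, float] = (10.0, 0.05)  # (d_ns, f_s)
    start: tuple[float, float] | None = None
    target_accept: float = 0.3
    sigma: float | None = None  # None -> profiled residual variance


@dataclass(frozen=True)
class FitResult:
    """Posterior summary of a Metropolis-Hastings calibration.

    ``samples`` holds the post-burn-in chain (columns ``d_ns``, ``f_s``,
    ``log_posterior``); means and sds are reported the way the calibration
    is usually tabulated: ``mean (sd)`` per parameter.
    """

    samples: pd.DataFrame
    posterior_mean: dict[str, float]
    posterior_sd: dict[str, float]
    acceptance_rate: float
    config: ChainConfig
    final_scales: tuple[float, float]

    def credible_interval(self, param: str, level: float = 0.9) -> tuple[float, float]:
        """Central credible interval for ``param`` from the chain quantiles."""
        tail = (1.0 - level) / 2.0
        values = self.samples[param]
        return float(values.quantile(tail)), float(values.quantile(1.0 - tail))

    def summary(self) -> str:
        lines = [
            "Metropolis-Hastings fit of the nitrogen allocation model",
            "--------------------------------------------------------",
            "parameter                              mean (sd)",
            (
                "Proportion of storage N to leaf (f_s)  "
                f"{self.posterior_mean['f_s']:.3g} ({self.posterior_sd['f_s']:.3g})"
            ),
            (
                "Nitrogen storage duration (D_ns, d)    "
                f"{self.posterior_mean['d_ns']:.3g} ({self.posterior_sd['d_ns']:.3g})"
            ),
            f"acceptance rate: {self.acceptance_rate:.3f}   "
            f"iterations: {self.config.n_iter}   seed: {self.config.seed}",
        ]
        return "\n".join(lines)


class VcmaxCalibration:
    """Calibrate ``(D_ns, f_s)`` against observed Vcmax25 vs leaf N.

    Statsmodels-style: construct from an :class:`ObservationSet`, call
    :meth:`fit` with a seed to obtain a :class:`FitResult`.
    """

    def __init__(self, obs: ObservationSet) -> None:
        obs.require_context()
        if len(obs) < 3:
            raise ValueError(
                f"at least 3 observations are required for an identifiable "
                f"fit; got {len(obs)}"
            )
        self.obs = obs

    def log_posterior(self, params: np.ndarray, sigma: float | None = None) -> float:
        # Uniform priors over the support: posterior = likelihood there.
        return log_likelihood((params[0], params[1]), self.obs, sigma=sigma)

    def fit(self, config: ChainConfig | None = None, **kwargs) -> FitResult:
        """Run the chain. ``kwargs`` override :class:`ChainConfig` fields."""
        if config is None:
            if "seed" not in kwargs:
                raise ValueError("an explicit seed is required")
            config = ChainConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        rng = np.random.default_rng(config.seed)
        start = (
            np.array(config.start, dtype=float)
            if config.start is not None
            else np.array(
                [0.5 * sum(D_NS_BOUNDS), 0.5 * sum(F_S_BOUNDS)], dtype=float
            )
        )
        burn = int(config.burn_in_frac * config.n_iter)
        samples, logps, acc_rate, final_scales = metropolis_sample(
            lambda x: self.log_posterior(x, sigma=config.sigma),
            start,
            np.array(config.initial_scales, dtype=float),
            config.n_iter,
            rng,
            adapt_until=burn,
            target_accept=config.target_accept,
        )
        if not 0.05 <= acc_rate <= 0.7:
            warnings.warn(
                f"MH acceptance rate {acc_rate:.3f} outside [0.05, 0.7] after "
                "adaptation; inspect the chain",
                RuntimeWarning,
                stacklevel=2,
            )
        kept = pd.DataFrame(
            {
                "d_ns": samples[burn:, 0],
                "f_s": samples[burn:, 1],
                "log_posterior": logps[burn:],
            }
        )
        return FitResult(
            samples=kept,
            posterior_mean={
                "d_ns": float(kept["d_ns"].mean()),
                "f_s": float(kept["f_s"].mean()),
            },
            posterior_sd={
                "d_ns": float(kept["d_ns"].std(ddof=1)),
                "f_s": float(kept["f_s"].std(ddof=1)),
            },
            acceptance_rate=acc_rate,
            config=config,
            final_scales=(float(final_scales[0]), float(final_scales[1])),
        )


def metropolis_fit(obs: ObservationSet, config: ChainConfig) -> FitResult:
    """Functional wrapper around :class:`VcmaxCalibration`."""
    return VcmaxCalibration(obs).fit(config)


def gelman_rubin(results: list[FitResult], param: str) -> float:
    """Potential scale reduction factor across independently seeded chains."""
    if len(results) < 2:
        raise ValueError("need at least two chains")
    chains = [r.samples[param].to_numpy() for r in results]
    n = min(len(c) for c in chains)
    chains = np.array([c[:n] for c in chains])
    m = chains.shape[0]
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w)) if w > 0 else float("inf")
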