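"""Factorial sensitivity experiments and built-in test-case scenarios.

The sensitivity design perturbs a shared control environment (growing
temperature 15 C, PAR 800 umol photon m-2 s-1, CO2 370 ppm) with three
factors — T: +5 C, CO2: +200 ppm, RAD: x0.5 — singly and in combination,
for generic deciduous-tree, evergreen-tree and herbaceous trait sets, and
reports the acclimation of Vcmax25 and the reallocation of nitrogen among
the five pools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .allocation import ConvergenceError, LeafNitrogenModel, POOLS
from .kinetics import COLLATZ, KineticConstants
from .photosynthesis import Environment
from .traits import DEFAULT_NUE, NitrogenUseEfficiencies, PlantTraits

__all__ = [
    "FACTORS",
    "Scenario",
    "apply_factors",
    "run_factorial",
    "lma_from_relative_light",
    "build_test_case",
    "sensitivity_control_env",
    "table3_traits",
    "TEST_CASE_FITTED_PARAMS",
]

#: Factorial treatment factors and their deltas relative to control.
FACTORS = ("T", "CO2", "RAD")

_T_DELTA = 5.0  # C added to day and night temperature
_CO2_DELTA = 200.0  # ppm added
_RAD_FACTOR = 0.5  # PAR multiplier


def apply_factors(env: Environment, factors: tuple[str, ...]) -> Environment:
    """Return the treatment environment for a set of factor toggles."""
    unknown = set(factors) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factors {sorted(unknown)}; allowed: {FACTORS}")
    changes: dict[str, float] = {}
    if "T" in factors:
        changes["day_temp"] = env.day_temp + _T_DELTA
        changes["night_temp"] = env.night_temp + _T_DELTA
    if "CO2" in factors:
        changes["co2_ppm"] = env.co2_ppm + _CO2_DELTA
    if "RAD" in factors:
        changes["par"] = env.par * _RAD_FACTOR
    return replace(env, **changes)


@dataclass(frozen=True)
class Scenario:
    """A labelled trait set with control environment and treatment toggles."""

    label: str
    traits: PlantTraits
    control_env: Environment
    deltas: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.deltas) - set(FACTORS)
        if unknown:
            raise ValueError(
                f"scenario deltas {sorted(unknown)} not among declared factors {FACTORS}"
            )

    @property
    def treatment_env(self) -> Environment:
        return apply_factors(self.control_env, self.deltas)


def sensitivity_control_env() -> Environment:
    """Control environment of the sensitivity analysis."""
    return Environment(
        par=800.0, co2_ppm=370.0, day_temp=15.0, night_temp=15.0,
        rh=0.8, day_hours=14.0,
    )


def table3_traits() -> dict[str, PlantTraits]:
    """Generic deciduous, evergreen and herbaceous trait sets."""
    return {
        "deciduous": PlantTraits(
            lma=120.0, leaf_n=0.02, f_s=0.86, d_ns=85.0, f_cleaf=0.2
        ),
        "evergreen": PlantTraits(
            lma=85.0, leaf_n=0.015, f_s=0.5, d_ns=50.0, f_cleaf=0.2
        ),
        "herbaceous": PlantTraits(
            lma=60.0, leaf_n=0.03, f_s=0.5, d_ns=4.0, f_cleaf=0.6
        ),
    }


def _combo_label(combo: tuple[str, ...]) -> str:
    return "+".join(combo) if combo else "control"


def run_factorial(
    pfts: dict[str, PlantTraits],
    control_env: Environment,
    factors: tuple[str, ...] = FACTORS,
    nue: NitrogenUseEfficiencies = DEFAULT_NUE,
    kinetics: KineticConstants = COLLATZ,
) -> pd.DataFrame:
    """Run all factor combinations for every plant functional type.

    Each treatment cell is solved independently from the shared control (no
    path dependence). Returns one row per (PFT, treatment) in a fixed
    order, with Vcmax25 under control and treatment, the percent change,
    and the change of every allocation fraction in percentage points. A
    non-converged cell is recorded as missing and the run continues.
    """
    combos: list[tuple[str, ...]] = []
    for mask in range(1, 2 ** len(factors)):
        combos.append(tuple(f for i, f in enumerate(factors) if mask >> i & 1))
    combos.sort(key=lambda c: (len(c), [factors.index(f) for f in c]))

    rows = []
    for pft in sorted(pfts):
        traits = pfts[pft]
        control = LeafNitrogenModel(
            traits, control_env, nue=nue, kinetics=kinetics
        ).solve()
        if control.degenerate:
            raise ValueError(
                f"control environment does not support photosynthesis for "
                f"PFT {pft!r}: {control.message}"
            )
        for combo in combos:
            row: dict[str, object] = {"pft": pft, "treatment": _combo_label(combo)}
            try:
                treat = LeafNitrogenModel(
                    traits, apply_factors(control_env, combo),
                    nue=nue, kinetics=kinetics,
                ).solve()
            except ConvergenceError as exc:
                warnings.warn(
                    f"treatment {_combo_label(combo)} for {pft} did not "
                    f"converge: {exc}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                treat = None
            row["vcmax25_control"] = control.vcmax25
            if treat is None or treat.degenerate:
                row["vcmax25_treatment"] = float("nan")
                row["pct_change_vcmax25"] = float("nan")
                for pool in POOLS:
                    row[f"dfrac_{pool}_pp"] = float("nan")
                row["note"] = (
                    "degenerate" if treat is not None else "non-converged"
                )
            else:
                row["vcmax25_treatment"] = treat.vcmax25
                row["pct_change_vcmax25"] = (
                    100.0 * (treat.vcmax25 - control.vcmax25) / control.vcmax25
                )
                cf, tf = control.fractions, treat.fractions
                for pool in POOLS:
                    row[f"dfrac_{pool}_pp"] = 100.0 * (tf[pool] - cf[pool])
                row["note"] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def lma_from_relative_light(x: float) -> float:
    """LMA (g m-2) from relative light in the canopy: ``73 + 65.5 x``."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"relative light must lie in [0, 1]; got {x}")
    return 73.0 + 65.5 * x


#: (d_ns, f_s) estimated by calibration for the three built-in test cases.
TEST_CASE_FITTED_PARAMS = {
    1: {"d_ns": 85.2, "f_s": 0.86},
    2: {"d_ns": 50.4, "f_s": 0.54},
    3: {"d_ns": 3.98, "f_s": 0.52},
}

_TEST_CASE_ENVS = {
    (1, "control"): dict(par=1010.0, co2_ppm=370.0, day_temp=28.0,
                         night_temp=23.0, rh=0.8, day_hours=14.0),
    (1, "treatment"): dict(par=1010.0, co2_ppm=570.0, day_temp=28.0,
                           night_temp=23.0, rh=0.8, day_hours=14.0),
    (2, "control"): dict(par=621.0, co2_ppm=370.0, day_temp=17.0,
                         night_temp=13.0, rh=0.6, day_hours=17.0),
    (3, "control"): dict(par=450.0, co2_ppm=370.0, day_temp=30.0,
                         night_temp=30.0, rh=0.8, day_hours=14.0),
    (3, "treatment"): dict(par=450.0, co2_ppm=370.0, day_temp=15.0,
                           night_temp=15.0, rh=0.8, day_hours=14.0),
}

_TEST_CASE_TRAITS = {
    1: dict(lma=85.0, leaf_n=0.014, f_cleaf=0.2),
    2: dict(lma=138.0, leaf_n=0.0215, f_cleaf=0.2),
    3: dict(lma=55.0, leaf_n=0.03, f_cleaf=0.6),
}


def build_test_case(
    case_id: int, arm: str = "control", relative_light: float | None = None
) -> Scenario:
    """Built-in scenario for one of the three evaluation test cases.

    Case 1: loblolly pine under FACE CO2 enrichment (370 vs 570 ppm).
    Case 2: poplar canopy light gradient; the treatment arm needs
    ``relative_light`` x in (0, 1]: PAR becomes ``621 x`` and LMA follows
    the canopy regression ``73 + 65.5 x``.
    Case 3: plantain grown at 30 C (control) vs 15 C (treatment; LMA 66).
    """
    if case_id not in (1, 2, 3):
        raise ValueError(f"unknown test case {case_id!r}; expected 1, 2 or 3")
    if arm not in ("control", "treatment"):
        raise ValueError(f"arm must be 'control' or 'treatment'; got {arm!r}")

    traits_kw = dict(_TEST_CASE_TRAITS[case_id])
    traits_kw.update(TEST_CASE_FITTED_PARAMS[case_id])
    if case_id == 2 and arm == "treatment":
        if relative_light is None:
            raise ValueError(
                "test case 2 treatment requires relative_light in (0, 1]"
            )
        env_kw = dict(_TEST_CASE_ENVS[(2, "control")])
        env_kw["par"] = env_kw["par"] * relative_light
        traits_kw["lma"] = lma_from_relative_light(relative_light)
    else:
        env_kw = dict(_TEST_CASE_ENVS[(case_id, arm)])
        if case_id == 3 and arm == "treatment":
            traits_kw["lma"] = 66.0
    return Scenario(
        label=f"test_case_{case_id}_{arm}",
        traits=PlantTraits(**traits_kw),
        control_env=Environment(**env_kw),
    )
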