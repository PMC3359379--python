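"""Farquhar-type photosynthesis rates, daily carbon gain, and capacity
standardisation to a common kinetic convention.

Rate conventions
----------------
``rubisco_limited_rate`` returns the gross carboxylation rate
``Wc = Vcmax(T) * Ci / (Ci + Kc(1 + O/Ko))``. ``electron_limited_rate``
returns ``Wj = J (Ci - gamma*) / (4 Ci + 8 gamma*)``, which is already net
of photorespiration. When the two pathways are compared or co-limited the
Rubisco pathway is therefore also expressed net of photorespiration,
``Ac = Vcmax(T) (Ci - gamma*) / (Ci + Km)``, so that the rates are
commensurate. Realised electron transport is the strict minimum of the
light-capture flux and Jmax(T); an optional hyperbolic smoothing is exposed
but off by default because the allocation solver enforces co-limitation
upstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from . import constants as const
from .kinetics import COLLATZ, KineticConstants

__all__ = [
    "Environment",
    "PhotoCapacity",
    "RespirationModel",
    "rubisco_limited_rate",
    "rubisco_limited_net_rate",
    "electron_limited_rate",
    "realized_electron_transport",
    "daily_net_assimilation",
    "standardize_capacity",
]


@dataclass(frozen=True)
class Environment:
    """Growth environment of a single leaf layer.

    Parameters
    ----------
    par : float
        Daytime mean photosynthetically active radiation (umol photon m-2 s-1).
    co2_ppm : float
        Ambient CO2 mixing ratio (ppm).
    day_temp, night_temp : float
        Day and night air (= leaf) temperatures (C).
    rh : float
        Relative humidity, fraction in (0, 1]. Retained as configuration
        metadata; the default intercellular-CO2 closure does not use it.
    day_hours : float
        Photoperiod (h), 0 < day_hours < 24.
    ci_ratio : float
        Intercellular-to-ambient CO2 ratio (big-leaf constant closure).
    """

    par: float
    co2_ppm: float
    day_temp: float
    night_temp: float
    rh: float = 0.8
    day_hours: float = 14.0
    ci_ratio: float = 0.7

    def __post_init__(self) -> None:
        errors = []
        if not (math.isfinite(self.par) and self.par >= 0):
            errors.append(f"par must be >= 0; got {self.par}")
        if not (math.isfinite(self.co2_ppm) and self.co2_ppm > 0):
            errors.append(f"co2_ppm must be > 0; got {self.co2_ppm}")
        if not 0.0 < self.rh <= 1.0:
            errors.append(f"rh must lie in (0, 1]; got {self.rh}")
        if not 0.0 < self.day_hours < 24.0:
            errors.append(f"day_hours must lie in (0, 24); got {self.day_hours}")
        if not 0.0 < self.ci_ratio < 1.0:
            errors.append(f"ci_ratio must lie in (0, 1); got {self.ci_ratio}")
        for name in ("day_temp", "night_temp"):
            if not math.isfinite(getattr(self, name)):
                errors.append(f"{name} must be finite")
        if errors:
            raise ValueError("invalid Environment: " + "; ".join(errors))

    @property
    def ca_pa(self) -> float:
        """Ambient CO2 partial pressure (Pa) at standard pressure."""
        return const.ppm_to_pa(self.co2_ppm)

    @property
    def ci_pa(self) -> float:
        """Intercellular CO2 partial pressure (Pa), ``ci_ratio * Ca``."""
        return self.ci_ratio * self.ca_pa

    @property
    def night_hours(self) -> float:
        return const.HOURS_PER_DAY - self.day_hours


@dataclass(frozen=True)
class PhotoCapacity:
    """Photosynthetic capacities at 25 C under a stated kinetic convention.

    ``kinetics`` may be ``None`` for reported literature values whose
    convention is unknown; operations that need it either fall back to the
    Collatz convention (rate evaluation) or refuse to proceed
    (standardisation, which must never silently assume a convention).
    """

    vcmax25: float
    jmax25: float
    kinetics: KineticConstants | None = field(default=None)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.vcmax25) and self.vcmax25 >= 0):
            raise ValueError(f"vcmax25 must be >= 0; got {self.vcmax25}")
        if not (math.isfinite(self.jmax25) and self.jmax25 >= 0):
            raise ValueError(f"jmax25 must be >= 0; got {self.jmax25}")

    def effective_kinetics(self) -> KineticConstants:
        return self.kinetics if self.kinetics is not None else COLLATZ


@dataclass(frozen=True)
class RespirationModel:
    """Leaf-layer respiration parameters.

    ``maint_rate25``: maintenance respiration at 25 C (umol CO2 m-2 s-1);
    ``growth_frac``: growth respiration per unit net-of-maintenance carbon.
    """

    maint_rate25: float = 0.0
    growth_frac: float = 0.25
    kinetics: KineticConstants = field(default_factory=lambda: COLLATZ)

    def maint_rate(self, t_c: float) -> float:
        return self.maint_rate25 * self.kinetics.resp_response.factor(t_c)


def _check_ci(ci_pa: float) -> None:
    if not (math.isfinite(ci_pa) and ci_pa > 0):
        raise ValueError(f"intercellular CO2 must be > 0 Pa; got {ci_pa}")


def rubisco_limited_rate(
    capacity: PhotoCapacity, ci_pa: float, t_c: float
) -> float:
    """Gross Rubisco-limited carboxylation rate (umol CO2 m-2 s-1)."""
    _check_ci(ci_pa)
    kin = capacity.effective_kinetics()
    vcmax_t = capacity.vcmax25 * kin.vcmax_response.factor(t_c)
    return vcmax_t * ci_pa / (ci_pa + kin.km(t_c))


def rubisco_limited_net_rate(
    capacity: PhotoCapacity, ci_pa: float, t_c: float
) -> float:
    """Rubisco-limited rate net of photorespiration,
    ``Vcmax(T) (Ci - gamma*) / (Ci + Km)``."""
    _check_ci(ci_pa)
    kin = capacity.effective_kinetics()
    gs = kin.gamma_star(t_c)
    if ci_pa <= gs:
        return 0.0
    vcmax_t = capacity.vcmax25 * kin.vcmax_response.factor(t_c)
    return vcmax_t * (ci_pa - gs) / (ci_pa + kin.km(t_c))


def electron_limited_rate(
    capacity: PhotoCapacity, j: float, ci_pa: float, t_c: float
) -> float:
    """Electron-transport-limited carboxylation rate (umol CO2 m-2 s-1).

    ``Wj = J (Ci - gamma*) / (4 Ci + 8 gamma*)`` for a realised electron
    flux ``J``. Below the compensation point the rate is clamped to zero
    with a warning rather than raising, so upstream solvers stay finite.
    """
    _check_ci(ci_pa)
    if not (math.isfinite(j) and j >= 0):
        raise ValueError(f"electron flux J must be >= 0; got {j}")
    gs = capacity.effective_kinetics().gamma_star(t_c)
    if ci_pa <= gs:
        warnings.warn(
            f"Ci = {ci_pa:.3g} Pa is at or below the compensation point "
            f"gamma* = {gs:.3g} Pa; no net carboxylation",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return j * (ci_pa - gs) / (4.0 * ci_pa + 8.0 * gs)


def realized_electron_transport(
    light_flux: float,
    jmax_t: float,
    smoothing_theta: float | None = None,
) -> float:
    """Couple the chlorophyll-absorbed light flux with Jmax(T).

    Default is the strict minimum. If ``smoothing_theta`` in (0, 1) is
    given, the smaller root of the non-rectangular hyperbola
    ``theta J^2 - (I + Jmax) J + I Jmax = 0`` is used instead.
    """
    if smoothing_theta is None:
        return min(light_flux, jmax_t)
    theta = smoothing_theta
    if not 0.0 < theta < 1.0:
        raise ValueError(f"smoothing theta must lie in (0, 1); got {theta}")
    b = light_flux + jmax_t
    disc = b * b - 4.0 * theta * light_flux * jmax_t
    return (b - math.sqrt(disc)) / (2.0 * theta)


def daily_net_assimilation(
    capacity: PhotoCapacity,
    env: Environment,
    resp_model: RespirationModel,
    absorptance: float = 0.85,
    phi_e: float = 0.22,
) -> float:
    """Daily net carbon gain of the leaf layer (g C m-2 leaf day-1).

    Gross co-limited assimilation (net of photorespiration) at ``day_temp``
    over ``day_hours``, minus maintenance respiration at day and night
    temperatures, minus growth respiration on the remaining surplus.
    Growth respiration applies only when the surplus is positive.
    """
    if not 0.0 <= absorptance <= 1.0:
        raise ValueError(f"absorptance must lie in [0, 1]; got {absorptance}")
    kin = capacity.effective_kinetics()
    t_day = env.day_temp
    ci = env.ci_pa
    a_c = rubisco_limited_net_rate(capacity, ci, t_day)
    jmax_t = capacity.jmax25 * kin.jmax_response.factor(t_day)
    j = realized_electron_transport(phi_e * env.par * absorptance, jmax_t)
    gs = kin.gamma_star(t_day)
    a_j = j * max(ci - gs, 0.0) / (4.0 * ci + 8.0 * gs)
    gross_rate = min(a_c, a_j)

    gross_daily = const.umol_s_to_g_c_per_period(gross_rate, env.day_hours)
    maint_daily = const.umol_s_to_g_c_per_period(
        resp_model.maint_rate(t_day), env.day_hours
    ) + const.umol_s_to_g_c_per_period(
        resp_model.maint_rate(env.night_temp), env.night_hours
    )
    surplus = gross_daily - maint_daily
    return surplus - resp_model.growth_frac * max(surplus, 0.0)


def standardize_capacity(
    reported: PhotoCapacity,
    measurement_t: float,
    target: KineticConstants = COLLATZ,
    ci_pa: float = 25.0,
) -> PhotoCapacity:
    """Re-express reported Vcmax25/Jmax25 under a target kinetic convention.

    Returns the capacities that, under ``target`` constants and temperature
    functions, reproduce the same limiting rates at the measurement
    conditions (temperature ``measurement_t``, evaluation point ``ci_pa``)
    as the reported values do under their own stated convention.

    Raises
    ------
    ValueError
        If the reported capacity does not state its kinetic convention.
    """
    if reported.kinetics is None:
        raise ValueError(
            "reported PhotoCapacity must carry explicit KineticConstants; "
            "refusing to assume a convention for standardisation"
        )
    _check_ci(ci_pa)
    rep = reported.kinetics
    t = measurement_t

    # Equal gross Rubisco-limited rate at (ci_pa, t).
    vc_scale = (
        rep.vcmax_response.factor(t)
        * (ci_pa + target.km(t))
        / ((ci_pa + rep.km(t)) * target.vcmax_response.factor(t))
    )
    vcmax25_t = reported.vcmax25 * vc_scale

    # Equal electron-transport-limited rate at (ci_pa, t).
    gs_rep = rep.gamma_star(t)
    gs_tgt = target.gamma_star(t)
    if ci_pa <= gs_rep or ci_pa <= gs_tgt:
        raise ValueError(
            f"evaluation point Ci = {ci_pa} Pa must exceed gamma* under both "
            f"conventions (reported {gs_rep:.3g}, target {gs_tgt:.3g})"
        )
    j_scale = (
        rep.jmax_response.factor(t)
        * (ci_pa - gs_rep)
        / (4.0 * ci_pa + 8.0 * gs_rep)
        * (4.0 * ci_pa + 8.0 * gs_tgt)
        / ((ci_pa - gs_tgt) * target.jmax_response.factor(t))
    )
    jmax25_t = reported.jmax25 * j_scale

    return replace(reported, vcmax25=vcmax25_t, jmax25=jmax25_t, kinetics=target)
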