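"""Enzyme kinetic constants and temperature response functions.

The default :class:`KineticConstants` reproduces the Collatz et al. (1991)
C3 convention: Michaelis constants ``Kc25 = 30 Pa`` (Q10 2.1) and
``Ko25 = 30 kPa`` (Q10 1.2), and a CO2 compensation point derived from a
Rubisco specificity of 2600 at 25 C with Q10 0.57, i.e. ``gamma* = O/(2*tau)``
so that gamma* itself carries Q10 = 1/0.57. Vcmax-type rates use Q10 2.4 with
a logistic high-temperature inhibition; respiration-type rates use Q10 2.0.

All responses are normalised so that the multiplier is exactly 1 at the
25 C reference temperature, including any inhibition terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import O2_PARTIAL_PRESSURE_PA, T_REF_C

__all__ = [
    "TempResponse",
    "KineticConstants",
    "COLLATZ",
    "temp_scale",
    "temp_scale_to_ref",
]


@dataclass(frozen=True)
class TempResponse:
    """Q10-style temperature response with optional logistic inhibition.

    The multiplier is ``Q10**((T - 25)/10) * h(T)/h(25)`` where ``h`` is the
    product of the configured high- and low-temperature logistic inhibition
    terms. Normalising by ``h(25)`` keeps the response an exact identity at
    the reference temperature.

    Parameters
    ----------
    q10 : float
        Proportional rate change per 10 C. Must lie in (1, 4).
    high_inhibition : (slope, T_half) or None
        High-temperature inhibition ``1/(1 + exp(slope*(T - T_half)))``.
    low_inhibition : (slope, T_half) or None
        Low-temperature inhibition ``1/(1 + exp(slope*(T_half - T)))``.
    """

    q10: float
    high_inhibition: tuple[float, float] | None = None
    low_inhibition: tuple[float, float] | None = None
    t_ref: float = T_REF_C

    def __post_init__(self) -> None:
        if not 1.0 < self.q10 < 4.0:
            raise ValueError(f"Q10 must lie in (1, 4); got {self.q10}")

    def _inhibition(self, t_c: float) -> float:
        h = 1.0
        if self.high_inhibition is not None:
            slope, t_half = self.high_inhibition
            h /= 1.0 + math.exp(slope * (t_c - t_half))
        if self.low_inhibition is not None:
            slope, t_half = self.low_inhibition
            h /= 1.0 + math.exp(slope * (t_half - t_c))
        return h

    def factor(self, t_c: float) -> float:
        """Multiplier applied to a 25 C rate to obtain the rate at ``t_c``."""
        if not math.isfinite(t_c):
            raise ValueError(f"temperature must be finite; got {t_c}")
        base = self.q10 ** ((t_c - self.t_ref) / 10.0)
        return base * self._inhibition(t_c) / self._inhibition(self.t_ref)


def temp_scale(value25: float, t_c: float, coeffs: TempResponse) -> float:
    """Scale a rate defined at 25 C to leaf temperature ``t_c``."""
    if not math.isfinite(value25) or value25 < 0:
        raise ValueError(f"value25 must be finite and >= 0; got {value25}")
    return value25 * coeffs.factor(t_c)


def temp_scale_to_ref(value_t: float, t_c: float, coeffs: TempResponse) -> float:
    """Inverse of :func:`temp_scale`: bring a measured rate back to 25 C."""
    if not math.isfinite(value_t) or value_t < 0:
        raise ValueError(f"value_t must be finite and >= 0; got {value_t}")
    return value_t / coeffs.factor(t_c)


# Rubisco CO2/O2 specificity at 25 C in the Collatz convention; gamma* =
# O / (2 * tau). tau halves roughly every 12 C, i.e. gamma* has Q10 1/0.57.
_TAU25 = 2600.0
_TAU_Q10 = 0.57


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetics and temperature-response coefficients for one convention.

    Fields default to the Collatz et al. (1991) C3 values. ``gamma_star25``
    is derived from the specificity ``tau25 = 2600`` unless given explicitly.
    """

    kc25: float = 30.0  # Pa
    ko25: float = 30_000.0  # Pa
    gamma_star25: float = O2_PARTIAL_PRESSURE_PA / (2.0 * _TAU25)  # Pa
    o2: float = O2_PARTIAL_PRESSURE_PA  # Pa
    kc_response: TempResponse = field(default_factory=lambda: TempResponse(2.1))
    ko_response: TempResponse = field(default_factory=lambda: TempResponse(1.2))
    gamma_star_response: TempResponse = field(
        default_factory=lambda: TempResponse(1.0 / _TAU_Q10)
    )
    vcmax_response: TempResponse = field(
        default_factory=lambda: TempResponse(2.4, high_inhibition=(0.3, 40.0))
    )
    jmax_response: TempResponse = field(default_factory=lambda: TempResponse(2.0))
    resp_response: TempResponse = field(default_factory=lambda: TempResponse(2.0))

    def __post_init__(self) -> None:
        for name in ("kc25", "ko25", "gamma_star25", "o2"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a positive pressure; got {value}")

    def kc(self, t_c: float) -> float:
        """Michaelis constant for CO2 (Pa) at leaf temperature."""
        return self.kc25 * self.kc_response.factor(t_c)

    def ko(self, t_c: float) -> float:
        """Michaelis constant for O2 (Pa) at leaf temperature."""
        return self.ko25 * self.ko_response.factor(t_c)

    def gamma_star(self, t_c: float) -> float:
        """CO2 compensation point without dark respiration (Pa)."""
        return self.gamma_star25 * self.gamma_star_response.factor(t_c)

    def km(self, t_c: float) -> float:
        """Effective Michaelis constant ``Kc * (1 + O/Ko)`` (Pa)."""
        return self.kc(t_c) * (1.0 + self.o2 / self.ko(t_c))


#: The Collatz (1991) convention used as the common standardisation target.
COLLATZ = KineticConstants()
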