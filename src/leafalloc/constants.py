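"""Physical constants and unit conversions used throughout the package.

Every unit conversion lives here so that numerical results are bit-stable
and auditable in one place.
"""

#: Standard atmospheric pressure (Pa) used for ppm -> Pa conversion.
STANDARD_PRESSURE_PA = 101_325.0

#: Atmospheric O2 partial pressure (Pa) at standard pressure.
O2_PARTIAL_PRESSURE_PA = 21_000.0

#: Grams of carbon per micromole of CO2 (12 g/mol * 1e-6 mol/umol).
G_C_PER_UMOL_CO2 = 12.0e-6

SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24.0
SECONDS_PER_DAY = SECONDS_PER_HOUR * HOURS_PER_DAY

#: Reference temperature (degrees C) for all rate parameters.
T_REF_C = 25.0


def ppm_to_pa(ppm: float, pressure_pa: float = STANDARD_PRESSURE_PA) -> float:
    """Convert a molar mixing ratio (ppm) to a partial pressure (Pa)."""
    return ppm * 1e-6 * pressure_pa


def umol_s_to_g_c_per_period(rate_umol_m2_s: float, hours: float) -> float:
    """Convert a CO2 flux (umol CO2 m-2 s-1) sustained for `hours` into g C m-2."""
    return rate_umol_m2_s * hours * SECONDS_PER_HOUR * G_C_PER_UMOL_CO2
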