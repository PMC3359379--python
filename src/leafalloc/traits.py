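"""Plant trait sets and nitrogen use efficiencies.

The nitrogen-use-efficiency defaults are standard leaf-biochemistry values:
Rubisco turnover gives ~128 umol CO2 s-1 per g Rubisco N at 25 C; the
electron-transport chain ~420 umol e- s-1 per g bioenergetics N; the
chlorophyll-protein complexes bind ~1.8 mmol Chl per g light-capture N.
All of them are configuration, not constants of nature: absolute predicted
capacities move with them while relative acclimation responses are robust
to moderate rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["PlantTraits", "NitrogenUseEfficiencies", "DEFAULT_NUE"]


@dataclass(frozen=True)
class PlantTraits:
    """Traits of a leaf layer and the plant's nitrogen strategy.

    Parameters
    ----------
    lma : float
        Leaf mass per unit area (g m-2).
    f_s : float
        Proportion of whole-plant storage nitrogen charged to the leaf
        layer's budget (0-1).
    d_ns : float
        Nitrogen storage duration (days): how long the storage pool could
        sustain the current growth rate if uptake ceased.
    f_cleaf : float
        Proportion of net carbon assimilation allocated to leaf biomass.
    leaf_n : float or None
        Leaf nitrogen content (g N g-1 leaf). Used to derive ``fnc_m`` when
        the latter is not given directly.
    fnc_m : float or None
        Plant functional nitrogen per unit leaf biomass (g N g-1 leaf).
    f_r : float
        Leaf share of whole-plant respiratory nitrogen (default 0.5).
    structural_n : float
        Structural nitrogen, fixed at 0.001 g N g-1 biomass.
    nonleaf_n_ratio : float
        Nitrogen content of non-leaf new tissue relative to leaf tissue.
    carbon_frac : float
        Carbon fraction of new biomass (g C g-1 biomass).
    """

    lma: float
    f_s: float
    d_ns: float
    f_cleaf: float
    leaf_n: float | None = None
    fnc_m: float | None = None
    f_r: float = 0.5
    structural_n: float = 0.001
    nonleaf_n_ratio: float = 0.25
    carbon_frac: float = 0.5

    def __post_init__(self) -> None:
        errors = []
        for name in ("f_s", "f_r", "f_cleaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must lie in [0, 1]; got {v}")
        if not (math.isfinite(self.d_ns) and self.d_ns >= 0):
            errors.append(f"d_ns must be >= 0; got {self.d_ns}")
        if not (math.isfinite(self.lma) and self.lma > 0):
            errors.append(f"lma must be > 0; got {self.lma}")
        if self.leaf_n is None and self.fnc_m is None:
            errors.append("one of leaf_n or fnc_m is required")
        if self.fnc_m is not None and self.fnc_m < 0:
            errors.append(f"fnc_m must be >= 0; got {self.fnc_m}")
        if self.leaf_n is not None and self.leaf_n <= 0:
            errors.append(f"leaf_n must be > 0; got {self.leaf_n}")
        if not 0.0 < self.carbon_frac <= 1.0:
            errors.append(f"carbon_frac must lie in (0, 1]; got {self.carbon_frac}")
        if errors:
            raise ValueError("invalid PlantTraits: " + "; ".join(errors))

    def functional_n_mass(self) -> float:
        """Functional N per g leaf (g N g-1): ``fnc_m`` or ``leaf_n - structural_n``."""
        if self.fnc_m is not None:
            return self.fnc_m
        return max(self.leaf_n - self.structural_n, 0.0)

    def total_leaf_n(self) -> float:
        """Total leaf N content (g N g-1 leaf), including structural N."""
        if self.leaf_n is not None:
            return self.leaf_n
        return self.fnc_m + self.structural_n

    def new_tissue_n(self) -> float:
        """N concentration of newly grown tissue (g N g-1 biomass).

        Blends leaf and non-leaf tissue via the carbon partitioning
        fraction: ``f_cleaf * leaf_n + (1 - f_cleaf) * nonleaf_n_ratio * leaf_n``.
        """
        ln = self.total_leaf_n()
        return ln * (self.f_cleaf + (1.0 - self.f_cleaf) * self.nonleaf_n_ratio)

    def with_leaf_n(self, leaf_n: float) -> "PlantTraits":
        """Copy of the traits at a different leaf N content (fnc_m rederived)."""
        return replace(self, leaf_n=leaf_n, fnc_m=None)


@dataclass(frozen=True)
class NitrogenUseEfficiencies:
    """Capacity generated per gram of nitrogen in each enzyme pool.

    ``nue_cb``: Vcmax25 per g carboxylation N (umol CO2 g-1 N s-1).
    ``nue_et``: Jmax25 per g electron-transport N (umol e- g-1 N s-1).
    ``nue_resp``: respiratory capacity at 25 C per g mitochondrial N.
    ``chl_per_n``: chlorophyll bound per g light-capture N (mmol g-1).
    ``chl_half``: Beer-law chlorophyll scale of leaf absorptance (mmol m-2).
    ``alpha_max``: asymptotic leaf absorptance.
    ``phi_e``: effective electron yield per absorbed photon at operating
    conditions (lumps photosystem partitioning and curvature losses).
    ``maint_resp_coeff``: maintenance respiration per g functional N at
    25 C (umol CO2 g-1 N s-1).
    ``growth_resp_frac``: growth respiration per unit new-tissue carbon.
    """

    nue_cb: float = 128.0
    nue_et: float = 420.0
    nue_resp: float = 30.0
    chl_per_n: float = 1.8
    chl_half: float = 0.11
    alpha_max: float = 0.85
    phi_e: float = 0.22
    maint_resp_coeff: float = 0.5
    growth_resp_frac: float = 0.25

    def __post_init__(self) -> None:
        errors = []
        for name in (
            "nue_cb",
            "nue_et",
            "nue_resp",
            "chl_per_n",
            "chl_half",
            "maint_resp_coeff",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                errors.append(f"{name} must be > 0; got {v}")
        if not 0.0 < self.alpha_max <= 1.0:
            errors.append(f"alpha_max must lie in (0, 1]; got {self.alpha_max}")
        if not 0.0 < self.phi_e <= 0.5:
            errors.append(f"phi_e must lie in (0, 0.5]; got {self.phi_e}")
        if not 0.0 <= self.growth_resp_frac < 1.0:
            errors.append(
                f"growth_resp_frac must lie in [0, 1); got {self.growth_resp_frac}"
            )
        if errors:
            raise ValueError("invalid NitrogenUseEfficiencies: " + "; ".join(errors))

    def absorptance(self, n_lc: float) -> float:
        """Leaf absorptance from light-capture N via Beer's law in chlorophyll."""
        if n_lc < 0:
            raise ValueError(f"n_lc must be >= 0; got {n_lc}")
        chl = self.chl_per_n * n_lc
        return self.alpha_max * (1.0 - math.exp(-chl / self.chl_half))

    def n_lc_for_absorptance(self, alpha: float) -> float:
        """Inverse of :meth:`absorptance`; infeasible targets return +inf."""
        if alpha < 0:
            raise ValueError(f"absorptance must be >= 0; got {alpha}")
        ratio = alpha / self.alpha_max
        if ratio >= 1.0:
            return math.inf
        return -self.chl_half * math.log(1.0 - ratio) / self.chl_per_n


DEFAULT_NUE = NitrogenUseEfficiencies()
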