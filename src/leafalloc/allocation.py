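"""Optimal partitioning of a leaf layer's functional nitrogen.

The leaf layer has a fixed area-based functional nitrogen budget
``FNA_a = FNC_m * LMA``. The budget is split among five pools — storage,
respiration, light capture, electron transport and carboxylation — so that
three conditions hold simultaneously:

i.   storage nitrogen equals the requirement implied by the daily net
     photosynthesis rate, the nitrogen concentration of new tissue, and the
     storage duration ``D_ns`` (leaf share ``f_s``);
ii.  respiratory nitrogen equals the enzyme capacity demanded by maintenance
     plus growth respiration at the prevailing temperatures (leaf share
     ``f_r``), with maintenance respiration proportional to the total
     functional nitrogen supported (photosynthetic + storage + respiratory);
iii. the Rubisco-, electron-transport- and light-capture-limited
     carboxylation rates are equal (co-limitation), which maximises
     photosynthesis for the nitrogen spent.

Because each pool's nitrogen cost is a closed-form, strictly increasing
function of the common co-limited rate ``A``, the solve reduces to a
bracketed one-dimensional root find on ``A``: total nitrogen demanded minus
the budget. The forward model contains no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.optimize import brentq

from . import constants as const
from .kinetics import COLLATZ, KineticConstants
from .photosynthesis import Environment, PhotoCapacity
from .traits import DEFAULT_NUE, NitrogenUseEfficiencies, PlantTraits

__all__ = [
    "NitrogenAllocation",
    "AllocationSolution",
    "LeafNitrogenModel",
    "ConvergenceError",
    "functional_n_area",
    "storage_requirement",
    "respiration_requirement",
    "maintenance_respiration_rate",
    "capacities_from_n",
    "solve_allocation",
]

POOLS = ("store", "resp", "lc", "et", "cb")


class ConvergenceError(RuntimeError):
    """The allocation root could not be bracketed or refined."""


@dataclass(frozen=True)
class NitrogenAllocation:
    """Nitrogen masses (g N m-2 leaf) of the five functional pools."""

    n_store: float
    n_resp: float
    n_lc: float
    n_et: float
    n_cb: float
    fna_a: float

    @property
    def total(self) -> float:
        return self.n_store + self.n_resp + self.n_lc + self.n_et + self.n_cb

    @property
    def fractions(self) -> dict[str, float]:
        """Pool sizes as proportions of the functional N budget."""
        denom = self.fna_a if self.fna_a > 0 else 1.0
        return {
            "store": self.n_store / denom,
            "resp": self.n_resp / denom,
            "lc": self.n_lc / denom,
            "et": self.n_et / denom,
            "cb": self.n_cb / denom,
        }


def functional_n_area(traits: PlantTraits) -> float:
    """Leaf-area-based functional nitrogen availability (g N m-2 leaf)."""
    return traits.functional_n_mass() * traits.lma


def _storage_total(a_net_daily: float, traits: PlantTraits) -> float:
    """Whole-plant storage N requirement per m2 leaf (g N m-2).

    Net daily carbon gain converts to a biomass growth rate through the
    carbon fraction; multiplying by new-tissue N concentration and the
    storage duration gives the store needed to sustain that growth rate.
    """
    growth_n_per_day = max(a_net_daily, 0.0) * traits.new_tissue_n() / traits.carbon_frac
    return growth_n_per_day * traits.d_ns


def storage_requirement(a_net_daily: float, traits: PlantTraits) -> float:
    """Leaf-layer storage nitrogen requirement (g N m-2).

    ``f_s`` maps the whole-plant storage demand onto the leaf budget.
    Negative net assimilation clamps the requirement to zero.
    """
    return traits.f_s * _storage_total(a_net_daily, traits)


def maintenance_respiration_rate(
    functional_n_total: float,
    t_c: float,
    nue: NitrogenUseEfficiencies = DEFAULT_NUE,
    kinetics: KineticConstants = COLLATZ,
) -> float:
    """Maintenance respiration (umol CO2 m-2 s-1) of ``functional_n_total`` g N."""
    return nue.maint_resp_coeff * kinetics.resp_response.factor(t_c) * functional_n_total


def respiration_requirement(
    a_gross_daily: float,
    functional_n_total: float,
    traits: PlantTraits,
    env: Environment,
    nue: NitrogenUseEfficiencies = DEFAULT_NUE,
    kinetics: KineticConstants = COLLATZ,
) -> float:
    """Leaf-layer respiratory enzyme nitrogen requirement (g N m-2).

    The mitochondrial machinery must cover, at every time of day, the sum of
    maintenance respiration (proportional to total supported functional N)
    and growth respiration (proportional to the net-of-maintenance carbon
    surplus, spread over the photoperiod). The binding period sizes the
    25 C enzyme capacity; ``f_r`` maps the whole-plant demand to the leaf.
    """
    f_day = kinetics.resp_response.factor(env.day_temp)
    daysec = env.day_hours * const.SECONDS_PER_HOUR
    nightsec = env.night_hours * const.SECONDS_PER_HOUR
    u = const.G_C_PER_UMOL_CO2
    maint_daily = (
        nue.maint_resp_coeff
        * functional_n_total
        * (f_day * daysec + kinetics.resp_response.factor(env.night_temp) * nightsec)
        * u
    )
    surplus = a_gross_daily - maint_daily
    growth_rate_day = nue.growth_resp_frac * max(surplus, 0.0) / (daysec * u)
    # Daytime demand / f(T_day) always dominates the night-time demand.
    r25_required = nue.maint_resp_coeff * functional_n_total + growth_rate_day / f_day
    return traits.f_r * r25_required / nue.nue_resp


def capacities_from_n(
    n_cb: float,
    n_et: float,
    n_lc: float,
    nue: NitrogenUseEfficiencies = DEFAULT_NUE,
) -> tuple[float, float, float]:
    """Map pool nitrogen to (Vcmax25, Jmax25, leaf absorptance).

    Vcmax25 and Jmax25 are exactly linear in their pools; absorptance
    saturates with chlorophyll (Beer law) and is bounded by ``alpha_max``.
    """
    for name, v in (("n_cb", n_cb), ("n_et", n_et), ("n_lc", n_lc)):
        if not (math.isfinite(v) and v >= 0):
            raise ValueError(f"{name} must be >= 0; got {v}")
    return nue.nue_cb * n_cb, nue.nue_et * n_et, nue.absorptance(n_lc)


@dataclass(frozen=True)
class _Context:
    """Precomputed per-solve constants (day-temperature kinetics, unit factors)."""

    ci: float
    gamma_star: float
    km: float
    f_vcmax: float
    f_jmax: float
    f_resp_day: float
    daysec: float
    c_maint: float  # g C day-1 respired per g functional N
    k_store: float  # g N stored per (g C day-1) of net assimilation
    c_resp_growth: float  # g resp-enzyme N per (g C day-1) of surplus
    m_over_nue: float  # maint capacity per g functional N / nue_resp
    j_cost: float  # electron flux per unit net carboxylation rate
    a_max: float  # light-capture asymptote of the net rate


def _build_context(
    traits: PlantTraits,
    env: Environment,
    nue: NitrogenUseEfficiencies,
    kinetics: KineticConstants,
) -> _Context:
    t_day = env.day_temp
    ci = env.ci_pa
    gs = kinetics.gamma_star(t_day)
    km = kinetics.km(t_day)
    f_resp_day = kinetics.resp_response.factor(t_day)
    f_resp_night = kinetics.resp_response.factor(env.night_temp)
    daysec = env.day_hours * const.SECONDS_PER_HOUR
    nightsec = env.night_hours * const.SECONDS_PER_HOUR
    u = const.G_C_PER_UMOL_CO2
    c_maint = nue.maint_resp_coeff * (f_resp_day * daysec + f_resp_night * nightsec) * u
    k_store = traits.new_tissue_n() / traits.carbon_frac * traits.d_ns
    c_resp_growth = nue.growth_resp_frac / (daysec * u * f_resp_day * nue.nue_resp)
    j_cost = (4.0 * ci + 8.0 * gs) / (ci - gs) if ci > gs else math.inf
    a_max = (
        nue.phi_e * env.par * nue.alpha_max / j_cost if math.isfinite(j_cost) else 0.0
    )
    return _Context(
        ci=ci,
        gamma_star=gs,
        km=km,
        f_vcmax=kinetics.vcmax_response.factor(t_day),
        f_jmax=kinetics.jmax_response.factor(t_day),
        f_resp_day=f_resp_day,
        daysec=daysec,
        c_maint=c_maint,
        k_store=k_store,
        c_resp_growth=c_resp_growth,
        m_over_nue=nue.maint_resp_coeff / nue.nue_resp,
        j_cost=j_cost,
        a_max=a_max,
    )


def solve_allocation(
    traits: PlantTraits,
    env: Environment,
    nue: NitrogenUseEfficiencies = DEFAULT_NUE,
    kinetics: KineticConstants = COLLATZ,
) -> "AllocationSolution":
    """Solve the co-limited nitrogen allocation for one leaf layer."""
    model = LeafNitrogenModel(traits, env, nue=nue, kinetics=kinetics)
    return model.solve()


class LeafNitrogenModel:
    """Mechanistic leaf nitrogen-allocation model for a single leaf layer.

    Statsmodels-style entry point: construct from traits and environment,
    call :meth:`solve` to obtain an :class:`AllocationSolution`.

    Parameters
    ----------
    traits : PlantTraits
    env : Environment
    nue : NitrogenUseEfficiencies, optional
    kinetics : KineticConstants, optional
        Kinetic convention under which the emitted Vcmax25/Jmax25 are defined.
    """

    def __init__(
        self,
        traits: PlantTraits,
        env: Environment,
        nue: NitrogenUseEfficiencies | None = None,
        kinetics: KineticConstants | None = None,
    ) -> None:
        self.traits = traits
        self.env = env
        self.nue = nue if nue is not None else DEFAULT_NUE
        self.kinetics = kinetics if kinetics is not None else COLLATZ

    @classmethod
    def from_config(cls, path) -> "LeafNitrogenModel":
        """Build a model from a traits/environment config file (YAML)."""
        from .io import read_trait_env_config

        traits, env = read_trait_env_config(path)
        return cls(traits, env)

    # -- internal pieces -------------------------------------------------

    def _photo_n(self, a_rate: float, ctx: _Context):
        """Pool N for light capture / electron transport / carboxylation
        at a common co-limited net rate ``a_rate``."""
        nue = self.nue
        ci, gs = ctx.ci, ctx.gamma_star
        vcmax25 = a_rate * (ci + ctx.km) / ((ci - gs) * ctx.f_vcmax)
        n_cb = vcmax25 / nue.nue_cb
        j_req = a_rate * ctx.j_cost
        jmax25 = j_req / ctx.f_jmax
        n_et = jmax25 / nue.nue_et
        alpha_req = j_req / (nue.phi_e * self.env.par) if self.env.par > 0 else math.inf
        n_lc = nue.n_lc_for_absorptance(alpha_req) if math.isfinite(alpha_req) else math.inf
        return n_cb, n_et, n_lc, vcmax25, jmax25

    def _support_n(self, a_rate: float, n_ps: float, ctx: _Context):
        """Storage and respiratory N consistent with rate ``a_rate``.

        Maintenance respiration is proportional to the total functional N
        supported, F = N_ps + storage_total + resp_N_total, which makes F a
        linear fixed point with a closed-form solution on each branch of
        the net-assimilation clamp.
        """
        nue = self.nue
        g = nue.growth_resp_frac
        gross_daily = a_rate * ctx.daysec * const.G_C_PER_UMOL_CO2
        coef = ctx.k_store * (1.0 - g) + ctx.c_resp_growth
        denom = 1.0 + coef * ctx.c_maint - ctx.m_over_nue
        f_total = (n_ps + coef * gross_daily) / denom
        surplus = gross_daily - ctx.c_maint * f_total
        if surplus < 0.0:
            # Maintenance exceeds gross gain: no growth, no storage demand.
            f_total = n_ps / (1.0 - ctx.m_over_nue)
            surplus = gross_daily - ctx.c_maint * f_total
            storage_total = 0.0
            resp_n_total = ctx.m_over_nue * f_total
            a_net_daily = surplus
        else:
            storage_total = ctx.k_store * (1.0 - g) * surplus
            resp_n_total = ctx.m_over_nue * f_total + ctx.c_resp_growth * surplus
            a_net_daily = (1.0 - g) * surplus
        return storage_total, resp_n_total, f_total, gross_daily, a_net_daily

    def _residual(self, a_rate: float, ctx: _Context, fna: float) -> float:
        n_cb, n_et, n_lc, _, _ = self._photo_n(a_rate, ctx)
        if not math.isfinite(n_lc):
            return math.inf
        n_ps = n_cb + n_et + n_lc
        storage_total, resp_n_total, _, _, _ = self._support_n(a_rate, n_ps, ctx)
        return (
            n_ps
            + self.traits.f_s * storage_total
            + self.traits.f_r * resp_n_total
            - fna
        )

    def _degenerate(self, fna: float, message: str) -> "AllocationSolution":
        alloc = NitrogenAllocation(
            n_store=max(fna, 0.0), n_resp=0.0, n_lc=0.0, n_et=0.0, n_cb=0.0,
            fna_a=max(fna, 0.0),
        )
        return AllocationSolution(
            model=self,
            allocation=alloc,
            capacity=PhotoCapacity(0.0, 0.0, kinetics=self.kinetics),
            a_rate=0.0,
            a_gross_daily=0.0,
            a_net_daily=0.0,
            functional_n_total=max(fna, 0.0),
            degenerate=True,
            message=message,
        )

    # -- public API ------------------------------------------------------

    def solve(self) -> "AllocationSolution":
        """Find the allocation satisfying conservation, demand-matching and
        co-limitation; deterministic for given inputs.

        Returns a degenerate all-storage allocation (flagged) when no
        positive photosynthesis is feasible (zero budget, zero light, or
        Ci below the compensation point). Raises :class:`ConvergenceError`
        if the root cannot be bracketed.
        """
        fna = functional_n_area(self.traits)
        ctx = _build_context(self.traits, self.env, self.nue, self.kinetics)
        if fna <= 0.0:
            return self._degenerate(fna, "non-positive functional N budget")
        if self.env.par <= 0.0:
            return self._degenerate(fna, "no photosynthetically active radiation")
        if ctx.ci <= ctx.gamma_star:
            return self._degenerate(
                fna, "intercellular CO2 at or below the compensation point"
            )

        a_hi = ctx.a_max * (1.0 - 1e-12)
        res_hi = self._residual(a_hi, ctx, fna)
        if not res_hi > 0.0:
            raise ConvergenceError(
                "allocation root not bracketable: residual at the light-capture "
                f"asymptote (A={a_hi:.4g}) is {res_hi:.4g} <= 0; "
                f"budget FNA_a={fna:.4g} g N m-2 cannot be exhausted"
            )
        a_star = brentq(
            self._residual, 0.0, a_hi, args=(ctx, fna), xtol=1e-14, maxiter=200
        )

        n_cb, n_et, n_lc, vcmax25, jmax25 = self._photo_n(a_star, ctx)
        n_ps = n_cb + n_et + n_lc
        storage_total, resp_n_total, f_total, gross_daily, a_net_daily = (
            self._support_n(a_star, n_ps, ctx)
        )
        alloc = NitrogenAllocation(
            n_store=self.traits.f_s * storage_total,
            n_resp=self.traits.f_r * resp_n_total,
            n_lc=n_lc,
            n_et=n_et,
            n_cb=n_cb,
            fna_a=fna,
        )
        return AllocationSolution(
            model=self,
            allocation=alloc,
            capacity=PhotoCapacity(vcmax25, jmax25, kinetics=self.kinetics),
            a_rate=a_star,
            a_gross_daily=gross_daily,
            a_net_daily=a_net_daily,
            functional_n_total=f_total,
            degenerate=False,
            message="",
        )


@dataclass(frozen=True)
class AllocationSolution:
    """Result of a leaf nitrogen-allocation solve.

    Carries the nitrogen pools, the implied photosynthetic capacities at
    25 C, carbon-balance diagnostics and convergence flags; ``summary()``
    renders a human-readable report.
    """

    model: LeafNitrogenModel = field(repr=False)
    allocation: NitrogenAllocation
    capacity: PhotoCapacity
    a_rate: float
    a_gross_daily: float
    a_net_daily: float
    functional_n_total: float
    degenerate: bool
    message: str

    @property
    def fractions(self) -> dict[str, float]:
        return self.allocation.fractions

    @property
    def vcmax25(self) -> float:
        return self.capacity.vcmax25

    @property
    def jmax25(self) -> float:
        return self.capacity.jmax25

    def limiting_rates(self) -> dict[str, float]:
        """The three limiting net carboxylation rates at the growth
        environment (equal at a converged, non-degenerate solution)."""
        mdl = self.model
        env, nue = mdl.env, mdl.nue
        kin = mdl.kinetics
        t = env.day_temp
        ci = env.ci_pa
        gs = kin.gamma_star(t)
        if ci <= gs:
            return {"rubisco": 0.0, "electron": 0.0, "light": 0.0}
        denom_j = 4.0 * ci + 8.0 * gs
        a_c = (
            self.vcmax25 * kin.vcmax_response.factor(t) * (ci - gs) / (ci + kin.km(t))
        )
        a_j = self.jmax25 * kin.jmax_response.factor(t) * (ci - gs) / denom_j
        alpha = nue.absorptance(self.allocation.n_lc)
        a_i = nue.phi_e * env.par * alpha * (ci - gs) / denom_j
        return {"rubisco": a_c, "electron": a_j, "light": a_i}

    def to_frame(self) -> pd.DataFrame:
        """One tidy row: pool masses, fractions, capacities, diagnostics."""
        alloc = self.allocation
        row: dict[str, float | bool | str] = {
            "fna_a_g_m2": alloc.fna_a,
            "n_store_g_m2": alloc.n_store,
            "n_resp_g_m2": alloc.n_resp,
            "n_lc_g_m2": alloc.n_lc,
            "n_et_g_m2": alloc.n_et,
            "n_cb_g_m2": alloc.n_cb,
        }
        for pool, frac in alloc.fractions.items():
            row[f"frac_{pool}"] = frac
        row.update(
            vcmax25_umol_m2_s=self.vcmax25,
            jmax25_umol_m2_s=self.jmax25,
            a_rate_umol_m2_s=self.a_rate,
            a_gross_g_c_m2_d=self.a_gross_daily,
            a_net_g_c_m2_d=self.a_net_daily,
            functional_n_total_g_m2=self.functional_n_total,
            degenerate=self.degenerate,
        )
        return pd.DataFrame([row])

    def summary(self) -> str:
        alloc = self.allocation
        lines = [
            "Leaf nitrogen allocation solution",
            "=================================",
            f"functional N budget FNA_a : {alloc.fna_a:10.4f} g N m-2",
            f"total functional N (plant): {self.functional_n_total:10.4f} g N m-2",
            "",
            "pool            g N m-2   fraction",
        ]
        names = {
            "store": "storage",
            "resp": "respiration",
            "lc": "light capture",
            "et": "electron transp",
            "cb": "carboxylation",
        }
        masses = {
            "store": alloc.n_store,
            "resp": alloc.n_resp,
            "lc": alloc.n_lc,
            "et": alloc.n_et,
            "cb": alloc.n_cb,
        }
        for pool in POOLS:
            lines.append(
                f"{names[pool]:<15s} {masses[pool]:8.4f}   {alloc.fractions[pool]:8.4f}"
            )
        lines += [
            "",
            f"Vcmax25 : {self.vcmax25:8.2f} umol CO2 m-2 s-1",
            f"Jmax25  : {self.jmax25:8.2f} umol e- m-2 s-1",
            f"A (day) : {self.a_rate:8.2f} umol CO2 m-2 s-1 (co-limited, net)",
            f"net gain: {self.a_net_daily:8.3f} g C m-2 d-1",
        ]
        if self.degenerate:
            lines.append(f"flag    : degenerate ({self.message})")
        return "\n".join(lines)
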