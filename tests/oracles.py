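"""Independent brute-force oracles used only by the test suite.

The grid-search oracle maximises the photosynthesis rate over the
(light-capture, electron-transport, carboxylation) nitrogen simplex by
exhaustive nested-refinement search, subject to the storage and
respiratory demands fitting inside the nitrogen budget (their fixed point
solved by plain iteration, not the solver's closed form), breaking
rate ties toward the cheapest allocation. It never imposes co-limitation
and never calls the allocation root-finder, so agreement with
``solve_allocation`` is a genuine cross-check of the optimiser.
"""

from __future__ import annotations

import numpy as np

from leafalloc import COLLATZ, DEFAULT_NUE
from leafalloc.allocation import functional_n_area
from leafalloc.constants import G_C_PER_UMOL_CO2, SECONDS_PER_HOUR


def grid_search_allocation(
    traits,
    env,
    nue=DEFAULT_NUE,
    kinetics=COLLATZ,
    n_grid: int = 17,
    refinements: int = 5,
):
    """Best allocation found by nested-refinement exhaustive search.

    Returns a dict with the five pool masses, the achieved net daily gain
    and the limiting net rate.
    """
    fna = functional_n_area(traits)
    t_day = env.day_temp
    ci = env.ci_pa
    gs = kinetics.gamma_star(t_day)
    km = kinetics.km(t_day)
    fv = kinetics.vcmax_response.factor(t_day)
    fj = kinetics.jmax_response.factor(t_day)
    fr_d = kinetics.resp_response.factor(t_day)
    fr_n = kinetics.resp_response.factor(env.night_temp)
    daysec = env.day_hours * SECONDS_PER_HOUR
    nightsec = (24.0 - env.day_hours) * SECONDS_PER_HOUR
    u = G_C_PER_UMOL_CO2
    g = nue.growth_resp_frac
    k_store = traits.new_tissue_n() / traits.carbon_frac * traits.d_ns
    c_maint = nue.maint_resp_coeff * (fr_d * daysec + fr_n * nightsec) * u
    co2_term = (ci - gs) / (4.0 * ci + 8.0 * gs)

    def evaluate(n_lc, n_et, n_cb):
        """Net daily gain for arrays of candidate photosynthetic pools."""
        a_c = nue.nue_cb * n_cb * fv * (ci - gs) / (ci + km)
        a_j = nue.nue_et * n_et * fj * co2_term
        alpha = nue.alpha_max * (1.0 - np.exp(-nue.chl_per_n * n_lc / nue.chl_half))
        a_i = nue.phi_e * env.par * alpha * co2_term
        a = np.minimum(np.minimum(a_c, a_j), a_i)
        gross = a * daysec * u
        n_ps = n_lc + n_et + n_cb
        # Fixed point for total supported functional N. The map is
        # decreasing in F (storage shrinks as maintenance grows) and can be
        # steeper than -1, so use damped iteration, which converges for any
        # slope above about -5.
        f_tot = n_ps.copy()
        damping = 0.3
        for _ in range(400):
            surplus = gross - c_maint * f_tot
            pos = np.maximum(surplus, 0.0)
            storage_total = k_store * (1.0 - g) * pos
            growth_rate = g * pos / (daysec * u)
            resp_total = (
                nue.maint_resp_coeff * f_tot + growth_rate / fr_d
            ) / nue.nue_resp
            f_new = n_ps + storage_total + resp_total
            if np.max(np.abs(f_new - f_tot)) < 1e-13:
                f_tot = f_new
                break
            f_tot = f_tot + damping * (f_new - f_tot)
        surplus = gross - c_maint * f_tot
        pos = np.maximum(surplus, 0.0)
        storage_total = k_store * (1.0 - g) * pos
        growth_rate = g * pos / (daysec * u)
        resp_total = (
            nue.maint_resp_coeff * f_tot + growth_rate / fr_d
        ) / nue.nue_resp
        budget = n_ps + traits.f_s * storage_total + traits.f_r * resp_total
        a_net = np.where(surplus >= 0.0, (1.0 - g) * surplus, surplus)
        feasible = budget <= fna * (1.0 + 1e-9)
        objective = np.where(feasible, a, -np.inf)
        return objective, a_net, budget, storage_total, resp_total

    center = np.full(3, fna / 6.0)
    width = fna
    best = None
    for _ in range(refinements):
        axes = [
            np.linspace(max(c - width / 2.0, 0.0), min(c + width / 2.0, fna), n_grid)
            for c in center
        ]
        lc, et, cb = np.meshgrid(*axes, indexing="ij")
        objective, a_net, budget, storage_total, resp_total = evaluate(lc, et, cb)
        top = np.max(objective)
        # Ties along the min() plateau: prefer the cheapest allocation, which
        # is the one with no over-provisioned pool.
        near_top = objective >= top - (1e-12 + 1e-9 * abs(top))
        cost = np.where(near_top, budget, np.inf)
        idx = np.unravel_index(np.argmin(cost), cost.shape)
        best = {
            "n_lc": float(lc[idx]),
            "n_et": float(et[idx]),
            "n_cb": float(cb[idx]),
            "n_store": float(traits.f_s * storage_total[idx]),
            "n_resp": float(traits.f_r * resp_total[idx]),
            "a_net_daily": float(a_net[idx]),
            "a_rate": float(objective[idx]),
        }
        center = np.array([best["n_lc"], best["n_et"], best["n_cb"]])
        width *= 0.2
    return best
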