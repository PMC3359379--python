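import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafalloc import (
    DEFAULT_NUE,
    Environment,
    LeafNitrogenModel,
    PlantTraits,
    capacities_from_n,
    functional_n_area,
    respiration_requirement,
    solve_allocation,
    storage_requirement,
)
from leafalloc.allocation import maintenance_respiration_rate

from conftest import random_environment, random_traits
from oracles import grid_search_allocation


class TestFunctionalNArea:
    def test_direct_product(self):
        traits = PlantTraits(lma=100.0, fnc_m=0.01, f_s=0.5, d_ns=10.0, f_cleaf=0.2)
        assert functional_n_area(traits) == pytest.approx(1.0)

    def test_zero_functional_n(self):
        traits = PlantTraits(lma=100.0, fnc_m=0.0, f_s=0.5, d_ns=10.0, f_cleaf=0.2)
        assert functional_n_area(traits) == 0.0

    def test_derived_from_leaf_n_minus_structural(self):
        traits = PlantTraits(
            lma=85.0, leaf_n=0.015, f_s=0.5, d_ns=10.0, f_cleaf=0.2,
            structural_n=0.001,
        )
        # bookkeeping: (0.015 - 0.001) * 85
        assert functional_n_area(traits) == pytest.approx(0.014 * 85.0)

    def test_missing_both_nitrogen_inputs_errors(self):
        with pytest.raises(ValueError, match="leaf_n or fnc_m"):
            PlantTraits(lma=85.0, f_s=0.5, d_ns=10.0, f_cleaf=0.2)


class TestStorageRequirement:
    def test_zero_at_zero_assimilation(self, pfts):
        assert storage_requirement(0.0, pfts["deciduous"]) == 0.0

    def test_negative_assimilation_clamps_to_zero(self, pfts):
        assert storage_requirement(-3.0, pfts["deciduous"]) == 0.0

    def test_linear_in_storage_duration(self, pfts):
        import dataclasses

        base = pfts["evergreen"]
        doubled = dataclasses.replace(base, d_ns=2 * base.d_ns)
        assert storage_requirement(5.0, doubled) == pytest.approx(
            2.0 * storage_requirement(5.0, base)
        )

    def test_hand_product_for_deciduous_traits(self, pfts):
        # new-tissue N = 0.02*(0.2 + 0.8*0.25) = 0.008 g N/g biomass; with
        # carbon fraction 0.5 and D_ns 85: 0.86 * 5 * 0.016 * 85 = 5.848
        assert storage_requirement(5.0, pfts["deciduous"]) == pytest.approx(
            5.848, rel=1e-12
        )


class TestRespirationRequirement:
    def test_zero_demand_for_zero_n_and_assimilation(self, pfts, control_env):
        assert respiration_requirement(0.0, 0.0, pfts["evergreen"], control_env) == 0.0

    def test_maintenance_rate_increases_with_temperature(self):
        rates = [maintenance_respiration_rate(2.0, t) for t in (5.0, 15.0, 25.0, 35.0)]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_matches_spreadsheet_style_recomputation(self, pfts, control_env):
        """Independent bookkeeping of the demand at a fixed instance."""
        traits = pfts["evergreen"]
        f_total, a_gross = 2.0, 3.0  # g N m-2, g C m-2 d-1
        q10_factor = 2.0 ** ((15.0 - 25.0) / 10.0)
        maint_rate = 0.5 * q10_factor * f_total  # umol m-2 s-1 at 15 C
        maint_daily = maint_rate * 86_400.0 * 12e-6  # whole day at 15 C
        growth_daily = 0.25 * (a_gross - maint_daily)  # g C d-1
        growth_rate = growth_daily / (14.0 * 3600.0 * 12e-6)  # day-period rate
        r25 = 0.5 * f_total + growth_rate / q10_factor
        expected = traits.f_r * r25 / 30.0
        got = respiration_requirement(a_gross, f_total, traits, control_env)
        assert got == pytest.approx(expected, rel=1e-12)


class TestCapacitiesFromN:
    def test_zero_n_gives_zero_vcmax(self):
        vcmax, jmax, alpha = capacities_from_n(0.0, 0.0, 0.0)
        assert vcmax == 0.0 and jmax == 0.0 and alpha == 0.0

    def test_exact_linearity_in_pool_n(self):
        v1, j1, _ = capacities_from_n(0.3, 0.2, 0.1)
        v2, j2, _ = capacities_from_n(0.6, 0.4, 0.1)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)
        assert j2 == pytest.approx(2.0 * j1, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(n_lc=st.floats(0.0, 100.0))
    def test_absorptance_bounded_above_by_one(self, n_lc):
        _, _, alpha = capacities_from_n(0.1, 0.1, n_lc)
        assert 0.0 <= alpha <= 1.0


class TestSolveAllocation:
    def test_zero_budget_is_degenerate_zero(self, control_env):
        traits = PlantTraits(lma=100.0, fnc_m=0.0, f_s=0.5, d_ns=10.0, f_cleaf=0.2)
        sol = solve_allocation(traits, control_env)
        assert sol.degenerate
        assert sol.vcmax25 == 0.0 and sol.jmax25 == 0.0
        assert sol.allocation.total == 0.0

    def test_dark_environment_goes_all_storage(self, pfts):
        env = Environment(par=0.0, co2_ppm=370.0, day_temp=15.0, night_temp=15.0)
        sol = solve_allocation(pfts["evergreen"], env)
        assert sol.degenerate
        assert sol.allocation.n_store == pytest.approx(sol.allocation.fna_a)

    def test_vcmax_monotone_in_functional_n(self, control_env):
        vcs = []
        for fnc in (0.004, 0.008, 0.012, 0.016, 0.02):
            traits = PlantTraits(
                lma=85.0, fnc_m=fnc, f_s=0.5, d_ns=50.0, f_cleaf=0.2
            )
            vcs.append(solve_allocation(traits, control_env).vcmax25)
        assert all(b >= a for a, b in zip(vcs, vcs[1:]))

    def test_conservation_and_colimitation_on_random_instances(self):
        from leafalloc import ConvergenceError

        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 25:
            traits = random_traits(rng)
            env = random_environment(rng)
            try:
                sol = solve_allocation(traits, env)
            except ConvergenceError:
                continue
            if sol.degenerate:
                continue
            checked += 1
            alloc = sol.allocation
            assert alloc.total == pytest.approx(alloc.fna_a, rel=1e-6)
            rates = list(sol.limiting_rates().values())
            top = max(rates)
            assert (top - min(rates)) / top < 1e-4
            assert min(
                alloc.n_store, alloc.n_resp, alloc.n_lc, alloc.n_et, alloc.n_cb
            ) >= 0.0

    def test_respiration_selfconsistent_at_solution(self, pfts, control_env):
        sol = solve_allocation(pfts["herbaceous"], control_env)
        alloc = sol.allocation
        got = respiration_requirement(
            sol.a_gross_daily, sol.functional_n_total, pfts["herbaceous"], control_env
        )
        assert got == pytest.approx(alloc.n_resp, rel=1e-9)

    def test_storage_selfconsistent_at_solution(self, pfts, control_env):
        sol = solve_allocation(pfts["deciduous"], control_env)
        assert storage_requirement(sol.a_net_daily, pfts["deciduous"]) == (
            pytest.approx(sol.allocation.n_store, rel=1e-9)
        )

    def test_matches_grid_search_maximizer(self, pfts, control_env):
        """The demand-balancing root find lands on the same allocation as an
        exhaustive constrained maximiser of net carbon gain."""
        sol = solve_allocation(pfts["evergreen"], control_env)
        best = grid_search_allocation(pfts["evergreen"], control_env)
        fna = sol.allocation.fna_a
        for key, value in (
            ("n_lc", sol.allocation.n_lc),
            ("n_et", sol.allocation.n_et),
            ("n_cb", sol.allocation.n_cb),
            ("n_store", sol.allocation.n_store),
            ("n_resp", sol.allocation.n_resp),
        ):
            assert abs(value - best[key]) <= 0.01 * fna

    def test_summary_and_frame_report_the_solution(self, pfts, control_env):
        sol = solve_allocation(pfts["evergreen"], control_env)
        text = sol.summary()
        assert "Vcmax25" in text and "storage" in text
        frame = sol.to_frame()
        assert frame.loc[0, "vcmax25_umol_m2_s"] == pytest.approx(sol.vcmax25)
        assert frame.loc[0, "frac_store"] == pytest.approx(sol.fractions["store"])

    def test_model_from_config_file(self, tmp_path, pfts, control_env):
        config = tmp_path / "leaf.yaml"
        config.write_text(
            "traits:\n"
            "  lma: 85.0\n  leaf_n: 0.015\n  f_s: 0.5\n  d_ns: 50.0\n  f_cleaf: 0.2\n"
            "environment:\n"
            "  par: 800.0\n  co2_ppm: 370.0\n  day_temp: 15.0\n  night_temp: 15.0\n"
        )
        sol = LeafNitrogenModel.from_config(config).solve()
        reference = solve_allocation(pfts["evergreen"], control_env)
        assert sol.vcmax25 == pytest.approx(reference.vcmax25, rel=1e-12)
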