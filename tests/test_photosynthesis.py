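import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafalloc import (
    COLLATZ,
    Environment,
    KineticConstants,
    PhotoCapacity,
    RespirationModel,
    daily_net_assimilation,
    electron_limited_rate,
    rubisco_limited_rate,
    standardize_capacity,
)
from leafalloc.constants import G_C_PER_UMOL_CO2, SECONDS_PER_HOUR
from leafalloc.photosynthesis import realized_electron_transport


class TestRubiscoLimitedRate:
    def test_hand_evaluation_at_reference(self):
        # Vcmax 50, Ci 25 Pa, Kc 30 Pa, Ko 30 kPa, O 21 kPa at 25 C:
        # 50 * 25 / (25 + 30 * (1 + 0.7)) = 16.447
        cap = PhotoCapacity(50.0, 100.0, kinetics=COLLATZ)
        assert rubisco_limited_rate(cap, 25.0, 25.0) == pytest.approx(
            50.0 * 25.0 / (25.0 + 30.0 * 1.7), rel=1e-9
        )
        assert rubisco_limited_rate(cap, 25.0, 25.0) == pytest.approx(16.447, abs=5e-4)

    def test_zero_capacity_gives_zero(self):
        cap = PhotoCapacity(0.0, 0.0)
        for ci in (1.0, 25.0, 200.0):
            assert rubisco_limited_rate(cap, ci, 25.0) == 0.0

    def test_saturates_to_vcmax_at_high_ci(self):
        cap = PhotoCapacity(50.0, 100.0)
        assert rubisco_limited_rate(cap, 1e9, 25.0) == pytest.approx(50.0, rel=1e-6)

    def test_rejects_nonpositive_ci(self):
        cap = PhotoCapacity(50.0, 100.0)
        with pytest.raises(ValueError):
            rubisco_limited_rate(cap, 0.0, 25.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        v1=st.floats(1.0, 150.0),
        dv=st.floats(0.0, 50.0),
        ci=st.floats(5.0, 100.0),
        dci=st.floats(0.0, 50.0),
        t=st.floats(5.0, 35.0),
    )
    def test_monotone_in_capacity_and_ci(self, v1, dv, ci, dci, t):
        lo = rubisco_limited_rate(PhotoCapacity(v1, 0.0), ci, t)
        hi_cap = rubisco_limited_rate(PhotoCapacity(v1 + dv, 0.0), ci, t)
        hi_ci = rubisco_limited_rate(PhotoCapacity(v1, 0.0), ci + dci, t)
        assert hi_cap >= lo
        assert hi_ci >= lo


class TestElectronLimitedRate:
    def test_zero_at_compensation_point(self):
        cap = PhotoCapacity(50.0, 100.0)
        gs = COLLATZ.gamma_star(25.0)
        with pytest.warns(RuntimeWarning):
            assert electron_limited_rate(cap, 100.0, gs, 25.0) == 0.0

    def test_asymptote_j_over_four(self):
        cap = PhotoCapacity(50.0, 100.0)
        assert electron_limited_rate(cap, 100.0, 1e9, 25.0) == pytest.approx(
            25.0, rel=1e-6
        )

    def test_hand_evaluation(self):
        # J=100, Ci=30 Pa, gamma*=3.5 Pa: 100 * 26.5 / 148 = 17.905
        kin = KineticConstants(gamma_star25=3.5)
        cap = PhotoCapacity(50.0, 100.0, kinetics=kin)
        assert electron_limited_rate(cap, 100.0, 30.0, 25.0) == pytest.approx(
            100.0 * 26.5 / 148.0, rel=1e-12
        )

    @settings(derandomize=True, max_examples=60)
    @given(
        j=st.floats(1.0, 300.0),
        dj=st.floats(0.0, 100.0),
        ci=st.floats(10.0, 100.0),
        dci=st.floats(0.0, 50.0),
    )
    def test_monotone_in_flux_and_ci_above_gamma(self, j, dj, ci, dci):
        cap = PhotoCapacity(50.0, 100.0)
        lo = electron_limited_rate(cap, j, ci, 25.0)
        assert electron_limited_rate(cap, j + dj, ci, 25.0) >= lo
        assert electron_limited_rate(cap, j, ci + dci, 25.0) >= lo


class TestRealizedElectronTransport:
    def test_strict_minimum_never_exceeds_either_input(self):
        for light, jmax in [(10.0, 100.0), (100.0, 10.0), (50.0, 50.0)]:
            j = realized_electron_transport(light, jmax)
            assert j <= light and j <= jmax

    def test_smoothed_coupling_below_minimum(self):
        j = realized_electron_transport(80.0, 100.0, smoothing_theta=0.9)
        assert j < min(80.0, 100.0)


class TestDailyNetAssimilation:
    def test_zero_capacity_returns_minus_respiration(self):
        env = Environment(par=800.0, co2_ppm=370.0, day_temp=15.0, night_temp=15.0)
        resp = RespirationModel(maint_rate25=1.0)
        cap = PhotoCapacity(0.0, 0.0)
        expected = -(
            resp.maint_rate(15.0) * 24.0 * SECONDS_PER_HOUR * G_C_PER_UMOL_CO2
        )
        assert daily_net_assimilation(cap, env, resp) == pytest.approx(expected)

    def test_gross_gain_linear_in_photoperiod_without_respiration(self):
        cap = PhotoCapacity(50.0, 100.0)
        resp = RespirationModel(maint_rate25=0.0, growth_frac=0.0)
        short = Environment(par=800.0, co2_ppm=370.0, day_temp=20.0,
                            night_temp=20.0, day_hours=6.0)
        long = Environment(par=800.0, co2_ppm=370.0, day_temp=20.0,
                           night_temp=20.0, day_hours=12.0)
        assert daily_net_assimilation(cap, long, resp) == pytest.approx(
            2.0 * daily_net_assimilation(cap, short, resp), rel=1e-12
        )

    def test_agrees_with_fine_step_quadrature(self):
        """Minute-resolution time integration reproduces the analytic day/night
        split within 0.5% on randomized instances."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            cap = PhotoCapacity(rng.uniform(10, 100), rng.uniform(20, 200))
            env = Environment(
                par=rng.uniform(100, 1500),
                co2_ppm=rng.uniform(300, 700),
                day_temp=rng.uniform(5, 35),
                night_temp=rng.uniform(5, 35),
                day_hours=rng.uniform(8, 16),
            )
            resp = RespirationModel(
                maint_rate25=rng.uniform(0.1, 2.0), growth_frac=0.25
            )
            # independent quadrature: accumulate gross and maintenance per
            # minute, then apply growth respiration to the surplus
            kin = cap.effective_kinetics()
            ci = env.ci_pa
            t = env.day_temp
            gs = kin.gamma_star(t)
            a_c = cap.vcmax25 * kin.vcmax_response.factor(t) * (ci - gs) / (ci + kin.km(t))
            j = min(0.22 * env.par * 0.85, cap.jmax25 * kin.jmax_response.factor(t))
            a_j = j * (ci - gs) / (4 * ci + 8 * gs)
            rate = min(a_c, a_j)
            minutes = np.arange(24 * 60)
            is_day = minutes < env.day_hours * 60
            gross = np.where(is_day, rate, 0.0) * 60.0 * G_C_PER_UMOL_CO2
            maint = (
                np.where(is_day, resp.maint_rate(env.day_temp),
                         resp.maint_rate(env.night_temp))
                * 60.0
                * G_C_PER_UMOL_CO2
            )
            surplus = gross.sum() - maint.sum()
            expected = surplus - resp.growth_frac * max(surplus, 0.0)
            got = daily_net_assimilation(cap, env, resp)
            assert got == pytest.approx(expected, rel=5e-3, abs=1e-9)


class TestStandardizeCapacity:
    def test_identity_under_same_convention(self):
        cap = PhotoCapacity(60.0, 120.0, kinetics=COLLATZ)
        out = standardize_capacity(cap, 25.0, COLLATZ)
        assert out.vcmax25 == pytest.approx(60.0, rel=1e-12)
        assert out.jmax25 == pytest.approx(120.0, rel=1e-12)

    def test_equal_rate_solution_for_different_kc(self):
        # Vcmax 60 reported under Kc25 = 27.2 Pa -> Collatz Kc25 = 30 Pa at
        # Ci = 25 Pa: V * 25/(25 + Km_t) = 60 * 25/(25 + Km_r)
        reported = PhotoCapacity(
            60.0, 0.0, kinetics=KineticConstants(kc25=27.2)
        )
        km_rep = 27.2 * 1.7
        km_tgt = 30.0 * 1.7
        expected = 60.0 * (25.0 + km_tgt) / (25.0 + km_rep)
        out = standardize_capacity(reported, 25.0, COLLATZ, ci_pa=25.0)
        assert out.vcmax25 == pytest.approx(expected, rel=1e-12)

    def test_round_trip_between_conventions(self):
        other = KineticConstants(kc25=40.4, ko25=24_800.0, gamma_star25=3.7)
        cap = PhotoCapacity(75.0, 140.0, kinetics=other)
        there = standardize_capacity(cap, 30.0, COLLATZ)
        back = standardize_capacity(there, 30.0, other)
        assert back.vcmax25 == pytest.approx(75.0, rel=1e-10)
        assert back.jmax25 == pytest.approx(140.0, rel=1e-10)

    def test_missing_convention_is_an_error(self):
        with pytest.raises(ValueError, match="convention"):
            standardize_capacity(PhotoCapacity(60.0, 120.0), 25.0, COLLATZ)


class TestEnvironment:
    def test_ci_from_ca_at_standard_pressure(self):
        env = Environment(par=800.0, co2_ppm=370.0, day_temp=15.0, night_temp=15.0)
        assert env.ca_pa == pytest.approx(370e-6 * 101_325.0)
        assert env.ci_pa == pytest.approx(0.7 * env.ca_pa)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rh=1.5),
            dict(rh=0.0),
            dict(day_hours=24.0),
            dict(ci_ratio=1.2),
            dict(par=-1.0),
        ],
    )
    def test_validation_rejects_out_of_range(self, kwargs):
        base = dict(par=800.0, co2_ppm=370.0, day_temp=15.0, night_temp=15.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            Environment(**base)

    def test_validation_message_is_itemized(self):
        with pytest.raises(ValueError, match="rh.*day_hours"):
            Environment(par=800.0, co2_ppm=370.0, day_temp=15.0,
                        night_temp=15.0, rh=2.0, day_hours=30.0)


def test_colimited_rate_never_exceeds_either_pathway():
    cap = PhotoCapacity(50.0, 100.0)
    env = Environment(par=800.0, co2_ppm=370.0, day_temp=20.0, night_temp=20.0)
    kin = cap.effective_kinetics()
    ci = env.ci_pa
    gs = kin.gamma_star(20.0)
    a_c = cap.vcmax25 * kin.vcmax_response.factor(20.0) * (ci - gs) / (ci + kin.km(20.0))
    jmax_t = cap.jmax25 * kin.jmax_response.factor(20.0)
    light = 0.22 * env.par * 0.85
    j = realized_electron_transport(light, jmax_t)
    a_j = j * (ci - gs) / (4 * ci + 8 * gs)
    assert min(a_c, a_j) <= a_c
    assert min(a_c, a_j) <= a_j
    assert math.isfinite(min(a_c, a_j))
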