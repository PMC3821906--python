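"""Engine-level tests: derived rates, stepping, dying pipeline, simulate."""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtkinetics.kinetics import (
    CELLS_PER_CC,
    GrowthParams,
    InvalidParameterError,
    PopulationState,
    derive_rates,
    init_state,
    mean_dying_time,
    simulate,
    step,
    tc_from_tpot,
    total_cells,
    volume,
)
from rtkinetics.timecourse import Schedule
from rtkinetics.treatment import EffectModel

LN2 = math.log(2.0)


def growth_strategy():
    """Valid (Td, GF, Tc, gamma) with a nonnegative quiescent loss rate.

    mu_q >= 0 requires Tpot <= Td, i.e. Tc <= Td*log2(1+GF).
    """
    return st.tuples(
        st.floats(15.0, 1000.0),
        st.floats(0.02, 1.0),
        st.floats(0.05, 1.0),  # Tc as a fraction of its admissible maximum
        st.sampled_from([0.0, 0.005, 0.01]),
    ).map(lambda t: (t[0], t[1], max(t[2] * t[0] * math.log2(1.0 + t[1]), 0.5), t[3]))


class TestDerivedRates:
    def test_all_cycling_potential_equals_actual_doubling(self):
        d = derive_rates(GrowthParams(Td=10, GF=1.0, Tc=10))
        assert d.Tpot == pytest.approx(10.0)
        assert d.mu_q == 0.0
        assert d.theta == pytest.approx(1.0)

    def test_closed_form_values(self):
        # direct evaluation of u and Tpot at a typical NSCLC parameter point
        d = derive_rates(GrowthParams(Td=100, GF=0.2, Tc=3))
        assert d.u == pytest.approx(0.3299, rel=1e-3)
        assert d.Tpot == pytest.approx(10.51, rel=1e-3)

    def test_tpot_inversion_matches_published_triple(self):
        # (Td=200, GF=0.15, Tpot=13.9) implies a ~3-day cell cycle
        assert tc_from_tpot(200, 0.15, 13.9) == pytest.approx(3.0, abs=0.05)
        # and the round trip returns the Tpot we started from
        g = GrowthParams.from_tpot(200, 0.15, 13.9)
        assert derive_rates(g).Tpot == pytest.approx(13.9, rel=1e-12)

    def test_invalid_parameter_combinations_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_rates(GrowthParams(Td=100, GF=1.0, Tc=3))  # mu_q ill-defined
        with pytest.raises(InvalidParameterError):
            GrowthParams.from_tpot(Td=20, GF=0.2, Tpot=25)  # Tpot > Td
        with pytest.raises(InvalidParameterError):
            derive_rates(GrowthParams(Td=100, GF=0.2, Tc=3), dt=0)
        with pytest.raises(InvalidParameterError):
            GrowthParams(Td=100, GF=0.2, Tc=3, gamma=0.5)  # gamma above 0.01

    def test_dt_prime_shrinks_monotonically_to_dt(self):
        g = GrowthParams(Td=50, GF=0.2, Tc=3)
        ratios = [derive_rates(g, dt).dt_prime / dt for dt in (4.0, 2.0, 1.0, 0.5, 0.25, 0.1)]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))
        assert all(r > 1.0 for r in ratios)
        assert ratios[-1] == pytest.approx(1.0, abs=2e-3)


class TestInitState:
    def test_split_by_growth_fraction(self):
        s = init_state(1000, GrowthParams(Td=100, GF=0.2, Tc=3))
        assert (s.Np, s.Nq, s.Nrp, s.Nrq) == (200, 800, 0, 0)
        assert s.dying == 0

    def test_split_with_initial_resistance(self):
        s = init_state(1000, GrowthParams(Td=100, GF=0.2, Tc=3), Rini=0.3)
        assert (s.Np, s.Nq) == (pytest.approx(140), pytest.approx(560))
        assert (s.Nrp, s.Nrq) == (pytest.approx(60), pytest.approx(240))

    def test_empty_tumor_rejected(self):
        with pytest.raises(ValueError):
            init_state(0, GrowthParams(Td=100, GF=0.2, Tc=3))


class TestGrowthInvariants:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(growth_strategy())
    def test_exponential_growth_exact_and_gf_stationary(self, params):
        """The dt' discretization makes N(t) = N(0)*2^(t/Td) exact and keeps
        Np/(Np+Nq) pinned at GF when compartments start at GF proportions."""
        Td, GF, Tc, gamma = params
        if GF == 1.0:
            Tc, gamma = Td, 0.0
        try:
            g = GrowthParams(Td=Td, GF=GF, Tc=Tc, gamma=gamma)
            d = derive_rates(g)
        except InvalidParameterError:
            return  # corner cases (theta outside [0,1]) are rejected by design
        s = init_state(1e9, g)
        for _ in range(30):
            s = step(s, g, d)
        assert total_cells(s) / 1e9 == pytest.approx(2.0 ** (30.0 / Td), rel=1e-9)
        assert s.Np / (s.Np + s.Nq) == pytest.approx(GF, rel=1e-9)

    def test_thousand_step_brute_force_iteration(self):
        # long-horizon check against the closed form
        g = GrowthParams(Td=100, GF=0.2, Tc=3)
        d = derive_rates(g)
        s = init_state(1e6, g)
        for _ in range(1000):
            s = step(s, g, d)
        assert total_cells(s) / 1e6 == pytest.approx(2.0 ** 10, rel=1e-8)


class TestDyingPipeline:
    def test_total_kill_clears_in_three_days(self):
        g = GrowthParams(Td=100, GF=0.2, Tc=3)
        d = derive_rates(g)
        s = dataclasses.replace(init_state(1.0, g), Np=0.0, Nq=0.0, Nd1=100.0)
        for _ in range(3):
            s = step(s, g, d, D=1.0)
        assert s.dying == 0.0

    def test_zero_rate_is_absorbing(self):
        g = GrowthParams(Td=100, GF=0.2, Tc=3)
        d = derive_rates(g)
        s = dataclasses.replace(init_state(1.0, g), Np=0.0, Nq=0.0, Nd1=100.0, Nd2=5.0)
        for _ in range(10):
            s = step(s, g, d, D=0.0)
        assert (s.Nd1, s.Nd2, s.Nd3) == (100.0, 5.0, 0.0)

    @pytest.mark.parametrize("D,days", [(0.75, 4.0), (0.5, 6.0), (0.2, 15.0), (1.0, 3.0)])
    def test_mean_time_to_loss(self, D, days):
        assert mean_dying_time(D) == pytest.approx(days)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            mean_dying_time(0.0)

    @pytest.mark.parametrize("D", [0.2, 0.5, 0.75, 1.0])
    def test_monte_carlo_single_cell_passage(self, D):
        """Simulated passage through three geometric stages reproduces the
        3/D mean within three standard errors at 1e5 replicates."""
        rng = np.random.default_rng(12345)
        times = rng.geometric(D, size=(100_000, 3)).sum(axis=1)
        se = times.std(ddof=1) / math.sqrt(len(times))
        assert abs(times.mean() - 3.0 / D) <= max(3 * se, 1e-12)


class TestBookkeeping:
    def test_total_and_volume(self):
        s = PopulationState(t=0, Np=1e8, Nq=1e8, Nrp=1e8, Nrq=1e8, Nd1=1e8, Nd2=1e8, Nd3=1e8)
        assert total_cells(s) == pytest.approx(7e8)
        assert volume(s) == pytest.approx(0.7)
        empty = PopulationState(t=0, Np=0, Nq=0)
        assert total_cells(empty) == 0.0

    def test_cell_count_volume_conversion(self):
        s = init_state(3.2e9, GrowthParams(Td=100, GF=0.2, Tc=3))
        assert volume(s) == pytest.approx(3.2)

    def test_conservation_of_killed_cells(self):
        """Cells removed from live compartments at fractions all enter dying
        stage I, and (losses from stage III) + (still dying) = total killed."""
        g = GrowthParams(Td=100, GF=0.2, Tc=3)
        d = derive_rates(g)
        e = EffectModel(tag="St", Kp=60, Kq=10, D=0.4)
        s = init_state(1e9, g)
        killed_total = 0.0
        lost_total = 0.0
        for t in range(30):
            if t in (0, 2, 4, 7, 9):
                before = s
                s = e.apply(s)
                live_drop = before.live - s.live
                assert s.dying - before.dying == pytest.approx(live_drop, rel=1e-12)
                killed_total += live_drop
            lost_total += e.D * s.Nd3  # stage-III exits during the coming step
            s = step(s, g, d, D=e.D)
        assert lost_total + s.dying == pytest.approx(killed_total, rel=1e-9)


class TestSimulate:
    def test_untreated_growth_is_pure_exponential(self):
        g = GrowthParams(Td=80, GF=0.2, Tc=3)
        e = EffectModel(tag="M", K=0, D=1.0)
        tc = simulate(g, e, Schedule(()), 5.0, (0, 30), [0, 10, 30])
        assert tc.volumes[0] == pytest.approx(5.0)
        assert tc.volumes[2] == pytest.approx(5.0 * 2 ** (30 / 80), rel=1e-9)

    def test_total_kill_reaches_zero_by_day_three(self):
        g = GrowthParams.single_population(100)
        e = EffectModel(tag="M", K=100, D=1.0)
        sched = Schedule(((0, 10.0),))
        tc = simulate(g, e, sched, 2.0, (0, 6), list(range(7)))
        vols = tc.volumes
        assert all(b <= a + 1e-15 for a, b in zip(vols, vols[1:]))
        assert vols[3] == pytest.approx(0.0, abs=1e-12)

    def test_matches_spreadsheet_style_iteration(self):
        """Independent oracle: a literal transcription of the update rules
        (no engine code) must agree with simulate to 1e-6 relative.

        Scenario: hypofractionated minimal-model patient, V0 = 2 cc,
        Td = 250 d, K = 8%, D = 0.999, fractions on days 0, 2, 4, 7, 9.
        """
        Td, K, D, V0 = 250.0, 8.0, 0.999, 2.0
        lam = LN2 / Td
        dtp = (math.exp(lam) - 1.0) / lam
        u = LN2 / (Td * (math.exp(LN2) - 1.0))  # Tc = Td (single population)
        theta = math.exp(LN2) / 2.0  # = 1 at GF=1
        n = V0 * 1e9
        nd1 = nd2 = nd3 = 0.0
        frac_days = {0, 2, 4, 7, 9}
        expected = {}
        for t in range(0, 10):
            expected[t] = (n + nd1 + nd2 + nd3) / 1e9
            if t in frac_days:
                nd1 += K / 100.0 * n
                n *= 1.0 - K / 100.0
            n = n + theta * 2 * u * n * dtp - u * n * dtp
            nd1, nd2, nd3 = (1 - D) * nd1, (1 - D) * nd2 + D * nd1, (1 - D) * nd3 + D * nd2
        g = GrowthParams.single_population(Td)
        e = EffectModel(tag="M", K=K, D=D)
        sched = Schedule.uniform([0, 2, 4, 7, 9], 10.0)
        tc = simulate(g, e, sched, V0, (0, 9), sorted(expected))
        for obs in tc.observations:
            assert obs.volume_cc == pytest.approx(expected[obs.day], rel=1e-6)

    def test_equals_explicit_step_composition(self):
        """simulate's inlined loop is exactly apply_fraction/step composed,
        including recruitment windows and initial resistance."""
        g = GrowthParams.from_tpot(200, 0.15, 13.9, gamma=0.01)
        e = EffectModel(tag="StRec", Kp=29, Kq=1, D=0.56, gamma_rec=0.10, rec_window=(21, None))
        sched = Schedule.uniform([d for d in range(40) if d % 7 < 5], 2.5)
        days = list(range(-7, 61))
        tc = simulate(g, e, sched, 8.5, (-7, 60), days)
        d = derive_rates(g)
        s = init_state(8.5e9 * 2 ** (-7 / 200), g, Rini=e.Rini, t=-7)
        frac = set(sched.days)
        for t in range(-7, 61):
            assert tc.observations[t + 7].volume_cc == total_cells(s) / CELLS_PER_CC
            if t in frac:
                s = e.apply(s)
            s = step(s, g, d, D=e.D, gamma=e.gamma_at(t - sched.start_day, g))

    def test_schedule_outside_span_rejected(self):
        g = GrowthParams.single_population(100)
        e = EffectModel(tag="M", K=10, D=0.5)
        with pytest.raises(ValueError):
            simulate(g, e, Schedule(((12, 10.0),)), 2.0, (0, 9), [0, 9])
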