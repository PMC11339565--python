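"""Unit and property tests for the daily chain-binomial dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from infodemic import (
    InterventionSpec,
    InvalidParametersError,
    ModelParams,
    Trajectory,
    duration,
    effective_rates,
    run,
    step,
)
from conftest import BASE_SEED


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"beta": 1.5},
            {"beta": -0.1},
            {"gamma": 2.0},
            {"n": 0},
            {"i0": 7000},
            {"contacts": -1.0},
            {"max_days": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParametersError):
            ModelParams(**kwargs)

    def test_r0_is_beta_c_over_gamma(self):
        assert ModelParams(beta=0.05, gamma=0.05, contacts=2.0).r0 == pytest.approx(2.0)


class TestEffectiveRates:
    def test_no_intervention_returns_baseline(self):
        p = ModelParams(beta=0.05, gamma=0.05)
        assert effective_rates(p, None, 200) == (0.05, 0.05)

    def test_identity_multipliers_leave_rates_unchanged(self):
        p = ModelParams(beta=0.05, gamma=0.05)
        iv = InterventionSpec(day=10, gamma_mult=1.0, beta_mult=1.0)
        assert effective_rates(p, iv, 10) == (0.05, 0.05)

    def test_before_intervention_day_rates_unchanged(self):
        p = ModelParams(beta=0.05, gamma=0.05)
        iv = InterventionSpec(day=10, gamma_mult=3.0, beta_mult=0.5)
        assert effective_rates(p, iv, 9) == (0.05, 0.05)

    def test_multiplied_rates_clamp_to_unit_interval(self):
        p = ModelParams(beta=0.05, gamma=0.05)
        iv = InterventionSpec(day=10, gamma_mult=30.0, beta_mult=1.0)
        assert effective_rates(p, iv, 10) == (0.05, 1.0)

    @given(
        beta=st.floats(0, 1),
        gamma=st.floats(0, 1),
        km=st.floats(0, 50),
        bm=st.floats(0, 50),
        day=st.integers(0, 500),
        t_day=st.integers(0, 500),
    )
    @settings(max_examples=50, derandomize=True)
    def test_effective_rates_always_probabilities(self, beta, gamma, km, bm, day, t_day):
        p = ModelParams(beta=beta, gamma=gamma)
        iv = InterventionSpec(day=t_day, gamma_mult=km, beta_mult=bm)
        b, g = effective_rates(p, iv, day)
        assert 0.0 <= b <= 1.0 and 0.0 <= g <= 1.0


class TestStep:
    def test_no_believers_nothing_happens(self):
        rng = np.random.default_rng(0)
        assert step(100, 0, 50, 0.5, 0.5, 2.0, 150, rng) == (100, 0, 50)

    def test_forced_full_recovery(self):
        rng = np.random.default_rng(0)
        s, i, r = step(100, 40, 10, 0.0, 1.0, 2.0, 150, rng)
        assert (s, i, r) == (100, 0, 50)

    def test_new_infections_follow_binomial_law(self):
        # S=3, I=1, N=4, c=1, beta=0.5: p_inf = 1 - (1 - 0.5/4) = 0.125.
        rng = np.random.default_rng(42)
        n_draws = 100_000
        counts = np.zeros(4, dtype=int)
        for _ in range(n_draws):
            s, i, r = step(3, 1, 0, 0.5, 0.0, 1.0, 4, rng)
            counts[3 - s] += 1
        expected_p = stats.binom.pmf(np.arange(4), 3, 0.125)
        # empirical mean within 3 SE of 3 * 0.125
        mean = np.sum(np.arange(4) * counts) / n_draws
        se = np.sqrt(3 * 0.125 * 0.875 / n_draws)
        assert abs(mean - 0.375) <= 3 * se
        chi = stats.chisquare(counts, expected_p * n_draws)
        assert chi.pvalue > 1e-4


class TestRun:
    def test_no_initial_believers_gives_duration_zero(self):
        traj = run(ModelParams(i0=0), seed=1)
        assert len(traj.days) == 1 and traj.extinct and duration(traj) == 0

    def test_same_seed_bit_identical(self, small_params):
        a = run(small_params, seed=7)
        b = run(small_params, seed=7)
        assert np.array_equal(a.i, b.i) and np.array_equal(a.s, b.s)
        assert np.array_equal(a.r, b.r) and a.extinct == b.extinct

    def test_trajectory_starts_at_initial_state(self, small_params):
        traj = run(small_params, seed=3)
        assert (traj.s[0], traj.i[0], traj.r[0]) == (495, 5, 0)

    def test_capped_run_is_censored(self):
        p = ModelParams(n=200, beta=0.0, gamma=0.001, contacts=1.0, i0=50, max_days=20)
        traj = run(p, seed=5)
        if not traj.extinct:
            assert len(traj.days) == 21 and duration(traj) == 20 and traj.censored

    @given(
        n=st.integers(2, 300),
        beta=st.floats(0, 1),
        gamma=st.floats(0, 1),
        contacts=st.floats(0, 4),
        frac=st.floats(0, 1),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_and_monotonicity_hold(self, n, beta, gamma, contacts, frac, seed):
        """S+I+R=N every day; S never rises, R never falls."""
        p = ModelParams(
            n=n, beta=beta, gamma=gamma, contacts=contacts,
            i0=int(frac * n), max_days=150,
        )
        traj = run(p, InterventionSpec(day=30, gamma_mult=2.0, beta_mult=0.5), seed=seed)
        traj.validate()  # raises on any violation

    def test_geometric_limit_mean_duration(self):
        """With beta=0 and one believer, duration ~ Geometric(gamma)."""
        gamma = 0.05
        p = ModelParams(n=100, beta=0.0, gamma=gamma, contacts=1.0, i0=1, max_days=5000)
        n_reps = 10_000
        durs = np.fromiter(
            (duration(run(p, seed=BASE_SEED + k)) for k in range(n_reps)),
            dtype=float,
            count=n_reps,
        )
        se = np.sqrt((1 - gamma) / gamma**2 / n_reps)
        assert abs(durs.mean() - 1 / gamma) <= 3 * se

    def test_regime_qualitative_behaviour(self):
        """Low transmission dies out; high transmission peaks higher."""
        final_r, peak_i = {}, {}
        for beta in (0.01, 0.05, 0.1):
            p = ModelParams(n=2000, beta=beta, gamma=0.05, contacts=1.5, i0=5,
                            max_days=1000)
            fr, pk = [], []
            for k in range(30):
                traj = run(p, seed=BASE_SEED + k)
                fr.append(traj.r[-1] / p.n)
                pk.append(traj.i.max() / p.n)
            final_r[beta] = np.mean(fr)
            peak_i[beta] = np.mean(pk)
        assert final_r[0.01] < final_r[0.05]
        assert peak_i[0.1] > peak_i[0.05]


class TestDuration:
    def test_handcrafted_trajectory(self):
        traj = Trajectory(
            days=np.arange(3),
            s=np.array([5, 4, 4]),
            i=np.array([5, 2, 0]),
            r=np.array([0, 4, 6]),
            extinct=True,
        )
        assert duration(traj) == 2

    def test_duration_respects_threshold(self):
        traj = Trajectory(
            days=np.arange(3),
            s=np.array([5, 4, 4]),
            i=np.array([5, 2, 0]),
            r=np.array([0, 4, 6]),
            extinct=True,
            extinction_threshold=2,
        )
        assert duration(traj) == 1

    def test_csv_round_trip(self, small_params, tmp_path):
        traj = run(small_params, seed=11)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "day,S,I,R"
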