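"""Moran simulator: probability rules, drift/selection oracles, chemotherapy."""

import numpy as np
import pandas as pd
import pytest

from colonyphylo import moran
from colonyphylo.moran import (PopulationState, SimulationParams,
                               death_probabilities, division_probabilities,
                               moran_step, run_scenario, simulate_fixation)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"epsilon": 0.0}, {"epsilon": 1.0}, {"w": 1.0}, {"n": 1},
        {"s": -0.1}, {"u": 1.5},
        {"chemo_start_age": 50, "chemo_end_age": 40},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)


class TestDivisionProbabilities:
    def test_single_mutant(self):
        state = PopulationState.initial(3)
        state.drivers[:] = [0, 0, 1]
        p = division_probabilities(state, 0.1)
        assert p.sum() == pytest.approx(1.0)
        assert p[2] == pytest.approx(1.1 / 3.1)

    def test_neutral_uniform(self):
        state = PopulationState.initial(10)
        state.drivers[:] = np.arange(10)
        p = division_probabilities(state, 0.0)
        assert np.allclose(p, 0.1)

    def test_equal_drivers_uniform(self):
        state = PopulationState.initial(5)
        state.drivers[:] = 3
        assert np.allclose(division_probabilities(state, 0.2), 0.2)


class TestDeathProbabilities:
    def test_no_resistant_uniform(self):
        state = PopulationState.initial(8)
        assert np.allclose(death_probabilities(state, True, 0.5), 1 / 8)

    def test_half_resistant_weighted(self):
        state = PopulationState.initial(4)
        state.resistant[:2] = True
        p = death_probabilities(state, True, 0.5)
        # weights (0.5, 0.5, 1, 1) normalized
        assert p[0] == pytest.approx(0.5 / 3.0)
        assert p[3] == pytest.approx(1.0 / 3.0)

    def test_w_one_reduces_to_uniform(self):
        state = PopulationState.initial(6)
        state.resistant[:3] = True
        assert np.allclose(death_probabilities(state, True, 1.0), 1 / 6)

    def test_outside_chemo_uniform(self):
        state = PopulationState.initial(6)
        state.resistant[:3] = True
        assert np.allclose(death_probabilities(state, False, 0.1), 1 / 6)


class TestMoranStep:
    def test_population_conserved_and_clone_delta(self):
        params = SimulationParams(n=10, s=0.0, u=0.0, m=0.0)
        rng = np.random.default_rng(0)
        state = PopulationState.initial(10)
        before = np.bincount(state.clone[:10], minlength=10)
        moran_step(state, params, rng)
        after = np.bincount(state.clone[:10], minlength=10)
        assert after.sum() == 10
        delta = after - before
        assert np.abs(delta).sum() in (0, 2)       # one clone +1, another -1

    def test_certain_driver_mutation(self):
        params = SimulationParams(n=5, s=0.0, u=1.0, m=0.0)
        rng = np.random.default_rng(1)
        state = PopulationState.initial(5)
        for _ in range(20):
            moran_step(state, params, rng)
        assert state.drivers[:5].max() >= 1
        # every division added a driver to the daughter
        assert state.drivers[:5].sum() >= 1

    def test_deterministic_under_seed(self):
        params = SimulationParams(n=50, s=0.1, u=1e-3, seed=9)
        t1 = run_scenario("drivers", params, replicates=2, record_every=10.0)
        t2 = run_scenario("drivers", params, replicates=2, record_every=10.0)
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestBottleneck:
    def test_minimum_size_at_chemo_end(self):
        params = SimulationParams(n=1000, epsilon=0.1, beta=1.0,
                                  chemo_start_age=5.0, chemo_end_age=10.0,
                                  t_end=12.0, u=0.0, m=0.0, seed=3)
        rng = np.random.default_rng(3)
        state = PopulationState.initial(1000)
        moran._advance(state, params, "chemo", 10.0, rng)
        assert state.size == 100
        moran._advance(state, params, "chemo", 11.0, rng)
        assert state.size == 1000

    def test_instant_recovery_beta_zero(self):
        params = SimulationParams(n=200, epsilon=0.3, beta=0.0,
                                  chemo_start_age=2.0, chemo_end_age=4.0,
                                  t_end=6.0, seed=4)
        rng = np.random.default_rng(4)
        state = PopulationState.initial(200)
        # restoring 200 - 60 = 140 cells takes 140 birth-only steps = 0.7 y
        moran._advance(state, params, "chemo", 4.0 + 140 / 200 + 0.05, rng)
        assert state.size == 200

    def test_post_recovery_constant(self):
        params = SimulationParams(n=300, epsilon=0.5, beta=0.5,
                                  chemo_start_age=1.0, chemo_end_age=2.0,
                                  t_end=5.0, seed=5)
        traj = run_scenario("chemo", params, replicates=1, record_every=1.0)
        late = traj.data[traj.data["time"] >= 3.0]
        assert (late["population_size"] == 300).all()


class TestFixationOracles:
    def test_neutral_fixation_equals_initial_frequency(self):
        """Classical Moran drift: P(fix) = initial frequency (n=10, 0.3)."""
        rng = np.random.default_rng(11)
        reps = 4000
        fixed = sum(simulate_fixation(10, 3, 0.0, rng) for _ in range(reps))
        phat = fixed / reps
        se = np.sqrt(0.3 * 0.7 / reps)
        assert abs(phat - 0.3) <= 3 * se

    def test_selective_fixation_closed_form(self):
        """Birth-death Moran: rho = (1 - 1/r) / (1 - 1/r^n), r = 1 + s."""
        rng = np.random.default_rng(12)
        n, s, reps = 12, 0.4, 4000
        r = 1 + s
        rho = (1 - 1 / r) / (1 - 1 / r ** n)
        fixed = sum(simulate_fixation(n, 1, s, rng) for _ in range(reps))
        phat = fixed / reps
        se = np.sqrt(rho * (1 - rho) / reps)
        assert abs(phat - rho) <= 3.5 * se

    def test_full_scenario_neutral_drift(self):
        """The scenario runner's neutral arm preserves the drift property:
        a 30%-frequency label fixes with probability ~0.3."""
        fixed = 0
        reps = 300
        for rng in moran.replicate_seeds(77, reps):
            state = PopulationState.initial(10)
            state.clone[:10] = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
            params = SimulationParams(n=10, t_end=1.0, seed=0)
            while True:
                moran._advance(state, params, "neutral",
                               state.age + 50.0, rng)
                c = state.clone[:state.size]
                if (c == 1).all():
                    fixed += 1
                    break
                if (c == 0).all():
                    break
        phat = fixed / reps
        se = np.sqrt(0.3 * 0.7 / reps)
        assert abs(phat - 0.3) <= 3.5 * se


class TestScenarios:
    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            run_scenario("magic", SimulationParams(n=10), 1)

    def test_chemo_reduces_shannon_vs_neutral(self):
        """Chemotherapy bottleneck causes an immediate diversity loss
        relative to the neutral arm at matched seeds."""
        params = SimulationParams(n=500, u=0.0, m=0.0, epsilon=0.2,
                                  chemo_start_age=5.0, chemo_end_age=8.0,
                                  beta=1.0, t_end=10.0, seed=101)
        neutral = run_scenario("neutral", params, replicates=10,
                               record_every=2.0)
        chemo = run_scenario("chemo", params, replicates=10, record_every=2.0)
        assert chemo.mean_at(8.0) < neutral.mean_at(8.0)

    def test_subsampled_trajectory(self):
        params = SimulationParams(n=400, t_end=4.0, seed=6)
        traj = run_scenario("neutral", params, replicates=2,
                            record_every=2.0, subsample_size=50)
        full = run_scenario("neutral", params, replicates=2, record_every=2.0)
        assert (traj.data["shannon"] <= full.data["shannon"] + 1e-9).all()

    def test_shannon_non_increasing_in_expectation(self):
        """No new clone labels arise, so neutral diversity can only decay."""
        params = SimulationParams(n=200, t_end=20.0, seed=13)
        traj = run_scenario("neutral", params, replicates=20, record_every=5.0)
        means = traj.data.groupby("time")["shannon"].mean()
        assert (np.diff(means.to_numpy()) <= 1e-9).all()


def test_fast_path_matches_reference_distribution():
    """Rejection-sampled division choices reproduce the explicit
    fitness-proportionate probabilities (chi-squared on one step)."""
    params = SimulationParams(n=4, s=1.0, u=0.0, m=0.0)
    state = PopulationState.initial(4)
    state.drivers[:] = [0, 0, 0, 3]      # fitness 1,1,1,4
    probs = division_probabilities(state, params.s)
    counts = np.zeros(4)
    for rng in moran.replicate_seeds(5, 4000):
        st = PopulationState.initial(4)
        st.drivers[:4] = state.drivers[:4]
        st.clone[:4] = np.arange(4)
        moran._advance(st, params, "drivers", 1.0 / 4, rng)
        # the daughter carries the parent's clone label
        new = np.bincount(st.clone[:4], minlength=4)
        gained = np.flatnonzero(new > 1)
        if len(gained):
            counts[gained[0]] += 1
    freq = counts / counts.sum()
    assert np.abs(freq - probs).max() < 0.035
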