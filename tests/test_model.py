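import math

import numpy as np
import pandas as pd
import pytest

from rlwm.errors import ConfigError, DataError
from rlwm.model import (
    AgentParams,
    init_block_state,
    learning_policy,
    rl_update,
    session_loglik,
    simulate_agent,
    test_policy as phase_test_policy,
    wm_decay,
    wm_update,
)
from rlwm.task import TaskConfig, build_session

from _reference import reference_session_loglik


def make_params(**kw):
    base = dict(
        alpha_pos=0.1,
        alpha_neg=0.05,
        beta_learn=8.0,
        beta_test=4.0,
        epsilon=0.05,
        phi=0.2,
        omega3=0.7,
        omega6=0.4,
    )
    base.update(kw)
    return AgentParams(**base)


class TestAgentParams:
    def test_nu_is_rate_ratio_and_may_exceed_one(self):
        p = make_params(alpha_pos=0.2, alpha_neg=0.3)
        assert p.nu == pytest.approx(1.5)

    def test_zero_positive_rate_rejected(self):
        with pytest.raises(ConfigError, match="alpha_pos"):
            make_params(alpha_pos=0.0)

    @pytest.mark.parametrize("field,value", [("phi", 1.5), ("epsilon", -0.1), ("beta_test", -1.0)])
    def test_out_of_range_rejected(self, field, value):
        with pytest.raises(ConfigError, match=field):
            make_params(**{field: value})


class TestStateUpdates:
    def test_initial_state_uniform(self):
        st = init_block_state(6, 3)
        assert st.Q.shape == (6, 3) and st.W.shape == (6, 3)
        assert np.all(st.Q == pytest.approx(1 / 3)) and np.all(st.W == pytest.approx(1 / 3))
        assert np.all(init_block_state(2, 1).Q == 1.0)
        with pytest.raises(ConfigError):
            init_block_state(3, 0)

    def test_rl_update_hand_arithmetic(self):
        st = init_block_state(3, 3)
        rl_update(st, 0, 0, 1.0, alpha_pos=0.3, alpha_neg=0.1)
        assert st.Q[0, 0] == pytest.approx(1 / 3 + 0.3 * (1 - 1 / 3))
        st = init_block_state(3, 3)
        rl_update(st, 0, 0, 1.0, alpha_pos=0.0, alpha_neg=0.1)
        assert st.Q[0, 0] == pytest.approx(1 / 3)
        st = init_block_state(3, 3)
        rl_update(st, 0, 0, 0.0, alpha_pos=0.3, alpha_neg=0.1)
        assert st.Q[0, 0] == pytest.approx(0.3)
        # other entries untouched
        assert np.all(st.Q[1:] == pytest.approx(1 / 3))

    def test_wm_update_one_shot_positive(self):
        for nu in (0.0, 0.5, 2.0):
            st = init_block_state(3, 3)
            wm_update(st, 0, 0, 1.0, nu=nu)
            assert st.W[0, 0] == 1.0

    def test_wm_update_negative_scaled_by_nu(self):
        st = init_block_state(3, 3)
        wm_update(st, 0, 0, 0.0, nu=1.0)
        assert st.W[0, 0] == pytest.approx(0.0)
        st = init_block_state(3, 3)
        wm_update(st, 0, 0, 0.0, nu=0.0)
        assert st.W[0, 0] == pytest.approx(1 / 3)

    def test_wm_update_nu_above_one_overshoots_below_zero(self):
        st = init_block_state(3, 3)
        wm_update(st, 0, 0, 0.0, nu=1.5)
        assert st.W[0, 0] == pytest.approx(1 / 3 - 1.5 / 3)

    def test_decay_retention_fraction(self):
        """One decay step at phi = 0.174 keeps ~83% of the above-baseline
        association strength."""
        st = init_block_state(3, 3)
        st.W[1, 1] = 1.0
        wm_decay(st, 0.174, observed=(0, 0))
        assert st.W[1, 1] == pytest.approx(0.8840, abs=1e-4)
        retained = (st.W[1, 1] - st.w0) / (1.0 - st.w0)
        assert retained == pytest.approx(0.826, abs=1e-3)

    def test_decay_edge_rates(self):
        st = init_block_state(3, 3)
        st.W[:] = 0.9
        before = st.W.copy()
        wm_decay(st, 0.0, observed=(0, 0))
        assert np.array_equal(st.W, before)
        wm_decay(st, 1.0, observed=(0, 0))
        assert st.W[0, 0] == pytest.approx(0.9)  # observed pair untouched
        mask = np.ones_like(st.W, dtype=bool)
        mask[0, 0] = False
        assert np.all(st.W[mask] == pytest.approx(st.w0))

    def test_decay_leaves_q_untouched(self):
        st = init_block_state(3, 3)
        st.Q[:] = 0.8
        wm_decay(st, 0.5, observed=(0, 0))
        assert np.all(st.Q == 0.8)

    def test_decay_monotone_toward_baseline(self):
        rng = np.random.default_rng(0)
        st = init_block_state(6, 3)
        st.W[:] = rng.uniform(-0.5, 1.5, st.W.shape)
        before = np.abs(st.W - st.w0)
        wm_decay(st, 0.3, observed=(2, 1))
        after = np.abs(st.W - st.w0)
        assert np.all(after <= before + 1e-12)


class TestPolicies:
    def test_flat_softmax_uniform(self):
        st = init_block_state(3, 3)
        p = learning_policy(st, 0, make_params(beta_learn=0.0, epsilon=0.0))
        assert np.allclose(p, 1 / 3)

    def test_pure_lapse_uniform(self):
        st = init_block_state(3, 3)
        st.Q[0] = [0.9, 0.05, 0.05]
        st.W[0] = [0.9, 0.05, 0.05]
        p = learning_policy(st, 0, make_params(epsilon=1.0))
        assert np.allclose(p, 1 / 3)

    def test_learning_policy_scalar_oracle(self):
        st = init_block_state(3, 3)
        st.Q[0] = [0.5, 1 / 3, 1 / 3]
        st.W[0] = [0.5, 1 / 3, 1 / 3]
        p = learning_policy(st, 0, make_params(beta_learn=2.0, epsilon=0.0, omega3=0.3))
        expected = math.exp(1.0) / (math.exp(1.0) + 2 * math.exp(2 / 3))
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_test_policy_scalar_oracle(self):
        q = np.array([[1.0, 1 / 3, 1 / 3]])
        p = phase_test_policy(q, 0, make_params(beta_test=3.0, epsilon=0.0))
        expected = math.exp(3.0) / (math.exp(3.0) + 2 * math.exp(1.0))
        assert p[0] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(phase_test_policy(q, 0, make_params(beta_test=0.0)), 1 / 3)
        assert np.allclose(phase_test_policy(q, 0, make_params(epsilon=1.0)), 1 / 3)

    def test_unknown_set_size_rejected(self):
        st = init_block_state(4, 3)
        with pytest.raises(ConfigError):
            learning_policy(st, 0, make_params(), set_size=4)

    def test_normalization_and_lapse_floor_sweep(self):
        """Policies are probability vectors bounded below by eps/nA, for any
        state, including WM weights pushed outside [0, 1] by nu > 1."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            st = init_block_state(3, 3)
            st.Q[:] = rng.uniform(0, 1, st.Q.shape)
            st.W[:] = rng.uniform(-0.5, 1.5, st.W.shape)
            params = make_params(
                beta_learn=rng.uniform(0, 30),
                beta_test=rng.uniform(0, 30),
                epsilon=rng.uniform(0, 1),
                omega3=rng.uniform(0, 1),
            )
            p = learning_policy(st, 0, params)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= params.epsilon / 3 - 1e-12)
            pt = phase_test_policy(st.Q, 1, params)
            assert abs(pt.sum() - 1.0) < 1e-12
            assert np.all(pt >= params.epsilon / 3 - 1e-12)


class TestSimulation:
    def test_same_seed_identical(self, default_plan):
        a = simulate_agent(default_plan, make_params(), seed=9)
        b = simulate_agent(default_plan, make_params(), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_full_lapse_agent_at_chance(self, default_plan):
        df = simulate_agent(default_plan, make_params(epsilon=1.0), seed=3)
        acc = df[df.phase == "learn"].reward.mean()
        n = (df.phase == "learn").sum()
        assert abs(acc - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / n)

    def test_perfect_wm_retains_after_first_reward(self, default_plan):
        """With one-shot WM (alpha+ = alpha- = 1, omega3 = 1, phi = 0,
        eps = 0, large beta) every set-size-3 stimulus is answered correctly
        on every presentation after its first rewarded one, and error
        elimination guarantees success from the third presentation onward."""
        params = make_params(
            alpha_pos=1.0,
            alpha_neg=1.0,
            beta_learn=200.0,
            epsilon=0.0,
            phi=0.0,
            omega3=1.0,
        )
        df = simulate_agent(default_plan, params, seed=4)
        learn3 = df[(df.phase == "learn") & (df.set_size == 3)]
        for _, grp in learn3.groupby(["block", "stimulus"]):
            rewards = grp.sort_values("iteration").reward.to_numpy()
            first_hit = np.argmax(rewards == 1)
            assert np.all(rewards[first_hit:] == 1)
        assert learn3[learn3.iteration >= 3].reward.mean() == pytest.approx(1.0)

    def test_bounded_values_when_nu_below_one(self, default_plan):
        """With nu <= 1 and binary rewards, simulated behavior never requires
        Q or W outside [0, 1]: check via the likelihood of extreme agents."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            params = make_params(
                alpha_pos=rng.uniform(0.3, 1.0),
                alpha_neg=rng.uniform(0.0, 0.29),
                phi=rng.uniform(0, 1),
                omega3=rng.uniform(0, 1),
                omega6=rng.uniform(0, 1),
            )
            assert params.nu <= 1.0
            df = simulate_agent(default_plan, params, seed=int(rng.integers(2**31)))
            ll, _ = session_loglik(df, params)
            assert np.isfinite(ll)

    def test_miss_rate_produces_missed_trials(self):
        plan = build_session(TaskConfig(miss_rate=0.2), seed=1)
        df = simulate_agent(plan, make_params(), seed=2)
        frac = df.missed.mean()
        assert 0.1 < frac < 0.3
        assert df.loc[df.missed, "action"].isna().all()
        assert df.loc[df.missed, "reward"].isna().all()


class TestSessionLoglik:
    def test_full_lapse_contributes_log_third(self, default_plan):
        params = make_params(epsilon=1.0)
        df = simulate_agent(default_plan, params, seed=6)
        total, pointwise = session_loglik(df, params)
        n = (~df.missed).sum()
        assert total == pytest.approx(n * math.log(1 / 3), rel=1e-12)
        assert sum(pointwise.values()) == pytest.approx(total)

    def test_pointwise_units_are_blocks(self, default_plan):
        df = simulate_agent(default_plan, make_params(), seed=6, participant="p")
        _, pointwise = session_loglik(df, make_params())
        assert len(pointwise) == 10
        assert all(v < 0 for v in pointwise.values())  # exp(ll) in (0, 1]

    def test_missed_trials_contribute_nothing(self, default_plan):
        plan = build_session(TaskConfig(miss_rate=0.15), seed=8)
        params = make_params()
        df = simulate_agent(plan, params, seed=9)
        total_with, _ = session_loglik(df, params)
        total_without, _ = session_loglik(df[~df.missed], params)
        assert total_with == pytest.approx(total_without, rel=1e-12)

    def test_matches_scalar_reference_on_random_sessions(self):
        """Vectorized likelihood equals an independent straight-line scalar
        implementation to 1e-10 on randomized small sessions."""
        rng = np.random.default_rng(12)
        cfg = TaskConfig(
            n_small_blocks=1, n_large_blocks=1, reps_per_stimulus=4,
            test_reps_per_stimulus=2, miss_rate=0.1,
        )
        for k in range(25):
            plan = build_session(cfg, seed=k)
            params = make_params(
                alpha_pos=rng.uniform(0.05, 0.9),
                alpha_neg=rng.uniform(0.0, 0.9),
                beta_learn=rng.uniform(0, 20),
                beta_test=rng.uniform(0, 20),
                epsilon=rng.uniform(0.01, 0.5),
                phi=rng.uniform(0, 1),
                omega3=rng.uniform(0, 1),
                omega6=rng.uniform(0, 1),
            )
            df = simulate_agent(plan, params, seed=1000 + k)
            total, pointwise = session_loglik(df, params)
            ref = reference_session_loglik(
                df.to_dict("records"),
                {f: getattr(params, f) for f in (
                    "alpha_pos", "alpha_neg", "beta_learn", "beta_test",
                    "epsilon", "phi", "omega3", "omega6")},
            )
            assert total == pytest.approx(sum(ref.values()), abs=1e-10)
            for (_, b), v in pointwise.items():
                assert v == pytest.approx(ref[b], abs=1e-10)

    def test_test_phase_invariant_to_wm_parameters(self, default_plan):
        """Test-phase likelihood depends only on the final Q trajectory, so
        perturbing phi, omega3, omega6, or beta_learn leaves it unchanged."""
        base = make_params()
        df = simulate_agent(default_plan, base, seed=13)
        learn_only = df[df.phase == "learn"]

        def test_part(params):
            total, _ = session_loglik(df, params)
            learn_total, _ = session_loglik(learn_only, params)
            return total - learn_total

        ref = test_part(base)
        for change in (
            {"phi": 0.9}, {"omega3": 0.1}, {"omega6": 0.9}, {"beta_learn": 30.0}
        ):
            assert test_part(base.replace(**change)) == pytest.approx(ref, rel=1e-12)

    def test_unlearned_test_stimulus_rejected(self, default_plan):
        df = simulate_agent(default_plan, make_params(), seed=14)
        bad = df.copy()
        bad.loc[bad.index[-1], "stimulus"] = 999
        with pytest.raises(DataError):
            session_loglik(bad, make_params())

    def test_simulator_matches_policy_probabilities(self):
        """Across many simulated agents the chosen-action indicators minus
        the model's own policy probabilities (teacher-forced per agent) form
        a mean-zero sum for every action: the simulator samples from exactly
        the distribution the likelihood scores."""
        from _reference import reference_trial_probs

        cfg = TaskConfig(n_small_blocks=1, n_large_blocks=1, reps_per_stimulus=4,
                         test_reps_per_stimulus=1)
        plan = build_session(cfg, seed=3)
        params = make_params(beta_learn=5.0)
        pdict = {f: getattr(params, f) for f in (
            "alpha_pos", "alpha_neg", "beta_learn", "beta_test",
            "epsilon", "phi", "omega3", "omega6")}
        resid = np.zeros(3)
        var = np.zeros(3)
        for k in range(150):
            df = simulate_agent(plan, params, seed=k)
            probs = reference_trial_probs(df.to_dict("records"), pdict)
            for rec, p in zip(df.itertuples(), probs):
                if p is None:
                    continue
                a = int(rec.action) - 1
                for j in range(3):
                    resid[j] += (1.0 if j == a else 0.0) - p[j]
                    var[j] += p[j] * (1 - p[j])
        assert np.all(np.abs(resid) < 3 * np.sqrt(var))
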