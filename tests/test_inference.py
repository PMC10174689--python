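import math

import numpy as np
import pandas as pd
import pytest

import rlwm.inference as inf
from rlwm.cohort import CohortSpec, generate_cohort
from rlwm.errors import ConfigError, DataError
from rlwm.inference import (
    McmcConfig,
    PosteriorFit,
    PriorSpec,
    check_diagnostics,
    compare_variants,
    compute_waic,
    fit,
    group_contrast,
    counterfactual_swap,
)
from rlwm.model import AgentParams, simulate_agent
from rlwm.task import TaskConfig, build_session


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = CohortSpec(
        n_young=5, n_older=5, n_missing_brain_young=0, n_missing_brain_older=0
    )
    return generate_cohort(spec, seed=21)


@pytest.fixture(scope="module")
def tiny_fit(tiny_cohort):
    return fit(
        tiny_cohort.behavior,
        variant="two_group",
        mcmc=McmcConfig(n_chains=2, n_warmup=150, n_kept=250, seed=5),
    )


@pytest.fixture(scope="module")
def tiny_flat_fit(tiny_cohort):
    return fit(
        tiny_cohort.behavior,
        variant="flat",
        mcmc=McmcConfig(n_chains=2, n_warmup=150, n_kept=250, seed=6),
    )


def synthetic_fit(rng, n_chains=2, n_draws=400, P=3, good=True):
    """A hand-built PosteriorFit with well-mixed (or deliberately broken)
    draws, for exercising diagnostics without running the sampler."""
    theta = rng.uniform(0.2, 0.4, size=(n_chains, n_draws, P, 7))
    theta += rng.normal(0, 0.01, size=theta.shape)
    if not good:
        theta[0] += 0.5  # chain-level offset destroys Rhat
    return PosteriorFit(
        variant="two_group",
        participants=[f"p{i}" for i in range(P)],
        participant_group=["young", "older", "older"][:P],
        group_names=["young", "older"],
        theta=theta,
        beta_learn=rng.uniform(9, 10, size=(n_chains, n_draws, 2)),
        hyper_a=rng.uniform(1.9, 2.1, size=(n_chains, n_draws, 2, 6)),
        hyper_b=rng.uniform(3.9, 4.1, size=(n_chains, n_draws, 2, 6)),
        bt_mu=rng.uniform(7.9, 8.1, size=(n_chains, n_draws, 2)),
        pointwise=rng.normal(-40, 1, size=(n_chains, n_draws, P, 10)).astype(
            np.float32
        ),
        mcmc=McmcConfig(n_chains=n_chains, n_warmup=1, n_kept=n_draws),
        priors=PriorSpec(),
        data_fingerprint="synthetic",
    )


class TestWaic:
    def test_toy_matrix_matches_hand_formula(self):
        """2 units x 3 draws, evaluated against the direct formula."""
        ll = np.array([[-1.0, -2.0], [-1.5, -2.5], [-0.5, -1.0]])
        lppd = sum(
            math.log(np.mean(np.exp(ll[:, i]))) for i in range(2)
        )
        p_waic = sum(np.var(ll[:, i], ddof=1) for i in range(2))
        expected = -2.0 * (lppd - p_waic)
        out = compute_waic(ll)
        assert out["waic"] == pytest.approx(expected, abs=1e-9)
        assert out["p_waic"] == pytest.approx(p_waic, abs=1e-9)
        assert out["p_waic"] >= 0.0

    def test_identical_matrices_tie(self, tiny_fit):
        w1 = compute_waic(tiny_fit)
        w2 = compute_waic(tiny_fit)
        assert w1["waic"] == w2["waic"]

    def test_unit_bookkeeping(self, tiny_fit):
        # 10 participants x 10 blocks, test trials pooled into their block
        assert compute_waic(tiny_fit)["n_units"] == 100

    def test_bad_shape_rejected(self):
        with pytest.raises(DataError):
            compute_waic(np.zeros(5))


class TestDiagnostics:
    def test_well_mixed_draws_pass(self):
        rep = check_diagnostics(synthetic_fit(np.random.default_rng(0)))
        assert rep.rhat_ok and rep.ess_ok and rep.passed
        assert rep.n_divergent == 0 and rep.bfmi_min is None

    def test_split_chains_fail_rhat(self):
        rep = check_diagnostics(synthetic_fit(np.random.default_rng(0), good=False))
        assert not rep.rhat_ok and not rep.passed

    def test_single_divergence_fails_with_count(self):
        f = synthetic_fit(np.random.default_rng(1))
        div = np.zeros((2, 400), dtype=int)
        div[1, 37] = 1
        f.sample_stats = {"diverging": div}
        rep = check_diagnostics(f)
        assert rep.n_divergent == 1 and not rep.divergence_ok

    def test_low_bfmi_fails(self):
        f = synthetic_fit(np.random.default_rng(2))
        # an energy series with tiny step-to-step changes but huge marginal
        # variance gives BFMI << 0.2
        energy = np.cumsum(np.random.default_rng(3).normal(0, 1, (2, 400)), axis=1)
        f.sample_stats = {"energy": energy}
        rep = check_diagnostics(f)
        assert rep.bfmi_min is not None and rep.bfmi_min < 0.2 and not rep.bfmi_ok

    def test_ess_boundary_inclusive(self):
        f = synthetic_fit(np.random.default_rng(4))
        rep = check_diagnostics(f)
        # re-check with the threshold set exactly at the measured minimum:
        # the bound is inclusive
        rep2 = check_diagnostics(f, ess_min=rep.ess_min)
        assert rep2.ess_ok


class TestFit:
    def test_flat_variant_has_no_hyperdraws(self, tiny_flat_fit):
        assert tiny_flat_fit.hyper_a is None
        assert tiny_flat_fit.bt_mu is None

    def test_single_hierarchy_pools_groups(self, tiny_cohort):
        f = fit(
            tiny_cohort.behavior,
            variant="single_hierarchy",
            mcmc=McmcConfig(n_chains=1, n_warmup=60, n_kept=60, seed=4),
        )
        # one population of hyperparameters, but beta_L still per group
        assert f.hyper_a.shape[2] == 1
        assert f.beta_learn.shape[2] == 2

    def test_two_group_requires_two_groups(self, tiny_cohort):
        young_only = tiny_cohort.behavior[tiny_cohort.behavior.group == "young"]
        with pytest.raises(DataError):
            fit(young_only, variant="two_group", mcmc=McmcConfig(n_chains=1))

    def test_missing_test_phase_rejected(self, tiny_cohort):
        learn_only = tiny_cohort.behavior[tiny_cohort.behavior.phase == "learn"]
        with pytest.raises(DataError):
            fit(learn_only, mcmc=McmcConfig(n_chains=1))

    def test_unknown_variant_rejected(self, tiny_cohort):
        with pytest.raises(ConfigError):
            fit(tiny_cohort.behavior, variant="triple")

    def test_decay_ordering_recovered(self):
        """Two simulated agents differing only in decay (0.05 vs 0.9) keep
        their posterior-mean ordering."""
        plan = build_session(TaskConfig(), seed=31)
        base = dict(
            alpha_pos=0.08, alpha_neg=0.05, beta_learn=12.0, beta_test=5.0,
            epsilon=0.03, omega3=0.8, omega6=0.5,
        )
        frames = []
        for pid, phi in [("slow", 0.05), ("fast", 0.9)]:
            frames.append(
                simulate_agent(
                    plan, AgentParams(phi=phi, **base), seed=17,
                    participant=pid, group="all",
                )
            )
        data = pd.concat(frames, ignore_index=True)
        f = fit(
            data,
            variant="flat",
            mcmc=McmcConfig(n_chains=1, n_warmup=200, n_kept=300, seed=9),
        )
        pm = f.posterior_mean_params()
        assert pm.loc["fast", "phi"] > pm.loc["slow", "phi"]

    def test_reproducible_given_seed(self, tiny_cohort):
        cfg = McmcConfig(n_chains=1, n_warmup=40, n_kept=40, seed=11)
        f1 = fit(tiny_cohort.behavior, variant="two_group", mcmc=cfg)
        f2 = fit(tiny_cohort.behavior, variant="two_group", mcmc=cfg)
        assert np.array_equal(f1.theta, f2.theta)
        assert np.array_equal(f1.beta_learn, f2.beta_learn)


class TestCompareVariants:
    def test_single_fit_table(self, tiny_fit):
        table = compare_variants([tiny_fit])
        assert len(table) == 1 and table.delta_waic.iloc[0] == 0.0

    def test_order_invariance(self, tiny_fit, tiny_flat_fit):
        t1 = compare_variants([tiny_fit, tiny_flat_fit])
        t2 = compare_variants([tiny_flat_fit, tiny_fit])
        pd.testing.assert_frame_equal(t1, t2)

    def test_mismatched_data_rejected(self, tiny_fit):
        other = synthetic_fit(np.random.default_rng(5))
        with pytest.raises(DataError):
            compare_variants([tiny_fit, other])


class TestGroupContrast:
    def test_interval_brackets_mean(self, tiny_fit):
        out = group_contrast(tiny_fit, "phi")
        lo, hi = out["cri"]
        assert lo <= out["delta_mean"] <= hi

    def test_null_difference_covers_zero(self):
        """When the group hyperparameters are forced identical the contrast
        CrI contains zero."""
        f = synthetic_fit(np.random.default_rng(6))
        out = group_contrast(f, "phi")
        lo, hi = out["cri"]
        assert lo <= 0.0 <= hi

    def test_unknown_parameter_rejected(self, tiny_fit):
        with pytest.raises(KeyError):
            group_contrast(tiny_fit, "gamma")

    def test_beta_learn_contrast_uses_group_draws(self, tiny_fit):
        out = group_contrast(tiny_fit, "beta_learn")
        assert np.isfinite(out["delta_mean"])


class TestCounterfactualSwap:
    def test_noop_swap_matches_posterior_predictive(self, tiny_cohort, tiny_fit):
        sim = counterfactual_swap(
            tiny_fit, "older", "older", "phi", tiny_cohort.plans, seed=3
        )
        # trial counts match the plans
        pids = set(sim.participant)
        expected = sum(
            len(tiny_cohort.plans[p].test_sequence)
            + sum(len(s) for s in tiny_cohort.plans[p].learning_sequence)
            for p in pids
        )
        assert len(sim) == expected
        # donor == recipient leaves the parameter at (approximately) the
        # group's own posterior mean: accuracy within Monte-Carlo error of a
        # straight posterior-mean simulation
        base = counterfactual_swap(
            tiny_fit, "older", "older", "omega6", tiny_cohort.plans, seed=3
        )
        a = sim[sim.phase == "learn"].reward.mean()
        b = base[base.phase == "learn"].reward.mean()
        assert abs(a - b) < 0.08

    def test_swap_direction_improves_older_learning(self, tiny_cohort):
        """Giving older adults a much slower decay rate raises their
        set-size-6 learning accuracy (posterior constructed with widely
        separated group-level decay means so the direction is unambiguous)."""
        rng = np.random.default_rng(8)
        pids = sorted(tiny_cohort.participants.participant)
        groups = [
            tiny_cohort.participants.set_index("participant").loc[p, "group"]
            for p in pids
        ]
        f = synthetic_fit(rng, P=len(pids))
        f.participants = pids
        f.participant_group = groups
        # participant-level parameters: sensible values, slow WM for young
        theta = np.zeros((2, 10, len(pids), 7))
        theta[..., 0] = 0.08  # alpha_pos
        theta[..., 1] = 0.05
        theta[..., 2] = 5.0  # beta_test
        theta[..., 3] = 0.03  # epsilon
        theta[..., 5] = 0.8
        theta[..., 6] = 0.5
        for i, g in enumerate(groups):
            theta[..., i, 4] = 0.12 if g == "young" else 0.5
        f.theta = theta
        f.beta_learn = np.full((2, 10, 2), 14.0)
        # group-level phi means: young (1+2)/(2+2+20)=0.125, older 0.5
        f.hyper_a = np.zeros((2, 10, 2, 6))
        f.hyper_b = np.zeros((2, 10, 2, 6))
        f.hyper_a[..., 0, :] = 2.0
        f.hyper_b[..., 0, :] = 20.0
        f.hyper_a[..., 1, :] = 8.0
        f.hyper_b[..., 1, :] = 8.0
        f.bt_mu = np.full((2, 10, 2), 5.0)
        swapped = counterfactual_swap(f, "young", "older", "phi", tiny_cohort.plans, seed=4)
        own = counterfactual_swap(f, "older", "older", "phi", tiny_cohort.plans, seed=4)
        acc_swap = swapped[(swapped.phase == "learn") & (swapped.set_size == 6)].reward.mean()
        acc_own = own[(own.phase == "learn") & (own.set_size == 6)].reward.mean()
        assert acc_swap > acc_own

    def test_unknown_parameter_rejected(self, tiny_cohort, tiny_fit):
        with pytest.raises(KeyError):
            counterfactual_swap(
                tiny_fit, "young", "older", "gamma", tiny_cohort.plans, seed=1
            )


class TestPriorPredictive:
    def test_prior_spans_chance_to_ceiling(self):
        """Parameter sets drawn from the hierarchical prior generate learning
        accuracies covering the range from chance to near-perfect, without
        collapsing onto either extreme."""
        priors = PriorSpec()
        rng = np.random.default_rng(14)
        plan = build_session(
            TaskConfig(n_small_blocks=2, n_large_blocks=1, test_reps_per_stimulus=1),
            seed=2,
        )
        accs = []
        for k in range(40):
            hyper = {
                "a": rng.gamma(priors.unit_hyper_shape, 1 / priors.unit_hyper_rate, 6),
                "b": rng.gamma(priors.unit_hyper_shape, 1 / priors.unit_hyper_rate, 6),
            }
            unit = {
                name: rng.beta(1 + hyper["a"][i], 1 + hyper["b"][i])
                for i, name in enumerate(
                    ["alpha_pos", "alpha_neg", "epsilon", "phi", "omega3", "omega6"]
                )
            }
            if unit["alpha_pos"] == 0:
                continue
            mu = rng.lognormal(priors.bt_mu_logmean, priors.bt_mu_logsd)
            params = AgentParams(
                beta_learn=rng.gamma(priors.bl_shape, 1 / priors.bl_rate),
                beta_test=rng.gamma(priors.bt_shape, mu / priors.bt_shape),
                **unit,
            )
            df = simulate_agent(plan, params, seed=int(rng.integers(2**31)))
            accs.append(df[df.phase == "learn"].reward.mean())
        accs = np.array(accs)
        assert accs.min() < 0.45
        assert accs.max() > 0.75
        assert not np.all(np.abs(accs - 1 / 3) < 0.05)
        assert not np.all(accs > 0.9)
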