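"""Hierarchical Bayesian estimation of the RL-WM model.

Three hierarchical structures are supported:

* ``flat`` — independent priors per participant (no hyperparameters),
* ``single_hierarchy`` — one population distribution over all participants,
* ``two_group`` — separate population distributions per age group.

In every variant the learning-phase inverse temperature beta_L is a single
value shared by all participants of the same group.  Unit-interval parameters
follow Beta(1 + a, 1 + b) population distributions with Gamma hyperpriors on
a and b; beta_T follows a Gamma distribution whose mean carries a lognormal
hyperprior.  Sampling is adaptive Metropolis-within-Gibbs on unconstrained
scales (logit for unit-interval parameters, log for positive ones): each
participant's 7-vector is updated with an adaptive multivariate random-walk
proposal, the group-shared beta_L and the hyperparameters with scalar /
bivariate random walks.  Pointwise log-likelihoods are tracked at the
participant-block level (each block's test trials pooled into its unit),
which is the unit of the WAIC comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, expit

from .errors import ConfigError, DataError
from .model import PackedSession, pack_session, _session_loglik_core, AgentParams

__all__ = [
    "PARAM_NAMES",
    "UNIT_PARAM_IDX",
    "ModelVariant",
    "PriorSpec",
    "McmcConfig",
    "PosteriorFit",
    "DiagnosticsReport",
    "fit",
    "check_diagnostics",
    "compute_waic",
    "compare_variants",
    "group_contrast",
    "counterfactual_swap",
]

PARAM_NAMES = (
    "alpha_pos",
    "alpha_neg",
    "beta_test",
    "epsilon",
    "phi",
    "omega3",
    "omega6",
)
UNIT_PARAM_IDX = (0, 1, 3, 4, 5, 6)  # logit-transformed
POS_PARAM_IDX = (2,)  # log-transformed (beta_test)

VARIANTS = ("flat", "single_hierarchy", "two_group")
ModelVariant = str


@dataclass(frozen=True)
class PriorSpec:
    """Prior and hyperprior constants (all configurable).

    Unit-interval parameters: theta ~ Beta(1 + a, 1 + b) with a, b ~
    Gamma(unit_hyper_shape, unit_hyper_rate) in the hierarchical variants, and
    theta ~ Beta(flat_beta_a, flat_beta_b) in the flat variant.  beta_T ~
    Gamma(bt_shape, bt_shape / mu) with log mu ~ Normal(bt_mu_logmean,
    bt_mu_logsd) hierarchically, or Gamma(bt_shape, bt_flat_rate) flat.  The
    group-shared beta_L ~ Gamma(bl_shape, bl_rate) in every variant (prior
    mean 50, in line with the convention of fixing the learning-phase inverse
    temperature at a large value).
    """

    unit_hyper_shape: float = 2.0
    unit_hyper_rate: float = 0.2
    flat_beta_a: float = 2.0
    flat_beta_b: float = 2.0
    bt_shape: float = 2.0
    bt_flat_rate: float = 0.2
    bt_mu_logmean: float = float(np.log(10.0))
    bt_mu_logsd: float = 1.0
    bl_shape: float = 2.0
    bl_rate: float = 0.04


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration (defaults match the full-scale fitting recipe)."""

    n_chains: int = 4
    n_warmup: int = 500
    n_kept: int = 1500
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_kept", "thin"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics inputs, and pointwise log-likelihoods."""

    variant: str
    participants: list
    participant_group: list  # group label per participant
    group_names: list
    theta: np.ndarray  # (chains, draws, P, 7) constrained
    beta_learn: np.ndarray  # (chains, draws, G)
    hyper_a: np.ndarray | None  # (chains, draws, n_pop, 6)
    hyper_b: np.ndarray | None
    bt_mu: np.ndarray | None  # (chains, draws, n_pop)
    pointwise: np.ndarray  # (chains, draws, P, n_blocks)
    mcmc: McmcConfig
    priors: PriorSpec
    data_fingerprint: str
    accept_rates: dict = field(default_factory=dict)
    sample_stats: dict | None = None  # HMC-style stats when available

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def posterior_mean_params(self) -> pd.DataFrame:
        """Posterior-mean parameter table, one row per participant (including
        the participant's group-shared beta_learn)."""
        mean = self.theta.mean(axis=(0, 1))
        out = pd.DataFrame(mean, columns=list(PARAM_NAMES), index=self.participants)
        bl_mean = self.beta_learn.mean(axis=(0, 1))
        gidx = {g: i for i, g in enumerate(self.group_names)}
        out["beta_learn"] = [
            bl_mean[gidx[g]] for g in self.participant_group
        ]
        out.index.name = "participant"
        return out

    def group_level_mean(self, parameter: str) -> np.ndarray:
        """Per-draw group-level means, shape (chains, draws, G)."""
        G = len(self.group_names)
        if parameter == "beta_learn":
            return self.beta_learn
        if parameter not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {parameter!r}")
        j = PARAM_NAMES.index(parameter)
        if (
            self.variant == "two_group"
            and j != 2
            and self.hyper_a is not None
        ):
            ju = UNIT_PARAM_IDX.index(j)
            a = self.hyper_a[:, :, :, ju]
            b = self.hyper_b[:, :, :, ju]
            return (1.0 + a) / (2.0 + a + b)
        if parameter == "beta_test" and self.bt_mu is not None and self.variant == "two_group":
            return self.bt_mu
        # fall back to averaging participant-level draws within group
        groups = np.asarray(self.participant_group)
        out = np.empty(self.theta.shape[:2] + (G,))
        for gi, g in enumerate(self.group_names):
            out[:, :, gi] = self.theta[:, :, groups == g, j].mean(axis=2)
        return out

    def to_inference_data(self):
        """Posterior draws as an arviz InferenceData (for rhat/ess/plots)."""
        import arviz as az

        posterior = {
            name: self.theta[:, :, :, j] for j, name in enumerate(PARAM_NAMES)
        }
        posterior["beta_learn"] = self.beta_learn
        if self.hyper_a is not None:
            posterior["hyper_a"] = self.hyper_a
            posterior["hyper_b"] = self.hyper_b
        if self.bt_mu is not None:
            posterior["bt_mu"] = self.bt_mu
        coords = {
            "participant": list(self.participants),
            "group": list(self.group_names),
        }
        dims = {name: ["participant"] for name in PARAM_NAMES}
        dims["beta_learn"] = ["group"]
        return az.from_dict(posterior=posterior, coords=coords, dims=dims)

    def draws_table(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, participant, value) draw table."""
        C, D, P, _ = self.theta.shape
        frames = []
        for j, name in enumerate(PARAM_NAMES):
            arr = self.theta[:, :, :, j]
            idx = np.indices(arr.shape)
            frames.append(
                pd.DataFrame(
                    {
                        "chain": idx[0].ravel(),
                        "draw": idx[1].ravel(),
                        "parameter": name,
                        "participant": np.asarray(self.participants)[idx[2].ravel()],
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class DiagnosticsReport:
    rhat_max: float
    ess_min: float
    bfmi_min: float | None
    n_divergent: int
    rhat_ok: bool
    ess_ok: bool
    bfmi_ok: bool
    divergence_ok: bool

    @property
    def passed(self) -> bool:
        return self.rhat_ok and self.ess_ok and self.bfmi_ok and self.divergence_ok


# --------------------------------------------------------------------------
# densities on the constrained scale
# --------------------------------------------------------------------------


def _beta_logpdf(x, a, b):
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) + (shape - 1.0) * np.log(x) - rate * x - gammaln(shape)


def _theta_from_z(z: np.ndarray) -> np.ndarray:
    theta = np.empty_like(z)
    for j in UNIT_PARAM_IDX:
        theta[..., j] = expit(z[..., j])
    for j in POS_PARAM_IDX:
        theta[..., j] = np.exp(z[..., j])
    return theta


def _log_jacobian(z: np.ndarray) -> float:
    # logit: log sigma(z) + log sigma(-z); log: z
    total = 0.0
    for j in UNIT_PARAM_IDX:
        zj = z[..., j]
        total += float(np.sum(-np.logaddexp(0.0, -zj) - np.logaddexp(0.0, zj)))
    for j in POS_PARAM_IDX:
        total += float(np.sum(z[..., j]))
    return total


def _participant_logprior(theta: np.ndarray, hyp: dict, priors: PriorSpec) -> float:
    """Log density of one participant's constrained parameters given the
    population parameters (or the fixed flat priors)."""
    lp = 0.0
    for k, j in enumerate(UNIT_PARAM_IDX):
        x = theta[j]
        if x <= 0.0 or x >= 1.0:
            return -np.inf
        lp += _beta_logpdf(x, 1.0 + hyp["a"][k], 1.0 + hyp["b"][k])
    bt = theta[2]
    if bt <= 0.0:
        return -np.inf
    lp += _gamma_logpdf(bt, priors.bt_shape, priors.bt_shape / hyp["bt_mu"])
    return float(lp)


def _loglik(ps: PackedSession, theta: np.ndarray, beta_learn: float) -> np.ndarray:
    return _session_loglik_core(
        ps.phase,
        ps.block,
        ps.stim,
        ps.action,
        ps.reward,
        ps.set_sizes,
        ps.omegas_key,
        ps.n_actions,
        theta[0],
        theta[1],
        beta_learn,
        theta[2],
        theta[3],
        theta[4],
        theta[5],
        theta[6],
    )


def _fingerprint(data: pd.DataFrame) -> str:
    cols = ["participant", "phase", "block", "trial", "stimulus", "action", "reward"]
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(data[cols], index=False).values.tobytes())
    return h.hexdigest()[:16]


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


def _init_z(rng: np.random.Generator, P: int) -> np.ndarray:
    base = np.array(
        [
            _logit(0.08),  # alpha_pos
            _logit(0.05),  # alpha_neg
            np.log(5.0),  # beta_test
            _logit(0.05),  # epsilon
            _logit(0.25),  # phi
            _logit(0.60),  # omega3
            _logit(0.40),  # omega6
        ]
    )
    return base[None, :] + rng.normal(0.0, 0.4, size=(P, 7))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _run_chain(
    sessions: list,
    group_idx: np.ndarray,
    n_groups: int,
    pop_idx: np.ndarray,
    n_pop: int,
    variant: str,
    priors: PriorSpec,
    n_warmup: int,
    n_kept: int,
    thin: int,
    seed: int,
):
    rng = np.random.default_rng(seed)
    P = len(sessions)
    n_blocks = sessions[0].set_sizes.shape[0]
    hier = variant != "flat"

    Z = _init_z(rng, P)
    theta = _theta_from_z(Z)
    log_bl = np.log(12.0) + rng.normal(0.0, 0.3, size=n_groups)
    # population parameters: a, b per unit param; bt_mu per population
    A = np.full((n_pop, 6), 2.0)
    B = np.full((n_pop, 6), 4.0)
    bt_mu = np.full(n_pop, 8.0)
    if not hier:
        # fixed flat priors expressed in the same (a, b) bookkeeping
        A[:] = priors.flat_beta_a - 1.0
        B[:] = priors.flat_beta_b - 1.0
        bt_mu[:] = priors.bt_shape / priors.bt_flat_rate

    bl = np.exp(log_bl)
    PW = np.stack([_loglik(s, theta[p], bl[group_idx[p]]) for p, s in enumerate(sessions)])
    L = PW.sum(axis=1)

    def hyp_for(p: int) -> dict:
        g = pop_idx[p]
        return {"a": A[g], "b": B[g], "bt_mu": bt_mu[g]}

    prior_p = np.array(
        [_participant_logprior(theta[p], hyp_for(p), priors) for p in range(P)]
    )

    # adaptation state
    lam = np.full(P, 0.4)
    chol = np.tile(np.eye(7) * 0.12, (P, 1, 1))
    zbuf: list = []
    bl_scale = np.full(n_groups, 0.15)
    hyp_scale = np.full((n_pop, 6), 0.25)
    btmu_scale = np.full(n_pop, 0.2)
    acc_count = {"participant": 0, "beta_learn": 0, "hyper": 0}
    try_count = {"participant": 0, "beta_learn": 0, "hyper": 0}

    kept_theta = np.empty((n_kept, P, 7))
    kept_bl = np.empty((n_kept, n_groups))
    kept_A = np.empty((n_kept, n_pop, 6)) if hier else None
    kept_B = np.empty((n_kept, n_pop, 6)) if hier else None
    kept_btmu = np.empty((n_kept, n_pop)) if hier else None
    kept_pw = np.empty((n_kept, P, n_blocks), dtype=np.float32)

    total_iters = n_warmup + n_kept * thin
    kept = 0
    for t in range(total_iters):
        warm = t < n_warmup
        gain = 2.0 / (t + 20.0) ** 0.6 if warm else 0.0

        # --- participant blocks -----------------------------------------
        noise = rng.standard_normal((P, 7))
        for p in range(P):
            zp = Z[p] + lam[p] * (chol[p] @ noise[p])
            thp = _theta_from_z(zp)
            lp_prior = _participant_logprior(thp, hyp_for(p), priors)
            if np.isfinite(lp_prior):
                pw_new = _loglik(sessions[p], thp, bl[group_idx[p]])
                l_new = pw_new.sum()
                logr = (
                    l_new
                    + lp_prior
                    + _log_jacobian(zp)
                    - L[p]
                    - prior_p[p]
                    - _log_jacobian(Z[p])
                )
                accept = np.log(rng.random()) < logr
            else:
                accept = False
            try_count["participant"] += 1
            if accept:
                Z[p] = zp
                theta[p] = thp
                PW[p] = pw_new
                L[p] = l_new
                prior_p[p] = lp_prior
                acc_count["participant"] += 1
            if warm:
                lam[p] *= np.exp(gain * ((1.0 if accept else 0.0) - 0.25))

        if warm:
            zbuf.append(Z.copy())
            if len(zbuf) > 300:
                zbuf.pop(0)
            if t >= 60 and t % 25 == 0:
                hist = np.asarray(zbuf)  # (k, P, 7)
                for p in range(P):
                    cov = np.cov(hist[:, p, :].T) + 1e-5 * np.eye(7)
                    try:
                        chol[p] = np.linalg.cholesky(cov * (2.38**2 / 7.0))
                    except np.linalg.LinAlgError:
                        pass

        # --- group-shared beta_learn ------------------------------------
        for g in range(n_groups):
            members = np.flatnonzero(group_idx == g)
            prop = log_bl[g] + bl_scale[g] * rng.standard_normal()
            bl_new = float(np.exp(prop))
            pw_list = [_loglik(sessions[p], theta[p], bl_new) for p in members]
            delta_l = sum(pw.sum() for pw in pw_list) - L[members].sum()
            logr = (
                delta_l
                + _gamma_logpdf(bl_new, priors.bl_shape, priors.bl_rate)
                - _gamma_logpdf(np.exp(log_bl[g]), priors.bl_shape, priors.bl_rate)
                + prop
                - log_bl[g]
            )
            accept = np.log(rng.random()) < logr
            try_count["beta_learn"] += 1
            if accept:
                log_bl[g] = prop
                bl[g] = bl_new
                for k, p in enumerate(members):
                    PW[p] = pw_list[k]
                    L[p] = pw_list[k].sum()
                acc_count["beta_learn"] += 1
            if warm:
                bl_scale[g] *= np.exp(gain * ((1.0 if accept else 0.0) - 0.44))

        # --- population parameters --------------------------------------
        if hier:
            for g in range(n_pop):
                members = np.flatnonzero(pop_idx == g)
                for k in range(6):
                    j = UNIT_PARAM_IDX[k]
                    x = theta[members, j]
                    la, lb = np.log(A[g, k]), np.log(B[g, k])
                    du = hyp_scale[g, k] * rng.standard_normal()
                    dv = 0.35 * hyp_scale[g, k] * rng.standard_normal()
                    la_n, lb_n = la + du + dv, lb + du - dv
                    a_n, b_n = np.exp(la_n), np.exp(lb_n)
                    logr = (
                        np.sum(_beta_logpdf(x, 1.0 + a_n, 1.0 + b_n))
                        - np.sum(_beta_logpdf(x, 1.0 + A[g, k], 1.0 + B[g, k]))
                        + _gamma_logpdf(a_n, priors.unit_hyper_shape, priors.unit_hyper_rate)
                        + _gamma_logpdf(b_n, priors.unit_hyper_shape, priors.unit_hyper_rate)
                        - _gamma_logpdf(A[g, k], priors.unit_hyper_shape, priors.unit_hyper_rate)
                        - _gamma_logpdf(B[g, k], priors.unit_hyper_shape, priors.unit_hyper_rate)
                        + (la_n - la)
                        + (lb_n - lb)
                    )
                    accept = np.log(rng.random()) < logr
                    try_count["hyper"] += 1
                    if accept:
                        A[g, k], B[g, k] = a_n, b_n
                        acc_count["hyper"] += 1
                    if warm:
                        hyp_scale[g, k] *= np.exp(gain * ((1.0 if accept else 0.0) - 0.3))
                # beta_test population mean
                btv = theta[members, 2]
                lmu = np.log(bt_mu[g])
                lmu_n = lmu + btmu_scale[g] * rng.standard_normal()
                mu_n = float(np.exp(lmu_n))
                logr = (
                    np.sum(_gamma_logpdf(btv, priors.bt_shape, priors.bt_shape / mu_n))
                    - np.sum(_gamma_logpdf(btv, priors.bt_shape, priors.bt_shape / bt_mu[g]))
                    - 0.5 * ((lmu_n - priors.bt_mu_logmean) / priors.bt_mu_logsd) ** 2
                    + 0.5 * ((lmu - priors.bt_mu_logmean) / priors.bt_mu_logsd) ** 2
                )
                accept = np.log(rng.random()) < logr
                if accept:
                    bt_mu[g] = mu_n
                if warm:
                    btmu_scale[g] *= np.exp(gain * ((1.0 if accept else 0.0) - 0.44))
            # hyperparameters moved: refresh participant prior cache
            prior_p = np.array(
                [_participant_logprior(theta[p], hyp_for(p), priors) for p in range(P)]
            )

        # --- storage ------------------------------------------------------
        if not warm and (t - n_warmup) % thin == thin - 1:
            kept_theta[kept] = theta
            kept_bl[kept] = bl
            if hier:
                kept_A[kept] = A
                kept_B[kept] = B
                kept_btmu[kept] = bt_mu
            kept_pw[kept] = PW
            kept += 1

    rates = {k: acc_count[k] / max(try_count[k], 1) for k in acc_count}
    return kept_theta, kept_bl, kept_A, kept_B, kept_btmu, kept_pw, rates


def fit(
    data: pd.DataFrame,
    variant: ModelVariant = "two_group",
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    n_actions: int = 3,
) -> PosteriorFit:
    """Fit the hierarchical RL-WM model by adaptive Metropolis-within-Gibbs.

    ``data`` is the trial-table DataFrame with both phases.  Returns the
    posterior draws; diagnostic failures do not raise — run
    :func:`check_diagnostics` on the result and decide.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()

    if not {"learn", "test"} <= set(data["phase"].unique()):
        raise DataError("data must include both learning and test phases")

    participants = sorted(data["participant"].unique())
    sessions = []
    groups = []
    for pid in participants:
        ps = pack_session(data[data["participant"] == pid], n_actions=n_actions)
        sessions.append(ps)
        groups.append(ps.group)
    group_names = sorted(set(groups), key=lambda g: (g != "young", g))
    if variant == "two_group":
        if len(group_names) != 2:
            raise DataError(
                f"two_group variant needs exactly 2 groups, got {group_names}"
            )
        for g in group_names:
            if groups.count(g) == 0:
                raise DataError(f"group {g} is empty")
    group_idx = np.array([group_names.index(g) for g in groups])
    if variant == "two_group":
        pop_idx, n_pop = group_idx, len(group_names)
    else:
        pop_idx, n_pop = np.zeros(len(sessions), dtype=int), 1

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = []
    for c in range(mcmc.n_chains):
        chains.append(
            _run_chain(
                sessions,
                group_idx,
                len(group_names),
                pop_idx,
                n_pop,
                variant,
                priors,
                mcmc.n_warmup,
                mcmc.n_kept,
                mcmc.thin,
                seed=seeds[c].generate_state(1)[0] % (2**31),
            )
        )
    hier = variant != "flat"
    return PosteriorFit(
        variant=variant,
        participants=participants,
        participant_group=groups,
        group_names=group_names,
        theta=np.stack([c[0] for c in chains]),
        beta_learn=np.stack([c[1] for c in chains]),
        hyper_a=np.stack([c[2] for c in chains]) if hier else None,
        hyper_b=np.stack([c[3] for c in chains]) if hier else None,
        bt_mu=np.stack([c[4] for c in chains]) if hier else None,
        pointwise=np.stack([c[5] for c in chains]),
        mcmc=mcmc,
        priors=priors,
        data_fingerprint=_fingerprint(data),
        accept_rates={k: float(np.mean([c[6][k] for c in chains])) for k in chains[0][6]},
    )


# --------------------------------------------------------------------------
# diagnostics, WAIC, contrasts
# --------------------------------------------------------------------------


def check_diagnostics(
    fit: PosteriorFit,
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
    bfmi_min: float = 0.2,
) -> DiagnosticsReport:
    """Convergence report: Rhat <= 1.01 and ESS >= 400 for every parameter;
    BFMI >= 0.2 per chain and zero divergences when HMC-style sample stats
    are present (samplers without an energy diagnostic pass those vacuously).
    """
    import arviz as az

    idata = fit.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rh = float(
        max(np.nanmax(np.atleast_1d(rhat[v].values)) for v in rhat.data_vars)
    )
    es = float(min(np.nanmin(np.atleast_1d(ess[v].values)) for v in ess.data_vars))
    stats = fit.sample_stats or {}
    n_div = int(np.sum(stats.get("diverging", 0)))
    if "energy" in stats:
        energy = np.asarray(stats["energy"])  # (chains, draws)
        num = np.square(np.diff(energy, axis=1)).mean(axis=1)
        den = energy.var(axis=1)
        bfmi = float(np.min(num / den))
        bfmi_ok = bfmi >= bfmi_min
    else:
        bfmi, bfmi_ok = None, True
    return DiagnosticsReport(
        rhat_max=rh,
        ess_min=es,
        bfmi_min=bfmi,
        n_divergent=n_div,
        rhat_ok=rh <= rhat_max,
        ess_ok=es >= ess_min,
        bfmi_ok=bfmi_ok,
        divergence_ok=n_div == 0,
    )


def compute_waic(pointwise: np.ndarray | PosteriorFit) -> dict:
    """WAIC from a (draws, units) pointwise log-likelihood matrix.

    WAIC = -2 (lppd - p_waic), lppd = sum_i log mean_s exp(ll_si), p_waic =
    sum_i var_s(ll_si); lower is better.  A PosteriorFit may be passed
    directly (its participant-block pointwise matrix is used).
    """
    if isinstance(pointwise, PosteriorFit):
        C, D, P, B = pointwise.pointwise.shape
        ll = pointwise.pointwise.reshape(C * D, P * B).astype(float)
    else:
        ll = np.asarray(pointwise, dtype=float)
        if ll.ndim != 2:
            raise DataError("pointwise matrix must be 2-D (draws x units)")
    S = ll.shape[0]
    lppd_i = np.logaddexp.reduce(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1) if S > 1 else np.zeros(ll.shape[1])
    elpd_i = lppd_i - p_i
    waic = float(-2.0 * elpd_i.sum())
    se = float(2.0 * np.sqrt(ll.shape[1] * elpd_i.var(ddof=1)))
    return {"waic": waic, "se": se, "p_waic": float(p_i.sum()), "n_units": ll.shape[1]}


def compare_variants(fits: list) -> pd.DataFrame:
    """Ranked WAIC table for fits of different variants to the same data."""
    if len(fits) < 1:
        raise DataError("need at least one fit")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) > 1:
        raise DataError("fits were not computed on identical data")
    rows = []
    for f in fits:
        w = compute_waic(f)
        rows.append(
            {"variant": f.variant, "waic": w["waic"], "se": w["se"], "p_waic": w["p_waic"]}
        )
    table = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    table["delta_waic"] = table["waic"] - table["waic"].iloc[0]
    return table


def group_contrast(
    fit: PosteriorFit, parameter: str, order: tuple | None = None
) -> dict:
    """Group contrast Delta = young - older on the group-level mean of a
    parameter, with the 95% equal-tailed credible interval and P(Delta < 0)."""
    if len(fit.group_names) != 2:
        raise DataError("group contrast needs a two-group fit")
    means = fit.group_level_mean(parameter)  # (chains, draws, 2)
    names = list(fit.group_names)
    if order is None:
        order = tuple(names)
    i0, i1 = names.index(order[0]), names.index(order[1])
    delta = (means[:, :, i0] - means[:, :, i1]).ravel()
    lo, hi = np.percentile(delta, [2.5, 97.5])
    return {
        "parameter": parameter,
        "order": order,
        "delta_mean": float(delta.mean()),
        "cri": (float(lo), float(hi)),
        "p_lt_0": float((delta < 0).mean()),
    }


def counterfactual_swap(
    fit: PosteriorFit,
    donor_group: str,
    recipient_group: str,
    parameter: str,
    plans: dict,
    seed: int,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Simulate recipient participants with one parameter swapped.

    Each recipient is simulated ``n_reps`` times from their own
    posterior-mean parameters, except ``parameter`` which is replaced by the
    donor group's group-level posterior mean.  ``plans`` maps participant id
    -> SessionPlan.  Returns a trial table comparable to posterior-predictive
    simulations (repetitions are distinguished by a ``rep`` column).
    """
    from .model import simulate_agent

    if parameter not in PARAM_NAMES and parameter != "beta_learn":
        raise KeyError(f"unknown parameter {parameter!r}")
    means = fit.posterior_mean_params()
    gl = fit.group_level_mean(parameter).mean(axis=(0, 1))
    donor_value = float(gl[fit.group_names.index(donor_group)])
    rng = np.random.default_rng(seed)
    frames = []
    for pid, grp in zip(fit.participants, fit.participant_group):
        if grp != recipient_group:
            continue
        row = means.loc[pid].to_dict()
        row[parameter] = donor_value
        params = AgentParams(**{k: float(row[k]) for k in list(PARAM_NAMES) + ["beta_learn"]})
        for rep in range(n_reps):
            frames.append(
                simulate_agent(
                    plans[pid],
                    params,
                    seed=int(rng.integers(2**31)),
                    participant=pid,
                    group=recipient_group,
                ).assign(rep=rep)
            )
    if not frames:
        raise DataError(f"no participants in recipient group {recipient_group!r}")
    return pd.concat(frames, ignore_index=True)
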