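"""Posterior predictive checks and parameter-recovery studies.

These are the model's acceptance surface: posterior predictive learning
curves (simulate full sessions from sampled posterior draws and aggregate
accuracy by stimulus iteration), asymptotic means (last three iterations),
and end-to-end recovery runs (generate a synthetic cohort from known
hyperparameters, fit the two-group model, and compare recovered parameters
against the recorded truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import LearningCurve, empirical_learning_curves
from .errors import ConfigError, DataError
from .inference import (
    PARAM_NAMES,
    McmcConfig,
    PosteriorFit,
    PriorSpec,
    fit,
    group_contrast,
)
from .model import AgentParams, simulate_agent

__all__ = [
    "PredictiveCurve",
    "RecoveryReport",
    "posterior_predictive_curves",
    "asymptotic_mean",
    "run_recovery",
]


@dataclass
class PredictiveCurve:
    """Posterior predictive accuracy by iteration for one (group, set size)."""

    iterations: np.ndarray
    mean: np.ndarray  # predictive mean accuracy per iteration
    lo: np.ndarray  # 2.5% predictive band
    hi: np.ndarray  # 97.5% predictive band
    n_draws: int


@dataclass
class RecoveryReport:
    """True-vs-recovered comparison after fitting a simulated cohort."""

    table: pd.DataFrame  # participant, parameter, truth, recovered
    correlations: pd.Series  # Pearson r per parameter
    hyper_coverage: dict  # parameter -> truth-in-95%-CrI flag (group means)
    contrast: dict  # the phi group contrast of the recovery fit
    fit: PosteriorFit


def asymptotic_mean(curve) -> float:
    """Mean accuracy over the last three stimulus iterations of a curve."""
    mean = np.asarray(curve.mean, dtype=float)
    if mean.shape[0] < 3:
        raise DataError("asymptotic mean needs at least 3 iterations")
    return float(np.nanmean(mean[-3:]))


def posterior_predictive_curves(
    fit_: PosteriorFit,
    plans: dict,
    n_draws: int = 200,
    seed: int = 0,
) -> dict:
    """Posterior predictive learning curves per (group, set size).

    For each of ``n_draws`` posterior draws, every participant's session is
    re-simulated from that draw's participant-level parameters on the
    participant's own session plan; accuracies are aggregated by stimulus
    iteration.  Returns {(group, set_size): PredictiveCurve}.
    """
    C, D = fit_.theta.shape[:2]
    total = C * D
    if n_draws > total:
        raise ConfigError(f"n_draws={n_draws} exceeds available draws ({total})")
    rng = np.random.default_rng(seed)
    picks = rng.choice(total, size=n_draws, replace=False)
    gidx = {g: i for i, g in enumerate(fit_.group_names)}

    # accumulate per-draw mean accuracy per (group, set_size, iteration)
    per_draw: dict = {}
    for d_i, flat in enumerate(picks):
        ci, di = divmod(int(flat), D)
        frames = []
        for p_i, pid in enumerate(fit_.participants):
            th = fit_.theta[ci, di, p_i]
            grp = fit_.participant_group[p_i]
            params = AgentParams(
                alpha_pos=th[0],
                alpha_neg=th[1],
                beta_learn=float(fit_.beta_learn[ci, di, gidx[grp]]),
                beta_test=th[2],
                epsilon=th[3],
                phi=th[4],
                omega3=th[5],
                omega6=th[6],
            )
            frames.append(
                simulate_agent(
                    plans[pid],
                    params,
                    seed=int(rng.integers(2**31)),
                    participant=pid,
                    group=grp,
                )
            )
        sim = pd.concat(frames, ignore_index=True)
        learn = sim[sim["phase"] == "learn"]
        acc = learn.groupby(["group", "set_size", "iteration"])["reward"].mean()
        for key, val in acc.items():
            per_draw.setdefault(key, []).append(val)

    curves: dict = {}
    cells = sorted({(g, ns) for g, ns, _ in per_draw})
    for g, ns in cells:
        iters = sorted(i for gg, nn, i in per_draw if (gg, nn) == (g, ns))
        arr = np.array([per_draw[(g, ns, i)] for i in iters])  # (iters, draws)
        curves[(g, int(ns))] = PredictiveCurve(
            iterations=np.asarray(iters, dtype=int),
            mean=arr.mean(axis=1),
            lo=np.percentile(arr, 2.5, axis=1),
            hi=np.percentile(arr, 97.5, axis=1),
            n_draws=n_draws,
        )
    return curves


def run_recovery(
    spec,
    mcmc: McmcConfig,
    seed: int,
    priors: PriorSpec | None = None,
) -> RecoveryReport:
    """Simulate a cohort from ``spec`` (a CohortSpec), fit the two-group
    model, and report individual-level recovery correlations plus coverage of
    the generating group means by the 95% CrI of the fitted group means.

    Diagnostics are not silently swallowed: the returned report carries the
    full PosteriorFit so callers can run check_diagnostics on it.
    """
    from .cohort import generate_cohort

    cohort = generate_cohort(spec, seed=seed)
    fit_ = fit(cohort.behavior, variant="two_group", priors=priors, mcmc=mcmc)

    post_mean = fit_.posterior_mean_params()
    truth = pd.DataFrame(cohort.truth["participants"]).T
    rows = []
    for pid in fit_.participants:
        for par in PARAM_NAMES:
            rows.append(
                {
                    "participant": pid,
                    "parameter": par,
                    "truth": float(truth.loc[pid, par]),
                    "recovered": float(post_mean.loc[pid, par]),
                }
            )
    table = pd.DataFrame(rows)
    correlations = (
        table.groupby("parameter")
        .apply(
            lambda g: float(np.corrcoef(g["truth"], g["recovered"])[0, 1]),
            include_groups=False,
        )
        .rename("pearson_r")
    )

    # group-mean coverage: is the generating group mean inside the 95% CrI of
    # the fitted group-level mean?
    hyper_coverage = {}
    for par in ("phi", "omega3", "omega6", "alpha_pos", "alpha_neg", "epsilon"):
        means = fit_.group_level_mean(par)  # (chains, draws, G)
        cover = {}
        for gi, g in enumerate(fit_.group_names):
            gen = cohort.truth["group_hyper"][g]["means"][par]
            lo, hi = np.percentile(means[:, :, gi].ravel(), [2.5, 97.5])
            cover[g] = bool(lo <= gen <= hi)
        hyper_coverage[par] = cover

    contrast = group_contrast(fit_, "phi")
    return RecoveryReport(
        table=table,
        correlations=correlations,
        hyper_coverage=hyper_coverage,
        contrast=contrast,
        fit=fit_,
    )
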