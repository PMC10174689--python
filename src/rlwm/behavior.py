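"""Model-independent behavioral analyses.

Learning curves by stimulus iteration, trial-level logistic regressions with
set-size / delay / reward-history predictors (fitted per participant, with
group-level inference on the participant coefficients), a regression of age
on those coefficients, and training-vs-test performance comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import DataError

__all__ = [
    "LearningCurve",
    "GlmResult",
    "empirical_learning_curves",
    "reward_history",
    "glm_delay",
    "trial_glm",
    "age_regression",
    "train_test_comparison",
]

LEARN_PREDICTORS = ["set_size", "delay", "reward_history", "trial", "block"]
TEST_PREDICTORS = ["set_size", "reward_history"]


@dataclass
class LearningCurve:
    """Mean accuracy (+/- SEM) at each stimulus iteration for one cell."""

    iterations: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int  # contributing participants

    def asymptote(self) -> float:
        """Mean accuracy over the last three iterations."""
        if len(self.iterations) < 3:
            raise DataError("asymptotic mean needs at least 3 iterations")
        return float(np.nanmean(self.mean[-3:]))


@dataclass
class GlmResult:
    """Per-participant logistic coefficients plus group-level summaries."""

    coefficients: pd.DataFrame  # one row per retained participant
    group_stats: pd.DataFrame  # mean, t, p per predictor (pooled and by group)
    excluded: list = field(default_factory=list)  # (participant, reason)


def _learning_trials(data: pd.DataFrame) -> pd.DataFrame:
    out = data[(data["phase"] == "learn") & (~data["missed"].astype(bool))]
    if len(out) == 0:
        raise DataError("no usable learning-phase trials")
    return out


def empirical_learning_curves(data: pd.DataFrame) -> dict:
    """Observed learning curves keyed by (group, set_size).

    Accuracy is averaged per participant at each stimulus iteration (missed
    trials excluded), then averaged across participants; SEM is across
    participants.  Empty cells yield NaN rather than an imputed value.
    """
    learn = _learning_trials(data)
    curves: dict = {}
    for (grp, ns), cell in learn.groupby(["group", "set_size"]):
        per_part = cell.pivot_table(
            index="participant", columns="iteration", values="reward", aggfunc="mean"
        )
        iters = np.asarray(per_part.columns, dtype=int)
        mean = per_part.mean(axis=0).to_numpy()
        sem = per_part.sem(axis=0).to_numpy()
        curves[(grp, int(ns))] = LearningCurve(
            iterations=iters, mean=mean, sem=sem, n=per_part.shape[0]
        )
    return curves


def reward_history(data: pd.DataFrame) -> pd.Series:
    """Stimulus-wise cumulative count of prior rewarded presentations.

    For each learning trial, the number of previously rewarded presentations
    of that trial's stimulus within its block (0 on first presentations).
    Indexed like ``data``; NaN outside the learning phase.
    """
    out = pd.Series(np.nan, index=data.index)
    learn = data[data["phase"] == "learn"]
    for (_, _, _), grp in learn.groupby(["participant", "block", "stimulus"]):
        r = grp["reward"].fillna(0.0).to_numpy()
        out.loc[grp.index] = np.concatenate([[0.0], np.cumsum(r)[:-1]])
    return out


def glm_delay(data: pd.DataFrame) -> pd.Series:
    """Trials since the most recent REWARDED presentation of the stimulus.

    Counts intervening trials (within the block, across all stimuli) since the
    last presentation of the same stimulus that was rewarded; NaN when no
    prior rewarded presentation exists (those trials are excluded from GLMs).
    """
    out = pd.Series(np.nan, index=data.index)
    learn = data[data["phase"] == "learn"]
    for (_, _), block in learn.groupby(["participant", "block"]):
        trial = block["trial"].to_numpy()
        stim = block["stimulus"].to_numpy()
        rew = block["reward"].fillna(0.0).to_numpy()
        last_rewarded: dict = {}
        vals = np.full(len(block), np.nan)
        for i in range(len(block)):
            s = stim[i]
            if s in last_rewarded:
                vals[i] = trial[i] - last_rewarded[s] - 1
            if rew[i] == 1:
                last_rewarded[s] = trial[i]
        out.loc[block.index] = vals
    return out


def _fit_participant_logit(y: np.ndarray, X: pd.DataFrame):
    """Logistic fit; returns (params, reason) with params None on failure."""
    if y.min() == y.max():
        return None, "constant outcome"
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:  # separation, singular design
        return None, f"fit error: {exc}"
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 15:
        return None, "separation / runaway coefficients"
    return res.params, None


def trial_glm(data: pd.DataFrame, phase: str = "learn") -> GlmResult:
    """Trial-level logistic regression of accuracy, fitted per participant.

    Learning-phase predictors: set size, delay (since last rewarded
    presentation; undefined trials dropped), cumulative reward history, trial,
    and block.  Test phase uses reward history (carried over from learning)
    and set size.  Predictors are z-scored within participant so coefficients
    are comparable across participants; group-level inference is a one-sample
    t test on the participant coefficients.  Participants whose fit fails
    (separation, non-convergence) are flagged and excluded.
    """
    data = data.copy()
    data["reward_history"] = reward_history(data)
    if phase == "learn":
        data["delay"] = glm_delay(data)
        rows = _learning_trials(data).dropna(subset=["delay"])
        predictors = LEARN_PREDICTORS
        rows = rows.assign(accuracy=rows["reward"].astype(float))
    elif phase == "test":
        learn = _learning_trials(data)
        totals = learn.groupby(["participant", "stimulus"])["reward"].sum()
        test = data[(data["phase"] == "test") & (~data["missed"].astype(bool))].copy()
        key = list(zip(test["participant"], test["stimulus"]))
        # reward history carries over from learning; test rows' own reward
        # column records response correctness (no feedback was delivered)
        test["reward_history"] = [totals.get(k, 0.0) for k in key]
        rows = test.assign(accuracy=test["reward"].astype(float))
        predictors = TEST_PREDICTORS
    else:
        raise DataError(f"unknown phase {phase!r}")

    coef_rows = []
    excluded = []
    for pid, grp in rows.groupby("participant"):
        X = grp[predictors].astype(float)
        std = X.std(ddof=0)
        keep = [c for c in predictors if std[c] > 0]
        Xz = (X[keep] - X[keep].mean()) / X[keep].std(ddof=0)
        params, reason = _fit_participant_logit(
            grp["accuracy"].to_numpy(dtype=float), Xz
        )
        if params is None:
            excluded.append((pid, reason))
            continue
        row = {"participant": pid, "group": grp["group"].iloc[0]}
        row["intercept"] = params["const"]
        for c in predictors:
            row[c] = params.get(c, np.nan)
        coef_rows.append(row)
    if not coef_rows:
        raise DataError("no participant produced a usable GLM fit")
    coefs = pd.DataFrame(coef_rows)

    stats_rows = []
    for scope, sub in [("all", coefs)] + [
        (g, coefs[coefs["group"] == g]) for g in coefs["group"].unique()
    ]:
        for c in ["intercept"] + predictors:
            vals = sub[c].dropna().to_numpy()
            if len(vals) < 2:
                continue
            t, p = stats.ttest_1samp(vals, 0.0)
            stats_rows.append(
                {
                    "scope": scope,
                    "predictor": c,
                    "mean": vals.mean(),
                    "t": float(t),
                    "p": float(p),
                    "n": len(vals),
                }
            )
    return GlmResult(
        coefficients=coefs,
        group_stats=pd.DataFrame(stats_rows),
        excluded=excluded,
    )


def age_regression(
    coefs: pd.DataFrame, ages: pd.Series, predictors: list | None = None
):
    """Linear regression of age on participant GLM coefficients.

    Participants with any coefficient more than 2 SD above that coefficient's
    mean are excluded before fitting.  Returns the statsmodels OLS results
    plus the list of excluded participants.
    """
    if predictors is None:
        predictors = [c for c in coefs.columns if c not in ("participant", "group")]
    X = coefs.set_index("participant")[predictors].astype(float)
    if len(X) <= len(predictors) + 1:
        raise DataError("fewer participants than predictors in age regression")
    upper = X.mean() + 2.0 * X.std(ddof=0)
    outlier = (X > upper).any(axis=1)
    excluded = list(X.index[outlier])
    Xk = X[~outlier]
    y = ages.reindex(Xk.index).astype(float)
    if y.isna().any():
        raise DataError("missing age for participants in the coefficient table")
    res = sm.OLS(y, sm.add_constant(Xk)).fit()
    return res, excluded


def train_test_comparison(data: pd.DataFrame):
    """Per set size, the drop from late learning to test accuracy.

    Late learning is the mean of the last three stimulus iterations; test
    accuracy comes from the test rows' recorded correctness.  Returns a dict
    with the per-participant drop table, paired within-group tests of
    drop(set 3) vs drop(set 6), the between-group comparison of the set-size
    asymmetry, and Spearman correlations of accuracy with age.
    """
    data = data.copy()
    data["accuracy"] = data["reward"]

    learn = _learning_trials(data)
    max_iter = int(learn["iteration"].max())
    late = learn[learn["iteration"] > max_iter - 3]
    late_acc = late.groupby(["participant", "group", "set_size"])["reward"].mean()
    test = data[(data["phase"] == "test") & (~data["missed"].astype(bool))]
    if len(test) == 0:
        raise DataError("no test-phase trials present")
    test_acc = test.groupby(["participant", "group", "set_size"])["accuracy"].mean()

    table = pd.DataFrame({"late": late_acc, "test": test_acc}).dropna()
    table["drop"] = table["late"] - table["test"]
    wide = table["drop"].unstack("set_size")
    wide.columns = [f"drop_{int(c)}" for c in wide.columns]
    wide = wide.reset_index()

    results = {"drops": wide}
    has_both = {"drop_3", "drop_6"} <= set(wide.columns)
    if has_both:
        for g, sub in wide.groupby("group"):
            common = sub.dropna(subset=["drop_3", "drop_6"])
            t, p = stats.ttest_rel(common["drop_3"], common["drop_6"])
            results[f"paired_{g}"] = {"t": float(t), "p": float(p), "n": len(common)}
        asym = wide.dropna(subset=["drop_3", "drop_6"]).copy()
        asym["asymmetry"] = asym["drop_3"] - asym["drop_6"]
        grps = asym["group"].unique()
        if len(grps) == 2:
            a = asym.loc[asym["group"] == grps[0], "asymmetry"]
            b = asym.loc[asym["group"] == grps[1], "asymmetry"]
            t, p = stats.ttest_ind(a, b)
            results["between_group_asymmetry"] = {
                "groups": list(grps),
                "t": float(t),
                "p": float(p),
            }
    ages = data.groupby("participant")["age"].first()
    corr = {}
    for ns in sorted(set(int(s) for s in data["set_size"].unique())):
        for phase_name, acc in (("learn", late_acc), ("test", test_acc)):
            cell = acc.xs(ns, level="set_size").droplevel("group")
            common = cell.index.intersection(ages.index)
            if len(common) >= 3 and np.isfinite(ages[common]).all():
                rho, p = stats.spearmanr(ages[common], cell[common])
                corr[(phase_name, ns)] = {"rho": float(rho), "p": float(p)}
    results["age_correlations"] = corr
    return results
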