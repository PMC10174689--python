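"""Linking regional brain measures to task performance and model parameters.

The pipeline mirrors a data-driven feature-selection design: regional
neurochemical measures (glutamate, GABA, NAA) are averaged across their three
voxels (MFG, IPS, STR) and z-scored alongside structural measures (gray and
white matter volume, and cortical thickness in CMF, SF, RMF kept separate),
giving 8 candidate predictors of learning performance.  Repeated 4/5-1/5
cross-validation with an elastic net (equal L1/L2 weighting) selects the
predictor configuration with the best out-of-sample error; the winning
configuration is refit by OLS, its fitted values form a "brain-predicted
performance" axis that is regressed on the model parameters, and anatomical
specificity and age mediation are probed with follow-up regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.linear_model import enet_path

from .errors import DataError

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureSelectionResult",
    "aggregate_features",
    "select_features_cv",
    "brain_predicted_performance",
    "map_parameters",
    "anatomical_specificity",
    "mediation_acme",
]

#: candidate predictors, in emission order
FEATURE_COLUMNS = [
    "glutamate",
    "gaba",
    "naa",
    "gm_volume",
    "wm_volume",
    "thickness_CMF",
    "thickness_SF",
    "thickness_RMF",
]

MRS_REGIONS = ("MFG", "IPS", "STR")


def aggregate_features(brain: pd.DataFrame, zscore: bool = True) -> pd.DataFrame:
    """Region-averaged, z-scored predictor table (complete cases only).

    Glutamate, GABA, and NAA are averaged across MFG, IPS, and STR; gray and
    white matter volumes are single global measures; cortical thickness stays
    region-specific (CMF, SF, RMF).  Every output column is z-scored (set
    ``zscore=False`` to inspect the raw pooled values).
    """
    wide = {}
    for m in ("glutamate", "gaba", "naa"):
        sub = brain[(brain["measure"] == m) & (brain["region"].isin(MRS_REGIONS))]
        wide[m] = sub.groupby("participant")["value"].mean()
    for m in ("gm_volume", "wm_volume"):
        wide[m] = brain[brain["measure"] == m].groupby("participant")["value"].mean()
    thick = brain[brain["measure"] == "thickness"]
    for r in ("CMF", "SF", "RMF"):
        wide[f"thickness_{r}"] = (
            thick[thick["region"] == r].groupby("participant")["value"].mean()
        )
    table = pd.DataFrame(wide).dropna()[FEATURE_COLUMNS]
    if not zscore:
        return table
    sd = table.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise DataError(f"cannot z-score constant feature column(s): {bad}")
    return (table - table.mean()) / sd


@dataclass
class FeatureSelectionResult:
    """Outcome of the repeated cross-validated elastic-net selection."""

    iterations: pd.DataFrame  # iteration, configuration, mse, n_selected
    best_configuration: tuple  # ordered feature names (may be empty)
    refit: object  # statsmodels OLS results for the best configuration
    features: pd.DataFrame
    performance: pd.Series


def _nonnull_enet_selection(X: np.ndarray, y: np.ndarray, l1_ratio: float):
    """Nonzero-coefficient set at the largest penalty giving a non-null model.

    Walks the elastic-net path from its analytic maximum penalty (the
    smallest penalty at which every coefficient is zero) downward and stops at
    the first model with any nonzero coefficient.
    """
    n = X.shape[0]
    # enet_path fits no intercept: center both sides on the training data
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    amax = np.max(np.abs(Xc.T @ yc)) / (n * l1_ratio)
    if amax <= 0:
        return np.array([], dtype=int), np.zeros(X.shape[1])
    # fine grid just below the entry penalty, then a coarser tail as fallback
    alphas = np.concatenate(
        [np.geomspace(amax * 1.001, amax * 0.85, 20), np.geomspace(amax * 0.8, amax * 1e-3, 30)]
    )
    _, coefs, _ = enet_path(Xc, yc, l1_ratio=l1_ratio, alphas=alphas)
    for k in range(len(alphas)):
        nz = np.flatnonzero(np.abs(coefs[:, k]) > 0)
        if nz.size:
            return nz, coefs[:, k]
    return np.array([], dtype=int), np.zeros(X.shape[1])


def select_features_cv(
    features: pd.DataFrame,
    performance: pd.Series,
    n_iter: int = 200,
    mixing: float = 0.5,
    seed: int = 0,
) -> FeatureSelectionResult:
    """Repeated 4/5-1/5 cross-validated elastic-net feature selection.

    Each iteration fits an elastic net (L1 weight = ``mixing``) on a random
    4/5 of the complete cases at the largest penalty that keeps the model
    non-null, records the selected predictor set and its held-out MSE, and
    falls back to the empty configuration when the intercept-only model
    predicts the held-out fifth better.  The best configuration (lowest mean
    held-out MSE among configurations appearing in at least 5% of iterations,
    ties broken by fewer predictors) is refit by OLS for inference.
    """
    common = features.index.intersection(performance.dropna().index)
    if len(common) < 10:
        raise DataError("need at least 10 complete cases for feature selection")
    X = features.loc[common].to_numpy(dtype=float)
    y = performance.loc[common].to_numpy(dtype=float)
    n = len(common)
    n_val = max(1, n // 5)
    rng = np.random.default_rng(seed)

    records = []
    splits = []
    for it in range(n_iter):
        perm = rng.permutation(n)
        val, train = perm[:n_val], perm[n_val:]
        splits.append((train, val))
        if np.ptp(y[train]) == 0:
            records.append(
                {"iteration": it, "configuration": None, "mse": np.nan, "skipped": True}
            )
            continue
        nz, _ = _nonnull_enet_selection(X[train], y[train], mixing)
        # relaxed fit: the penalty chooses the subset, OLS on the training
        # 4/5 provides the coefficients that are scored on the held-out 1/5
        null_mse = float(np.mean((y[val] - y[train].mean()) ** 2))
        if nz.size:
            Xt = np.column_stack([np.ones(len(train)), X[train][:, nz]])
            beta = np.linalg.lstsq(Xt, y[train], rcond=None)[0]
            pred = np.column_stack([np.ones(len(val)), X[val][:, nz]]) @ beta
            mse = float(np.mean((y[val] - pred) ** 2))
        else:
            mse = null_mse
        if null_mse <= mse:
            config: tuple = ()
            mse = null_mse
        else:
            config = tuple(features.columns[i] for i in nz)
        records.append(
            {"iteration": it, "configuration": config, "mse": mse, "skipped": False}
        )
    iters = pd.DataFrame(records)
    usable = iters[~iters["skipped"]]
    if len(usable) == 0:
        raise DataError("every cross-validation iteration was degenerate")

    counts = usable["configuration"].value_counts()
    eligible = list(counts[counts >= 0.05 * len(usable)].index)
    # rank candidate configurations on a common footing: refit each on every
    # split and average its held-out MSE (avoids the bias of scoring a
    # configuration only on the splits where it happened to be chosen)
    def _cv_mse(config: tuple) -> float:
        idx = [features.columns.get_loc(c) for c in config]
        mses = []
        for train, val in splits:
            if np.ptp(y[train]) == 0:
                continue
            if idx:
                Xt = np.column_stack([np.ones(len(train)), X[train][:, idx]])
                beta = np.linalg.lstsq(Xt, y[train], rcond=None)[0]
                pred = np.column_stack([np.ones(len(val)), X[val][:, idx]]) @ beta
            else:
                pred = np.full(len(val), y[train].mean())
            mses.append(float(np.mean((y[val] - pred) ** 2)))
        return float(np.mean(mses))

    ranked = sorted(
        ((cfg, _cv_mse(cfg)) for cfg in eligible),
        key=lambda kv: (kv[1], len(kv[0])),
    )
    best = ranked[0][0] if ranked else ()

    y_series = performance.loc[common]
    if best:
        Xb = sm.add_constant(features.loc[common, list(best)])
    else:
        Xb = pd.DataFrame({"const": np.ones(n)}, index=common)
    refit = sm.OLS(y_series, Xb).fit()
    iters["n_selected"] = iters["configuration"].map(
        lambda c: len(c) if isinstance(c, tuple) else np.nan
    )
    return FeatureSelectionResult(
        iterations=iters,
        best_configuration=tuple(best),
        refit=refit,
        features=features.loc[common],
        performance=y_series,
    )


def selection_frequency(result: FeatureSelectionResult) -> pd.Series:
    """Fraction of usable CV iterations in which each feature was selected."""
    usable = result.iterations[~result.iterations["skipped"]]
    freqs = {c: 0.0 for c in result.features.columns}
    for config in usable["configuration"]:
        for c in config:
            freqs[c] += 1.0
    return pd.Series(freqs) / len(usable)


def brain_predicted_performance(
    result: FeatureSelectionResult, features: pd.DataFrame | None = None
) -> pd.Series:
    """Performance projected onto the axis of the best brain predictors.

    With no ``features`` argument, the fitted values of the selected model
    are returned; a feature table yields predictions for its rows (every
    selected feature must be present).
    """
    if features is None:
        return pd.Series(
            np.asarray(result.refit.fittedvalues),
            index=result.performance.index,
            name="brain_predicted_performance",
        )
    missing = [c for c in result.best_configuration if c not in features.columns]
    if missing:
        raise DataError(f"feature table lacks selected predictor(s): {missing}")
    X = sm.add_constant(
        features[list(result.best_configuration)], has_constant="add"
    )
    return pd.Series(
        np.asarray(result.refit.predict(X)),
        index=features.index,
        name="brain_predicted_performance",
    )


def map_parameters(brain_pred: pd.Series, parameters: pd.DataFrame):
    """OLS of brain-predicted performance on all model parameters jointly.

    Warns (via the returned diagnostics) when the design is ill-conditioned;
    variance inflation factors are reported alongside the fit.
    """
    common = brain_pred.index.intersection(parameters.dropna().index)
    X = parameters.loc[common].astype(float)
    missing = [c for c in X.columns if X[c].isna().any()]
    if missing:
        raise DataError(f"parameter table has missing values in {missing}")
    Xc = sm.add_constant(X)
    res = sm.OLS(brain_pred.loc[common], Xc).fit()
    cond = float(np.linalg.cond(Xc.to_numpy()))
    Xz = (X - X.mean()) / X.std(ddof=0)
    corr = np.corrcoef(Xz.to_numpy(), rowvar=False)
    vifs = dict(zip(X.columns, np.diag(np.linalg.pinv(corr))))
    return res, {"condition_number": cond, "vif": vifs, "collinear": cond > 1e4}


def anatomical_specificity(
    parameter: pd.Series,
    brain: pd.DataFrame,
    measure: str = "glutamate",
    partial_out: list | None = None,
):
    """Regress a model parameter on one measure's three regional values.

    Fits ``parameter ~ 1 + MFG + IPS + STR`` (for ``measure``).  When
    ``partial_out`` names additional (region, measure) pairs, both sides are
    residualized on them first and the follow-up Spearman correlation between
    the residualized parameter and residualized MFG measure is also returned.
    """
    cols = {}
    for r in MRS_REGIONS:
        sub = brain[(brain["measure"] == measure) & (brain["region"] == r)]
        cols[f"{r}_{measure}"] = sub.set_index("participant")["value"]
    X = pd.DataFrame(cols)
    common = X.dropna().index.intersection(parameter.dropna().index)
    X = X.loc[common]
    y = parameter.loc[common].astype(float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    out = {"ols": res}
    if partial_out:
        Z = pd.DataFrame(
            {
                f"{r}_{m}": brain[(brain["measure"] == m) & (brain["region"] == r)]
                .set_index("participant")["value"]
                for r, m in partial_out
            }
        ).reindex(common)
        if Z.isna().any().any():
            bad = list(Z.columns[Z.isna().any()])
            raise DataError(f"partial_out measures missing for some cases: {bad}")
        Zc = sm.add_constant(Z)
        resid_y = sm.OLS(y, Zc).fit().resid
        resid_x = sm.OLS(X[f"MFG_{measure}"], Zc).fit().resid
        rho, p = stats.spearmanr(resid_x, resid_y)
        out["partial_spearman"] = {"rho": float(rho), "p": float(p)}
    return out


def mediation_acme(
    age: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Average causal mediation effect of age on an outcome via a mediator.

    Product-of-coefficients estimate: a (age -> mediator) times b (mediator ->
    outcome controlling age), with a nonparametric percentile bootstrap CI and
    two-sided p value.  Proportion mediated = indirect / total effect (flagged
    undefined when the total effect is ~0).
    """
    if n_boot < 1000:
        raise DataError("n_boot must be >= 1000 for a stable bootstrap")
    table = pd.DataFrame({"age": age, "m": mediator, "y": outcome}).dropna()
    n = len(table)
    if n < 5:
        raise DataError("too few complete cases for mediation")
    arr = table.to_numpy(dtype=float)

    def paths(d):
        Xa = np.column_stack([np.ones(len(d)), d[:, 0]])
        a = np.linalg.lstsq(Xa, d[:, 1], rcond=None)[0][1]
        Xb = np.column_stack([np.ones(len(d)), d[:, 0], d[:, 1]])
        b = np.linalg.lstsq(Xb, d[:, 2], rcond=None)[0][2]
        total = np.linalg.lstsq(Xa, d[:, 2], rcond=None)[0][1]
        return a * b, total

    acme, total = paths(arr)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = paths(arr[rng.integers(0, n, size=n)])[0]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    out = {
        "acme": float(acme),
        "ci": (float(lo), float(hi)),
        "p": float(min(p, 1.0)),
        "total_effect": float(total),
    }
    if abs(total) < 1e-12:
        out["proportion_mediated"] = np.nan
        out["proportion_defined"] = False
    else:
        out["proportion_mediated"] = float(acme / total)
        out["proportion_defined"] = True
    return out
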