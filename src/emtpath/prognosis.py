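"""Prognostic screening, LASSO-Cox risk modeling and pathological subtyping.

WSI-level pathomics features are screened one at a time with univariate
Cox proportional-hazards models (Wald test on the z-scored feature,
p <= alpha selects).  Selected features enter an L1-penalised Cox model
whose penalty is chosen at the minimum of the cross-validated partial-
likelihood deviance; the linear predictor is the continuous risk score
and the training median dichotomises patients into risk groups.
Independently, z-scored features are reduced by PCA and K-means
clustered into two pathological subtypes, oriented so that subtype 1 is
the stromal-feature-high (poor-prognosis) cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._batch import combat_adjust  # noqa: F401  (pluggable pre-processing hook)


def _check_aligned(features: pd.DataFrame, surv: pd.DataFrame):
    if not features.index.equals(surv.index):
        raise ValueError("features and survival table must be aligned on patients")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be binary")


def univariate_cox_screen(features: pd.DataFrame, surv: pd.DataFrame,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature univariate Cox screen on z-scored features.

    Returns one row per feature with Wald hazard ratio, 95% CI, p-value
    and flags; constant features are skipped with a warning and
    non-converging fits are flagged unconverged (never selected).
    """
    _check_aligned(features, surv)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0 or np.unique(x).size < 2:
            warnings.warn(f"feature {name!r} is constant; skipped")
            rows.append((name, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        z = (x - x.mean()) / sd
        df = pd.DataFrame({"z": z, "time": surv["time"].to_numpy(),
                           "event": surv["event"].to_numpy()})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            coef = float(cph.params_["z"])
            se = float(cph.standard_errors_["z"])
            p = float(cph.summary.loc["z", "p"])
            rows.append((name, coef, np.exp(coef), np.exp(coef - 1.96 * se),
                         np.exp(coef + 1.96 * se), p, True))
        except Exception:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, np.nan, False))
    out = pd.DataFrame(
        rows,
        columns=["feature", "coef", "hazard_ratio", "ci_low", "ci_high",
                 "p_value", "converged"],
    ).set_index("feature")
    out["selected"] = out["converged"] & (out["p_value"] <= alpha)
    return out


@dataclass
class RiskModel:
    """Fitted LASSO-Cox risk model on standardized features."""

    features: list
    coef: pd.Series
    mean: pd.Series
    sd: pd.Series
    penalty: float
    cutoff: float
    cv_deviance: pd.DataFrame

    def score(self, features: pd.DataFrame) -> pd.Series:
        z = (features[self.features] - self.mean) / self.sd
        return z @ self.coef


def _cox_pll(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of linear predictors *lp*."""
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(lp)
    # handle tied times: risk set includes all with time >= t
    pll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        denom = log_cum[j]
        for k in range(i, j + 1):
            if event[k]:
                pll += lp[k] - denom
        i = j + 1
    return pll


def fit_lasso_cox(features: pd.DataFrame, surv: pd.DataFrame,
                  n_folds: int = 10, seed: int = 0,
                  n_alphas: int = 50) -> RiskModel:
    """Fit the L1-penalised Cox risk model with CV penalty choice.

    Features are z-scored; the Coxnet regularisation path supplies
    candidate penalties, scored by K-fold cross-validated partial-
    likelihood deviance (full-minus-train form), and the sparsest
    penalty within one standard error of the deviance minimum is kept
    (one-SE rule).  The model is refitted on all patients; the risk
    cutoff is the training median risk score.
    """
    _check_aligned(features, surv)
    if features.shape[1] < 2:
        raise ValueError("need at least 2 selected features")
    if int(surv["event"].sum()) < 20:
        raise ValueError("need at least 20 events to fit the risk model")

    mean = features.mean()
    sd = features.std(ddof=0).replace(0, 1.0)
    Z = ((features - mean) / sd).to_numpy()
    y = Surv.from_arrays(surv["event"].astype(bool).to_numpy(),
                         surv["time"].to_numpy())

    path_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                        alpha_min_ratio=0.01)
    path_model.fit(Z, y)
    alphas = path_model.alphas_

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(features))
    folds = np.array_split(idx, n_folds)
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()

    dev = np.zeros((n_folds, len(alphas)))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, test_idx)
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                   fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Z[train_idx], y[train_idx])
        # the fold path may stop early; reuse the last fitted column beyond it
        fold_pos = {round(float(x), 12): i for i, x in enumerate(m.alphas_)}
        for a, alpha in enumerate(alphas):
            col = fold_pos.get(round(float(alpha), 12), m.coef_.shape[1] - 1)
            # cross-validated partial likelihood, full-minus-train form
            # (Verweij & van Houwelingen): stabler than test-fold-only
            lp_all = Z @ m.coef_[:, col]
            dev[f, a] = -2 * (_cox_pll(lp_all, time, event)
                              - _cox_pll(lp_all[train_idx], time[train_idx],
                                         event[train_idx]))
    mean_dev = dev.mean(axis=0)
    # one-standard-error rule: the sparsest (largest) penalty whose mean CV
    # deviance is within one SE of the minimum; guards against the noise
    # features that the raw deviance minimum tends to admit
    i_min = int(np.argmin(mean_dev))
    se_min = dev[:, i_min].std(ddof=1) / np.sqrt(n_folds)
    best = int(np.flatnonzero(mean_dev <= mean_dev[i_min] + se_min)[0])
    best_alpha = float(alphas[best])

    coef = pd.Series(path_model.coef_[:, best], index=features.columns)
    if (coef == 0).all():
        raise ValueError("all coefficients shrunk to zero; lower the penalty "
                         "(degenerate model)")
    risk = pd.Series(Z @ coef.to_numpy(), index=features.index)
    cv_table = pd.DataFrame({"alpha": alphas, "mean_deviance": mean_dev})
    return RiskModel(list(features.columns), coef, mean, sd, best_alpha,
                     float(risk.median()), cv_table)


def risk_stratify(model: RiskModel, features: pd.DataFrame,
                  surv: pd.DataFrame):
    """Dichotomise by the model cutoff and test the two risk groups.

    Returns ``(groups, hazard_ratio, (ci_low, ci_high), logrank_p)``;
    groups are labelled so the reported HR (high vs low) is >= 1.
    """
    _check_aligned(features, surv)
    risk = model.score(features)
    groups = pd.Series(np.where(risk > model.cutoff, "high", "low"),
                       index=features.index)
    if groups.nunique() < 2:
        raise ValueError("risk cutoff produces a single group")
    hr, ci, p = _two_group_test(groups, surv)
    if hr < 1:
        groups = groups.map({"high": "low", "low": "high"})
        hr = 1 / hr
        ci = (1 / ci[1], 1 / ci[0])
    return groups, hr, ci, p


def _two_group_test(groups: pd.Series, surv: pd.DataFrame):
    """HR (high vs low), 95% CI and log-rank p for a two-group split."""
    ref = "high" if "high" in set(groups) else sorted(set(groups))[0]
    m = (groups == ref).to_numpy()
    df = pd.DataFrame({"g": m.astype(float), "time": surv["time"].to_numpy(),
                       "event": surv["event"].to_numpy()})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    hr = float(np.exp(coef))
    ci = (float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se)))
    lr = logrank_test(surv.loc[m, "time"], surv.loc[~m, "time"],
                      surv.loc[m, "event"], surv.loc[~m, "event"])
    return hr, ci, float(lr.p_value)


@dataclass
class SubtypeAssignment:
    """Two pathological subtypes from PCA + K-means."""

    labels: pd.Series
    pc_loadings: np.ndarray
    cluster_centers: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_kmeans_subtype(features: pd.DataFrame, n_pcs: int = 10, k: int = 2,
                       seed: int = 0) -> SubtypeAssignment:
    """Cluster patients into two pathological subtypes.

    Features are z-scored (constant columns dropped), reduced to the
    top *n_pcs* principal components by total variance, and K-means
    clustered (10 restarts, fixed seed).  Subtype 1 is the cluster with
    the higher mean of stromal-family (T-S, S-S) features, matching the
    stromal-high / poor-prognosis orientation; when no stromal feature
    is present the cluster with the higher mean first PC is subtype 1.
    """
    if len(features) <= n_pcs:
        raise ValueError("need more samples than principal components")
    sd = features.std(ddof=0)
    keep = sd[sd > 0].index
    Z = (features[keep] - features[keep].mean()) / sd[keep]
    n_pcs = min(n_pcs, Z.shape[1])
    pca = PCA(n_components=n_pcs, random_state=seed)
    pcs = pca.fit_transform(Z.to_numpy())
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(pcs)

    stromal = [c for c in keep if c.startswith(("T-S", "S-S"))]
    if stromal:
        crit = pd.Series(features[stromal].mean(axis=1).to_numpy()).groupby(raw).mean()
    else:
        crit = pd.Series(pcs[:, 0]).groupby(raw).mean()
    order = crit.sort_values(ascending=False).index.to_list()
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=features.index)
    return SubtypeAssignment(labels, pca.components_, km.cluster_centers_,
                             pca.explained_variance_ratio_)


def km_logrank(groups: pd.Series, surv: pd.DataFrame):
    """Kaplan-Meier curves and log-rank test across groups.

    Returns ``(curves, logrank_p, hr, ci)``; the HR and its CI come
    from a two-group Cox fit and are None when there are more than two
    groups.
    """
    _check_aligned(pd.DataFrame(index=groups.index), surv)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    curves = {}
    for lab in labels:
        m = (groups == lab).to_numpy()
        if surv.loc[m, "event"].sum() < 1:
            raise ValueError(f"group {lab!r} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[m, "time"], surv.loc[m, "event"], label=str(lab))
        curves[lab] = kmf.survival_function_
    if len(labels) == 2:
        m = (groups == labels[0]).to_numpy()
        lr = logrank_test(surv.loc[m, "time"], surv.loc[~m, "time"],
                          surv.loc[m, "event"], surv.loc[~m, "event"])
        p = float(lr.p_value)
        df = pd.DataFrame({"g": m.astype(float),
                           "time": surv["time"].to_numpy(),
                           "event": surv["event"].to_numpy()})
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_["g"])
        se = float(cph.standard_errors_["g"])
        hr = float(np.exp(coef))
        ci = (float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se)))
    else:
        mlr = multivariate_logrank_test(surv["time"], groups, surv["event"])
        p, hr, ci = float(mlr.p_value), None, None
    return curves, p, hr, ci
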