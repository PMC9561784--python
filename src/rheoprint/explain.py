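"""Random-forest evaluation and interpretation on a printability table.

Covers the evaluation and explanation toolchain around the classifier:
the printable-class F-score, repeated stratified cross-validation with
out-of-bag scoring, Shapley attributions accumulated across CV repeats,
global/local importance views (waterfalls, dependence, partial dependence),
split-rule threshold mining over every tree, and Spearman correlation
clustering of the selected features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from ._treeshap import forest_shap_values

LABEL = "printable"
NON_FEATURES = (LABEL, "score")


# ---------------------------------------------------------------------------
# F-score (the imbalance-aware per-class metric)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
    )


def f_score(c: ConfusionCounts) -> float:
    """F = TP / (TP + (FP + FN)/2); undefined (raises) when TP=FP=FN=0."""
    denom = c.TP + 0.5 * (c.FP + c.FN)
    if denom == 0:
        raise ValueError("F-score undefined: no positives predicted or present")
    return c.TP / denom


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    per_class: dict[str, dict[str, float]]  # class -> mean/min/max/sd
    oob_mean: float
    fold_scores: pd.DataFrame  # (repeat, fold) x class
    settings: dict = field(default_factory=dict)


def _split_xy(table: pd.DataFrame, label: str = LABEL):
    y = table[label].to_numpy().astype(int)
    X = table.drop(columns=[c for c in NON_FEATURES if c in table.columns])
    return X, y


def _class_f(y_true, y_pred, positive) -> float:
    return f_score(confusion_counts(y_true, y_pred, positive=positive))


def cross_validate(
    table: pd.DataFrame,
    n_repeats: int = 20,
    k: int = 5,
    n_trees: int = 200,
    seed: int = 0,
    label: str = LABEL,
    compute_oob: bool = True,
    n_jobs: int = 1,
) -> CVReport:
    """n-repeated stratified k-fold CV of the 200-tree forest.

    Per-class F-scores are aggregated over all folds x repeats; the OoB
    score comes from forests trained on the full table once per repeat.
    """
    X, y = _split_xy(table, label)
    n_min = min(np.bincount(y))
    if k > n_min:
        raise ValueError(f"k={k} exceeds the minority class count {n_min}")
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=n_repeats, random_state=seed)
    rows = []
    for fold_id, (tr, te) in enumerate(cv.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + 1000 + fold_id, n_jobs=n_jobs
        )
        rf.fit(X.iloc[tr], y[tr])
        pred = rf.predict(X.iloc[te])
        rows.append(
            {
                "repeat": fold_id // k,
                "fold": fold_id % k,
                "printable": _class_f(y[te], pred, 1),
                "not_printable": _class_f(y[te], pred, 0),
            }
        )
    fold_scores = pd.DataFrame(rows)
    per_class = {}
    for cls in ("printable", "not_printable"):
        s = fold_scores[cls]
        per_class[cls] = {
            "mean": float(s.mean()),
            "min": float(s.min()),
            "max": float(s.max()),
            "sd": float(s.std(ddof=1)),
        }
    oob = float("nan")
    if compute_oob:
        oobs = []
        for r in range(n_repeats):
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                oob_score=True,
                bootstrap=True,
                random_state=seed + 2000 + r,
                n_jobs=n_jobs,
            )
            rf.fit(X, y)
            oobs.append(rf.oob_score_)
        oob = float(np.mean(oobs))
    return CVReport(
        per_class=per_class,
        oob_mean=oob,
        fold_scores=fold_scores,
        settings={"n_repeats": n_repeats, "k": k, "n_trees": n_trees, "seed": seed},
    )


# ---------------------------------------------------------------------------
# SHAP accumulation over repeated CV


@dataclass
class ShapMatrix:
    """Per-observation additive attributions, accumulated over repeated CV.

    Every observation is explained only when it sits in a test fold, by that
    fold's trained forest, then averaged over repeats.  Local accuracy
    survives the averaging: ``base_per_obs + values.sum(axis=1)`` equals
    ``prediction`` (the averaged out-of-fold printable probability) to
    floating-point accuracy.
    """

    values: pd.DataFrame  # observations x features, probability units
    base_value: float  # grand mean of the fold models' expected predictions
    base_per_obs: pd.Series  # mean base of the fold models explaining each obs
    prediction: pd.Series  # averaged out-of-fold predicted probability
    X: pd.DataFrame  # feature values of the explained observations
    provenance: pd.DataFrame  # (observation x repeat) -> test-fold index
    max_local_error: float  # worst |base + sum(phi) - p| over single folds


def accumulate_shap(
    table: pd.DataFrame,
    n_repeats: int = 20,
    k: int = 5,
    n_trees: int = 200,
    seed: int = 0,
    label: str = LABEL,
) -> ShapMatrix:
    X, y = _split_xy(table, label)
    n_min = min(np.bincount(y))
    if k > n_min:
        raise ValueError(f"k={k} exceeds the minority class count {n_min}")
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=n_repeats, random_state=seed)
    phi_sum = np.zeros(X.shape)
    pred_sum = np.zeros(len(X))
    base_obs = np.zeros(len(X))
    base_sum = 0.0
    prov = np.full((len(X), n_repeats), -1, dtype=int)
    max_err = 0.0
    for fold_id, (tr, te) in enumerate(cv.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + 1000 + fold_id, n_jobs=1
        )
        rf.fit(X.iloc[tr], y[tr])
        phi, base = forest_shap_values(rf, X.iloc[te].to_numpy())
        p = rf.predict_proba(X.iloc[te])[:, -1]
        max_err = max(max_err, float(np.abs(base + phi.sum(axis=1) - p).max()))
        phi_sum[te] += phi
        pred_sum[te] += p
        base_obs[te] += base
        base_sum += base
        prov[te, fold_id // k] = fold_id % k
    values = pd.DataFrame(phi_sum / n_repeats, index=X.index, columns=X.columns)
    return ShapMatrix(
        values=values,
        base_value=base_sum / (n_repeats * k),
        base_per_obs=pd.Series(base_obs / n_repeats, index=X.index),
        prediction=pd.Series(pred_sum / n_repeats, index=X.index),
        X=X.copy(),
        provenance=pd.DataFrame(
            prov, index=X.index, columns=[f"repeat_{r}" for r in range(n_repeats)]
        ),
        max_local_error=max_err,
    )


def global_importance(shap: ShapMatrix) -> pd.Series:
    """Mean |attribution| per feature, descending; ties broken by name."""
    if shap.values.empty:
        raise ValueError("empty attribution matrix")
    imp = shap.values.abs().mean(axis=0)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order]


def waterfall(shap: ShapMatrix, obs_id) -> pd.DataFrame:
    """Signed contributions of one observation, largest magnitude first.

    The returned frame's ``cumulative`` starts from the base value and ends
    at the model's averaged predicted probability for the observation.
    """
    if obs_id not in shap.values.index:
        raise KeyError(f"unknown observation {obs_id!r}")
    phi = shap.values.loc[obs_id]
    phi = phi[phi != 0.0] if (phi != 0.0).any() else phi.iloc[:0]
    order = sorted(phi.index, key=lambda f: (-abs(phi[f]), f))
    out = pd.DataFrame(
        {
            "feature": order,
            "value": [shap.X.loc[obs_id, f] for f in order],
            "contribution": [phi[f] for f in order],
        }
    )
    base = float(shap.base_per_obs.loc[obs_id])
    out["cumulative"] = base + out["contribution"].cumsum()
    out.attrs["base_value"] = base
    out.attrs["prediction"] = float(shap.prediction.loc[obs_id])
    return out


def _interaction_candidate(shap: ShapMatrix, feature: str) -> str:
    """Pick the color feature whose halves most change the attribution
    pattern of ``feature`` (binned-variance heuristic)."""
    phi = shap.values[feature]
    v = shap.X[feature]
    bins = pd.qcut(v.rank(method="first"), q=min(8, max(2, len(v) // 10)), labels=False)
    resid = phi - phi.groupby(bins).transform("mean")
    best, best_score = None, -np.inf
    for c in shap.X.columns:
        if c == feature:
            continue
        cv = shap.X[c]
        if cv.nunique() < 2:
            continue
        half = (cv > cv.median()).astype(int)
        means = resid.groupby(half).mean()
        score = float(means.var(ddof=0))
        if score > best_score:
            best, best_score = c, score
    return best if best is not None else feature


def shap_dependence(
    shap: ShapMatrix, feature: str, color_feature: str | None = None
) -> pd.DataFrame:
    """(feature value, attribution, color value) per explained observation."""
    if feature not in shap.values.columns:
        raise KeyError(f"unknown feature {feature!r}")
    if color_feature is None:
        color_feature = _interaction_candidate(shap, feature)
    elif color_feature not in shap.X.columns:
        raise KeyError(f"unknown feature {color_feature!r}")
    return pd.DataFrame(
        {
            "value": shap.X[feature],
            "shap": shap.values[feature],
            "color_feature": color_feature,
            "color_value": shap.X[color_feature],
        }
    )


# ---------------------------------------------------------------------------
# partial dependence


def partial_dependence(
    model, X: pd.DataFrame, feature: str, grid_points: int = 20
) -> pd.DataFrame:
    """Average predicted printable probability with the feature forced to
    each grid value (grid = empirical quantiles)."""
    if feature not in X.columns:
        raise KeyError(f"unknown feature {feature!r}")
    qs = np.linspace(0.0, 1.0, grid_points)
    grid = np.unique(np.quantile(X[feature].to_numpy(), qs))
    means = []
    Xm = X.copy()
    for v in grid:
        Xm[feature] = v
        means.append(float(model.predict_proba(Xm)[:, -1].mean()))
    return pd.DataFrame({"value": grid, "mean_probability": means})


# ---------------------------------------------------------------------------
# split-rule mining


@dataclass
class SplitCatalog:
    thresholds: dict[str, np.ndarray]  # feature -> all split thresholds
    n_nodes: dict[str, int]
    total_nodes: int

    def summary(self) -> pd.DataFrame:
        """Tukey box-whisker summary of the mined thresholds per feature."""
        rows = []
        for f, t in self.thresholds.items():
            if t.size == 0:
                continue
            q1, med, q3 = np.percentile(t, [25, 50, 75])
            iqr = q3 - q1
            lo_w = t[t >= q1 - 1.5 * iqr].min()
            hi_w = t[t <= q3 + 1.5 * iqr].max()
            outliers = t[(t < q1 - 1.5 * iqr) | (t > q3 + 1.5 * iqr)]
            rows.append(
                {
                    "feature": f,
                    "n": t.size,
                    "min": float(t.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(t.max()),
                    "whisker_lo": float(lo_w),
                    "whisker_hi": float(hi_w),
                    "n_outliers": int(outliers.size),
                }
            )
        return pd.DataFrame(rows).sort_values("n", ascending=False).reset_index(drop=True)


def mine_split_rules(forest, feature_names=None) -> SplitCatalog:
    """Harvest the split threshold of every internal node of every tree."""
    if not hasattr(forest, "estimators_"):
        raise ValueError("forest must be fitted")
    p = forest.n_features_in_
    names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]
    acc: dict[str, list[float]] = {f: [] for f in names}
    total = 0
    for est in forest.estimators_:
        t = est.tree_
        internal = t.children_left >= 0
        total += int(internal.sum())
        for f_idx, thr in zip(t.feature[internal], t.threshold[internal]):
            acc[names[f_idx]].append(float(thr))
    return SplitCatalog(
        thresholds={f: np.sort(np.array(v)) for f, v in acc.items()},
        n_nodes={f: len(v) for f, v in acc.items()},
        total_nodes=total,
    )


# ---------------------------------------------------------------------------
# Spearman correlation clustering


@dataclass
class CorrelationClustering:
    rho: pd.DataFrame
    linkage: np.ndarray
    clusters: pd.Series  # feature -> cluster id (1 or 2)
    dropped: list[str]


def correlate_cluster(table: pd.DataFrame, features=None, n_clusters: int = 2) -> CorrelationClustering:
    """Spearman correlation matrix with average-linkage clustering.

    Distances are 1 - |rho|; constant features (undefined rank correlation)
    are dropped with a warning.  The tree is cut into two flat clusters,
    matching the two feature families the analysis distinguishes.
    """
    X = table[list(features)] if features is not None else table.drop(
        columns=[c for c in NON_FEATURES if c in table.columns]
    )
    if len(X) < 3:
        raise ValueError("need at least 3 rows")
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant features")
    rho = spearmanr(X.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho_df = pd.DataFrame(rho, index=X.columns, columns=X.columns)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return CorrelationClustering(
        rho=rho_df,
        linkage=Z,
        clusters=pd.Series(flat, index=X.columns),
        dropped=dropped,
    )
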