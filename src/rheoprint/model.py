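"""Model-object interface to the printability classifier.

``PrintabilityModel`` is built from a feature table (one row per
formulation, boolean ``printable`` label); ``fit`` trains the 200-tree
random forest, runs repeated stratified cross-validation and out-of-bag
scoring, and returns a ``PrintabilityResults`` carrying the fitted forest,
the fold-level F-score statistics and every interpretation view (SHAP
accumulation, waterfalls, dependence, partial dependence, split-rule
mining, correlation clustering).

Example
-------
>>> from rheoprint import pipeline
>>> from rheoprint.model import PrintabilityModel
>>> table = ...  # 65-feature table with a 'printable' column
>>> res = PrintabilityModel(table).fit(n_repeats=20, k=5, seed=0)
>>> print(res.summary())
>>> imp = res.global_importance()
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import explain
from .explain import LABEL, CVReport, ShapMatrix
from .selection import StabilitySelection, stability_select


class PrintabilityModel:
    """Random-forest printability classifier over a feature table."""

    def __init__(self, table: pd.DataFrame, label: str = LABEL, n_trees: int = 200):
        if label not in table.columns:
            raise ValueError(f"table lacks the {label!r} label column")
        self.table = table
        self.label = label
        self.n_trees = n_trees
        self.exog_names = [
            c for c in table.columns if c not in (label, "score")
        ]

    @classmethod
    def from_cohort(cls, cohort, scores: pd.DataFrame, seed: int | None = None, **kw):
        """Build the model straight from a synthetic cohort and its scores."""
        from .features import build_feature_table

        return cls(build_feature_table(cohort, scores, seed=seed), **kw)

    def select_features(self, n_iterations: int = 500, gate: float = 0.80,
                        seed: int = 0, **kw) -> StabilitySelection:
        """Balanced-subsample Boruta stability selection on this table."""
        return stability_select(
            self.table, n_iterations=n_iterations, gate=gate, seed=seed,
            label=self.label, **kw
        )

    def refined(self, selection: StabilitySelection) -> "PrintabilityModel":
        """New model restricted to the selected features."""
        cols = selection.selected + [c for c in ("score", self.label) if c in self.table]
        return PrintabilityModel(self.table[cols], label=self.label, n_trees=self.n_trees)

    def fit(self, n_repeats: int = 20, k: int = 5, seed: int = 0,
            compute_oob: bool = True) -> "PrintabilityResults":
        cv = explain.cross_validate(
            self.table, n_repeats=n_repeats, k=k, n_trees=self.n_trees,
            seed=seed, label=self.label, compute_oob=compute_oob,
        )
        X, y = explain._split_xy(self.table, self.label)
        forest = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=seed, n_jobs=1
        ).fit(X, y)
        return PrintabilityResults(self, forest, cv, seed=seed)


class PrintabilityResults:
    """Fitted forest plus cross-validated diagnostics and explanations."""

    def __init__(self, model: PrintabilityModel, forest: RandomForestClassifier,
                 cv_report: CVReport, seed: int = 0):
        self.model = model
        self.forest_ = forest
        self.cv_report = cv_report
        self.oob_ = cv_report.oob_mean
        self.seed = seed
        self._shap: ShapMatrix | None = None

    # -- diagnostics -------------------------------------------------------

    def summary(self) -> str:
        """Text summary of the cross-validated classifier performance."""
        cv = self.cv_report
        s = StringIO()
        n_rows = len(self.model.table)
        prev = float(self.model.table[self.model.label].mean())
        s.write("Printability random-forest classifier\n")
        s.write("=" * 62 + "\n")
        s.write(f"{'No. observations:':<28}{n_rows:>10}\n")
        s.write(f"{'No. features:':<28}{len(self.model.exog_names):>10}\n")
        s.write(f"{'Printable prevalence:':<28}{prev:>10.3f}\n")
        s.write(f"{'Trees:':<28}{self.model.n_trees:>10}\n")
        st = cv.settings
        s.write(f"{'CV:':<28}{st['n_repeats']:>6} x {st['k']}-fold\n")
        s.write("-" * 62 + "\n")
        s.write(f"{'class':<16}{'F mean':>9}{'min':>9}{'max':>9}{'sd':>9}\n")
        for cls, row in cv.per_class.items():
            s.write(
                f"{cls:<16}{row['mean']:>9.3f}{row['min']:>9.3f}"
                f"{row['max']:>9.3f}{row['sd']:>9.3f}\n"
            )
        s.write("-" * 62 + "\n")
        s.write(f"{'Mean OoB score:':<28}{self.oob_:>10.3f}\n")
        return s.getvalue()

    # -- explanations ------------------------------------------------------

    def accumulate_shap(self, n_repeats: int | None = None, k: int | None = None,
                        seed: int | None = None) -> ShapMatrix:
        """SHAP attributions accumulated over the same CV scheme (cached)."""
        if self._shap is None:
            st = self.cv_report.settings
            self._shap = explain.accumulate_shap(
                self.model.table,
                n_repeats=n_repeats or st["n_repeats"],
                k=k or st["k"],
                n_trees=self.model.n_trees,
                seed=self.seed if seed is None else seed,
                label=self.model.label,
            )
        return self._shap

    def global_importance(self) -> pd.Series:
        return explain.global_importance(self.accumulate_shap())

    def waterfall(self, obs_id) -> pd.DataFrame:
        return explain.waterfall(self.accumulate_shap(), obs_id)

    def dependence(self, feature: str, color_feature: str | None = None) -> pd.DataFrame:
        return explain.shap_dependence(self.accumulate_shap(), feature, color_feature)

    def partial_dependence(self, feature: str, grid_points: int = 20) -> pd.DataFrame:
        X, _ = explain._split_xy(self.model.table, self.model.label)
        return explain.partial_dependence(self.forest_, X, feature, grid_points)

    def split_catalog(self) -> explain.SplitCatalog:
        return explain.mine_split_rules(self.forest_, self.model.exog_names)

    def correlation_clusters(self, features=None) -> explain.CorrelationClustering:
        return explain.correlate_cluster(self.model.table, features)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict_proba(X[self.model.exog_names])[:, -1]
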