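"""Boruta all-relevant feature selection and its balanced-subsample wrapper.

Boruta compares each real feature's random-forest importance against the
maximum importance of "shadow" features (independently permuted copies of
every column) over many iterations; features whose hit counts fall in the
upper tail of the Binomial(iterations, 1/2) null at ``alpha`` are confirmed,
lower-tail features rejected, the rest left tentative.

The stability wrapper addresses class imbalance: each iteration draws a
75:25 not-printable:printable subsample (every minority row plus three times
as many majority rows), trains a 200-tree forest on a stratified 80/20
split, and only when the held-out printable-class F-score clears the
admission gate does a Boruta screening run on that subsample and contribute
to the per-feature confirmation frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .explain import confusion_counts, f_score

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass
class BorutaOutcome:
    status: dict[str, str]  # feature -> confirmed | rejected | tentative
    hits: dict[str, int]
    iterations: int
    alpha: float

    @property
    def confirmed(self) -> list[str]:
        return [f for f, s in self.status.items() if s == CONFIRMED]

    @property
    def rejected(self) -> list[str]:
        return [f for f, s in self.status.items() if s == REJECTED]


def boruta(
    X: pd.DataFrame,
    y: np.ndarray,
    max_iter: int = 50,
    alpha: float = 0.005,
    seed: int = 0,
    n_estimators: int = 60,
    max_depth: int | None = 7,
    n_jobs: int = 1,
) -> BorutaOutcome:
    """Run the Boruta shadow-feature screening on a feature matrix.

    Each iteration appends an independently permuted shadow copy of every
    column, fits a random forest, and credits a hit to every real feature
    whose impurity importance exceeds the maximum shadow importance.
    Deterministic given ``seed``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    if X.isna().any().any():
        raise ValueError("X must not contain missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if max_iter < 10:
        raise ValueError("max_iter must be at least 10")
    names = list(X.columns)
    p = len(names)
    vals = X.to_numpy(dtype=float)
    hits = np.zeros(p, dtype=int)
    root = np.random.SeedSequence([seed, 0x80F5])
    for it, ss in enumerate(root.spawn(max_iter)):
        rng = np.random.default_rng(ss)
        shadow = vals.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        both = np.hstack([vals, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            class_weight="balanced",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=n_jobs,
        )
        rf.fit(both, y)
        imp = rf.feature_importances_
        hits += imp[:p] > imp[p:].max()
    upper = binom.sf(hits - 1, max_iter, 0.5) < alpha  # P(H >= hits) under null
    lower = binom.cdf(hits, max_iter, 0.5) < alpha
    status = {}
    for j, name in enumerate(names):
        status[name] = CONFIRMED if upper[j] else REJECTED if lower[j] else TENTATIVE
    return BorutaOutcome(
        status=status,
        hits={n: int(h) for n, h in zip(names, hits)},
        iterations=max_iter,
        alpha=alpha,
    )


@dataclass
class StabilitySelection:
    frequency: pd.Series  # per-feature confirmation frequency over successes
    selected: list[str]
    attempts: int
    successful_iterations: int
    settings: dict = field(default_factory=dict)


def stability_select(
    table: pd.DataFrame,
    n_iterations: int = 500,
    gate: float = 0.80,
    seed: int = 0,
    cutoff: float = 0.5,
    label: str = "printable",
    n_trees: int = 200,
    boruta_iter: int = 12,
    boruta_trees: int = 40,
    majority_ratio: int = 3,
    n_jobs: int = 1,
) -> StabilitySelection:
    """Iterated balanced-subsample Boruta selection with an F-score gate.

    Frequencies are computed over gate-passing (successful) iterations only;
    ``selected`` are the features confirmed in at least ``cutoff`` of them.
    Zero successful iterations yield an empty selection with the status
    reported explicitly in the result.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    y = table[label].to_numpy().astype(int)
    X = table.drop(columns=[label, "score"], errors="ignore")
    feat_names = list(X.columns)
    if len(np.unique(y)) < 2:
        raise ValueError("table must contain both classes")
    minority = np.flatnonzero(y == 1)
    majority = np.flatnonzero(y == 0)
    n_maj = min(majority_ratio * len(minority), len(majority))
    counts = pd.Series(0, index=feat_names, dtype=int)
    successes = 0
    root = np.random.SeedSequence([seed, 0x5EED])
    for it, ss in enumerate(root.spawn(n_iterations)):
        rng = np.random.default_rng(ss)
        idx = np.concatenate([minority, rng.choice(majority, size=n_maj, replace=False)])
        Xs = X.iloc[idx]
        ys = y[idx]
        itrain, itest = train_test_split(
            np.arange(len(idx)),
            test_size=0.2,
            stratify=ys,
            random_state=int(rng.integers(2**31 - 1)),
        )
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=n_jobs,
        )
        rf.fit(Xs.iloc[itrain], ys[itrain])
        pred = rf.predict(Xs.iloc[itest])
        cm = confusion_counts(ys[itest], pred)
        score = f_score(cm) if (cm.TP + cm.FP + cm.FN) > 0 else 0.0
        if score > gate:
            out = boruta(
                Xs,
                ys,
                max_iter=boruta_iter,
                seed=int(rng.integers(2**31 - 1)),
                n_estimators=boruta_trees,
                n_jobs=n_jobs,
            )
            successes += 1
            for name in out.confirmed:
                counts[name] += 1
    if successes > 0:
        freq = counts / successes
        selected = [f for f in feat_names if freq[f] >= cutoff]
    else:
        freq = counts.astype(float)
        selected = []
    return StabilitySelection(
        frequency=freq,
        selected=selected,
        attempts=n_iterations,
        successful_iterations=successes,
        settings={
            "n_iterations": n_iterations,
            "gate": gate,
            "cutoff": cutoff,
            "seed": seed,
            "n_trees": n_trees,
            "boruta_iter": boruta_iter,
            "boruta_trees": boruta_trees,
            "majority_ratio": majority_ratio,
        },
    )
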