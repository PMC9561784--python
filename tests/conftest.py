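import numpy as np
import pandas as pd
import pytest

from rheoprint.features import build_feature_table
from rheoprint.grid import build_grid_design, difficulty_weights, score_print
from rheoprint.synthetic import GeneratorConfig, sample_cohort


def score_cohort(cohort) -> pd.DataFrame:
    """Score every mask of a cohort into the (id, score, printable) frame."""
    weights = difficulty_weights(cohort.design)
    rows = []
    for f in cohort.formulations:
        res = score_print(cohort.records[f.id].mask, cohort.design, weights)
        rows.append({"id": f.id, "score": res.score, "printable": res.printable})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def design():
    return build_grid_design()


@pytest.fixture(scope="session")
def small_cohort():
    """Small noiseless, jitter-free cohort: curve shapes hold exactly."""
    cfg = GeneratorConfig(noise_sd=0.0, latent_jitter_sd=0.0)
    return sample_cohort(30, seed=5, config=cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort at the study scale (180 formulations)."""
    return sample_cohort(180, seed=21)


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return build_feature_table(default_cohort, score_cohort(default_cohort), seed=21)


@pytest.fixture(scope="session")
def planted_forest(default_table):
    """200-tree forest trained on the full default table."""
    from sklearn.ensemble import RandomForestClassifier

    X = default_table.drop(columns=["score", "printable"])
    y = default_table["printable"].astype(int)
    return RandomForestClassifier(n_estimators=200, random_state=0, n_jobs=1).fit(X, y), X, y


def toy_table(n=120, p=6, seed=0, informative=2) -> pd.DataFrame:
    """Small separable table for fast classifier tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    margin = X[:, :informative].sum(axis=1)
    y = margin + 0.3 * rng.normal(size=n) > 0.8
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df.index = [f"F{i:04d}" for i in range(n)]
    df.index.name = "id"
    df["score"] = 0.5
    df["printable"] = y
    return df
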