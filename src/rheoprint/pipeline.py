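"""Configuration-driven orchestration of the five analysis stages.

simulate -> score -> extract -> select -> explain

Each stage reads its inputs from the run directory and writes its artifacts
there; every artifact embeds the configuration hash and the stage seed.
Stage seeds fan out deterministically from the master seed, so a rerun with
the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, explain
from .features import KEY_FEATURES, build_feature_table_from_parts, write_schema
from .grid import build_grid_design, difficulty_weights, score_print
from .io import read_cohort_parts, read_mask, write_cohort
from .model import PrintabilityModel
from .selection import stability_select
from .synthetic import GeneratorConfig, sample_cohort

log = logging.getLogger("rheoprint")

STAGES = ("simulate", "score", "extract", "select", "explain")


@dataclass
class PipelineConfig:
    master_seed: int = 1
    out_dir: str = "runs/default"
    n_formulations: int = 180
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grid_di_um: float = 410.0
    grid_multipliers: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    grid_pixel_size_um: float = 10.0
    select_iterations: int = 500
    select_gate: float = 0.80
    select_cutoff: float = 0.5
    cv_repeats: int = 20
    cv_k: int = 5
    n_trees: int = 200
    shap_repeats: int = 5
    n_jobs: int = 1

    def design(self):
        return build_grid_design(
            self.grid_di_um, self.grid_multipliers, self.grid_pixel_size_um
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_multipliers"] = list(self.grid_multipliers)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific settings (where the run is written and how
        many workers it uses do not change the result)."""
        d = self.to_dict()
        d.pop("out_dir")
        d.pop("n_jobs")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        gen = GeneratorConfig(**raw.pop("generator", {}))
        grid = raw.pop("grid", {})
        kw = dict(raw.pop("pipeline", {}), **raw)
        for key, name in (
            ("di_um", "grid_di_um"),
            ("multipliers", "grid_multipliers"),
            ("pixel_size_um", "grid_pixel_size_um"),
        ):
            if key in grid:
                kw[name] = grid[key]
        cfg = cls(generator=gen, **kw)
        return dataclasses.replace(
            cfg, grid_multipliers=tuple(cfg.grid_multipliers)
        )


DEFAULT_TOML = """\
# rheoprint pipeline configuration
[pipeline]
master_seed = 1
out_dir = "runs/default"
n_formulations = 180
select_iterations = 500
select_gate = 0.80
select_cutoff = 0.5
cv_repeats = 20
cv_k = 5
n_trees = 200
shap_repeats = 5

[generator]
noise_sd = 0.02
latent_jitter_sd = 0.15
spread_constant = 1.98

[grid]
di_um = 410.0
multipliers = [1, 2, 3, 4, 5, 6]
pixel_size_um = 10.0
"""


def _meta(config: PipelineConfig, stage: str) -> dict:
    return {
        "config_hash": config.config_hash(),
        "stage_seed": config.stage_seed(stage),
        "version": __version__,
    }


def _csv_header(config: PipelineConfig, stage: str) -> str:
    m = _meta(config, stage)
    return f"config_hash={m['config_hash']} stage_seed={m['stage_seed']}"


def _write_json(path: Path, payload: dict, config: PipelineConfig, stage: str) -> None:
    payload = {"meta": _meta(config, stage), **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_csv(frame: pd.DataFrame, path: Path, config: PipelineConfig, stage: str,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_csv_header(config, stage)}\n")
        frame.to_csv(fh, index=index)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing input artifact: {path}"
        )
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, run_dir: Path) -> None:
    seed = config.stage_seed("simulate")
    cohort = sample_cohort(config.n_formulations, seed, config.generator, config.design())
    write_cohort(cohort, run_dir / "cohort", header=_csv_header(config, "simulate"))
    log.info("simulate: %d formulations (seed %d)", config.n_formulations, seed)


def stage_score(config: PipelineConfig, run_dir: Path) -> None:
    design = config.design()
    weights = difficulty_weights(design)
    masks_dir = _require(run_dir / "cohort" / "masks", "score")
    manifest = pd.read_csv(_require(run_dir / "cohort" / "formulations.csv", "score"), comment="#")
    rows = []
    for ident in manifest["id"]:
        res = score_print(read_mask(masks_dir / f"{ident}.png"), design, weights)
        row = {"id": ident, "score": res.score, "printable": res.printable}
        for i, (m, r) in enumerate(zip(res.multipliers, res.resolved)):
            row[f"r_cell{i:02d}_m{m}"] = r
        rows.append(row)
    _write_csv(pd.DataFrame(rows), run_dir / "scores.csv", config, "score", index=False)
    log.info("score: %d masks scored", len(rows))


def stage_extract(config: PipelineConfig, run_dir: Path) -> None:
    seed = config.stage_seed("extract")
    pairs, bundles, base_bundles, records = read_cohort_parts(
        _require(run_dir / "cohort", "extract")
    )
    scores = pd.read_csv(_require(run_dir / "scores.csv", "extract"), comment="#")
    table = build_feature_table_from_parts(
        pairs, bundles, base_bundles, records, scores, seed=seed
    )
    _write_csv(table, run_dir / "features.csv", config, "extract")
    write_schema(run_dir / "schema.json")
    log.info("extract: %d x %d feature table", len(table), table.shape[1] - 2)


def stage_select(config: PipelineConfig, run_dir: Path) -> None:
    seed = config.stage_seed("select")
    table = pd.read_csv(
        _require(run_dir / "features.csv", "select"), comment="#", index_col="id"
    )
    sel = stability_select(
        table,
        n_iterations=config.select_iterations,
        gate=config.select_gate,
        cutoff=config.select_cutoff,
        seed=seed,
        n_trees=config.n_trees,
        n_jobs=config.n_jobs,
    )
    _write_json(
        run_dir / "selection.json",
        {
            "settings": sel.settings,
            "attempts": sel.attempts,
            "successful_iterations": sel.successful_iterations,
            "frequency": sel.frequency.round(6).to_dict(),
            "selected": sel.selected,
        },
        config,
        "select",
    )
    kept = sel.selected
    if not kept:  # nothing confirmed: keep the full table so later stages run
        log.warning("select: empty selection, refined table keeps all features")
        kept = [c for c in table.columns if c not in ("score", "printable")]
    refined = table[kept + ["score", "printable"]]
    _write_csv(refined, run_dir / "features_refined.csv", config, "select")
    log.info(
        "select: %d/%d iterations passed the gate, %d features selected",
        sel.successful_iterations, sel.attempts, len(sel.selected),
    )


def stage_explain(config: PipelineConfig, run_dir: Path) -> None:
    seed = config.stage_seed("explain")
    refined = pd.read_csv(
        _require(run_dir / "features_refined.csv", "explain"), comment="#", index_col="id"
    )
    model = PrintabilityModel(refined, n_trees=config.n_trees)
    res = model.fit(n_repeats=config.cv_repeats, k=config.cv_k, seed=seed)
    cv = res.cv_report
    _write_json(
        run_dir / "cv_report.json",
        {"per_class": cv.per_class, "oob_mean": cv.oob_mean, "settings": cv.settings},
        config,
        "explain",
    )
    shap = res.accumulate_shap(n_repeats=config.shap_repeats)
    _write_csv(shap.values, run_dir / "shap_values.csv", config, "explain")
    imp = explain.global_importance(shap)
    _write_csv(imp.rename("mean_abs_shap").to_frame(), run_dir / "importance.csv", config, "explain")
    cat = res.split_catalog()
    _write_json(
        run_dir / "split_catalog.json",
        {
            "total_nodes": cat.total_nodes,
            "n_nodes": cat.n_nodes,
            "summary": cat.summary().to_dict(orient="records"),
        },
        config,
        "explain",
    )
    clus = res.correlation_clusters()
    _write_json(
        run_dir / "clusters.json",
        {
            "clusters": clus.clusters.to_dict(),
            "dropped": clus.dropped,
            "rho": clus.rho.round(6).to_dict(),
        },
        config,
        "explain",
    )
    # plot-ready data
    beeswarm = shap.values.reset_index().melt(
        id_vars="id", var_name="feature", value_name="shap"
    )
    feat_vals = shap.X.reset_index().melt(
        id_vars="id", var_name="feature", value_name="value"
    )
    beeswarm = beeswarm.merge(feat_vals, on=["id", "feature"])
    _write_csv(beeswarm, run_dir / "beeswarm.csv", config, "explain", index=False)
    top_obs = shap.prediction.idxmax()
    _write_csv(explain.waterfall(shap, top_obs), run_dir / "waterfall.csv", config, "explain", index=False)
    X = shap.X
    for feat in imp.index[:4]:
        dep = explain.shap_dependence(shap, feat)
        _write_csv(dep, run_dir / f"dependence_{feat}.csv", config, "explain")
        pdp = explain.partial_dependence(res.forest_, X, feat)
        _write_csv(pdp, run_dir / f"pd_{feat}.csv", config, "explain", index=False)
    with open(run_dir / "summary.txt", "w") as fh:
        fh.write(res.summary())
    log.info("explain: CV printable F %.3f, OoB %.3f",
             cv.per_class["printable"]["mean"], cv.oob_mean)


def write_report(config: PipelineConfig, run_dir: Path) -> dict:
    """Aggregate the per-stage artifacts into ``report.json``."""
    features = pd.read_csv(run_dir / "features.csv", comment="#", index_col="id")
    with open(run_dir / "selection.json") as fh:
        selection = json.load(fh)
    with open(run_dir / "cv_report.json") as fh:
        cv = json.load(fh)
    imp = pd.read_csv(run_dir / "importance.csv", comment="#", index_col=0)
    selected = selection["selected"]
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "n_formulations": int(len(features)),
        "prevalence": float(features["printable"].mean()),
        "n_selected": len(selected),
        "selected_features": selected,
        "selected_key_features": sorted(set(selected) & set(KEY_FEATURES)),
        "successful_iterations": selection["successful_iterations"],
        "cv": {"per_class": cv["per_class"], "oob_mean": cv["oob_mean"]},
        "top_importance": imp["mean_abs_shap"].head(10).round(6).to_dict(),
    }
    with open(run_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "score": stage_score,
    "extract": stage_extract,
    "select": stage_select,
    "explain": stage_explain,
}


def run(config: PipelineConfig, stages=None) -> dict | None:
    """Run the requested stages in order; returns the aggregated report when
    the explain stage completes."""
    chosen = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for stage in chosen:
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](config, run_dir)
        log.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    if "explain" in chosen:
        return write_report(config, run_dir)
    return None
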