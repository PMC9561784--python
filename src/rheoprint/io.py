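"""Cohort directory layout and tidy-CSV readers/writers.

A cohort directory holds ``formulations.csv`` (print observations plus
``truth_``-prefixed hidden generator columns that never enter modeling),
one tidy long CSV per rheology test step under ``rheology/`` and
``bases/`` (columns: step, x_name, x_value, y_name, y_value), and binary
grid masks as 8-bit PNGs under ``masks/``.  Real rheometer exports in the
same tidy layout are read identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, PngImagePlugin

from .synthetic import Cohort, PrintRecord, RheologyBundle

_STEPS = {
    "freq_sweep": ("omega_rad_s", [("g_prime_pa", "freq_gp"), ("g_double_prime_pa", "freq_gpp")]),
    "amp_sweep": ("strain_pct", [("g_prime_pa", "amp_gp"), ("g_double_prime_pa", "amp_gpp")]),
    "stress_ramp": ("sigma_pa", [("eta_pa_s", "stress_eta")]),
    "flow_curve": ("gdot_1_s", [("eta_pa_s", "flow_eta")]),
    "itt": ("time_s", [("recovery_pct", "itt_recovery")]),
    "iot": ("time_s", [("recovery_pct", "iot_recovery")]),
}
_X_ATTR = {
    "freq_sweep": "freq_omega",
    "amp_sweep": "amp_gamma",
    "stress_ramp": "stress_sigma",
    "flow_curve": "flow_gdot",
}


def _bundle_frames(bundle: RheologyBundle) -> dict[str, pd.DataFrame]:
    from .synthetic import RECOVERY_TIMES

    frames = {}
    for step, (x_name, ys) in _STEPS.items():
        x = getattr(bundle, _X_ATTR[step]) if step in _X_ATTR else RECOVERY_TIMES
        parts = []
        for y_name, attr in ys:
            parts.append(
                pd.DataFrame(
                    {
                        "step": step,
                        "x_name": x_name,
                        "x_value": x,
                        "y_name": y_name,
                        "y_value": getattr(bundle, attr),
                    }
                )
            )
        frames[step] = pd.concat(parts, ignore_index=True)
    return frames


def write_bundle(bundle: RheologyBundle, directory: Path, ident: str, header: str = "") -> None:
    directory.mkdir(parents=True, exist_ok=True)
    for step, frame in _bundle_frames(bundle).items():
        path = directory / f"{ident}__{step}.csv"
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            frame.to_csv(fh, index=False)


def read_bundle(directory: Path, ident: str) -> RheologyBundle:
    data = {}
    for step, (x_name, ys) in _STEPS.items():
        frame = pd.read_csv(directory / f"{ident}__{step}.csv", comment="#")
        for y_name, attr in ys:
            sel = frame[frame["y_name"] == y_name]
            data[attr] = sel["y_value"].to_numpy()
            if step in _X_ATTR:
                data[_X_ATTR[step]] = sel["x_value"].to_numpy()
    return RheologyBundle(**data)


def write_mask(mask: np.ndarray, path: Path, header: str = "") -> None:
    img = Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8), mode="L")
    info = PngImagePlugin.PngInfo()
    if header:
        info.add_text("provenance", header)
    img.save(path, pnginfo=info)


def read_mask(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 0


def write_cohort(cohort: Cohort, directory: Path, header: str = "") -> None:
    """Write the full cohort directory (curves, masks, print observations)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in cohort.formulations:
        rec = cohort.records[f.id]
        rows.append(
            {
                "id": f.id,
                "base_id": f.base_id,
                "pressure_kpa": rec.pressure,
                "mass_rate_mg_s": rec.mass_rate,
                "filament_formed": rec.filament_formed,
                # hidden generator truths, flagged and excluded from modeling
                "truth_S": f.S,
                "truth_spread_um": f.spread,
                "truth_filament_p": f.filament_p,
                "truth_sigma_y": f.sigma_y if f.sigma_y is not None else np.nan,
                "truth_eta_peak": f.eta_peak,
                "truth_lambda_cy": f.lambda_cy,
            }
        )
    with open(directory / "formulations.csv", "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    for f in cohort.formulations:
        write_bundle(cohort.bundles[f.id], directory / "rheology", f.id, header)
        write_bundle(cohort.base_bundles[f.base_id], directory / "bases", f.base_id, header)
    (directory / "masks").mkdir(exist_ok=True)
    for f in cohort.formulations:
        write_mask(cohort.records[f.id].mask, directory / "masks" / f"{f.id}.png", header)


def read_cohort_parts(directory: Path):
    """Load a cohort directory into the pieces feature extraction needs:
    (id, base_id) pairs, bundles, base bundles and print records."""
    directory = Path(directory)
    manifest = directory / "formulations.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"missing cohort manifest: {manifest}")
    frame = pd.read_csv(manifest, comment="#")
    pairs = list(zip(frame["id"], frame["base_id"]))
    bundles = {i: read_bundle(directory / "rheology", i) for i, _ in pairs}
    base_bundles = {b: read_bundle(directory / "bases", b) for _, b in pairs}
    records = {}
    for row in frame.itertuples():
        records[row.id] = PrintRecord(
            pressure=float(row.pressure_kpa),
            mass_rate=float(row.mass_rate_mg_s),
            filament_formed=bool(row.filament_formed),
            mask=read_mask(directory / "masks" / f"{row.id}.png"),
        )
    return pairs, bundles, base_bundles, records
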