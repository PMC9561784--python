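"""Extraction of the 65-feature vector from a rheology bundle.

Features come in three kinds, mirroring how formulation screening data are
usually tabulated: primary features read off the individual test curves
(clipped to the trustworthy 1-10 rad/s and 0.1-100 % strain windows),
ratio-to-base (``_rel``) counterparts dividing each formulation value by the
matched base-polymer value, and one combinatorial elasticity feature that
mixes the formulation's flow-point modulus with the base's low-strain
stiffness.  Missing yield peaks and missing flow points are imputed as 0
with a paired indicator column so tree models can split on missingness
without losing rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic import Cohort, PrintRecord, RheologyBundle, carreau_yasuda

FREQ_CLIP = (1.0, 10.0)  # rad/s
STRAIN_CLIP = (0.1, 100.0)  # %
TAN_DELTA_STRAINS = (14.8, 21.7, 68.5, 100.0)  # % strain
LVE_TOL = 0.05  # G' drop from plateau defining the LVE limit
PEAK_PROMINENCE = 1.10  # smoothed max must exceed the first ramp sample by 10%

#: canonical 65-column order; frozen — tests pin this list.
PRIMARY_FEATURES = [
    "freq_gprime_1rad",
    "freq_gprime_10rad",
    "freq_gdprime_1rad",
    "freq_gdprime_10rad",
    "freq_tand_1rad",
    "freq_tand_10rad",
    "freq_tand_ratio_1_10",
    "freq_gprime_slope",
    "freq_gstar_1rad",
    "amp_gprime_lve",
    "amp_lve_limit",
    "amp_flow_strain",
    "amp_gprime_flow",
    "amp_plasticity",
    "amp_tand_14p8",
    "amp_tand_21p7",
    "amp_tand_68p5",
    "amp_tand_100",
    "amp_gprime_01",
    "amp_flow_missing",
    "amp_elastic_comb",
    "cy_eta0",
    "cy_eta_inf",
    "cy_lambda",
    "cy_a",
    "cy_n",
    "yield_sigma_peak",
    "yield_eta_peak",
    "yield_missing",
    "itt_rec_5s",
    "itt_rec_10s",
    "itt_rec_30s",
    "iot_rec_5s",
    "iot_rec_10s",
    "iot_rec_30s",
    "print_flow_prop",
    "print_filament",
]

#: primary features that get a ratio-to-base counterpart
RATIOED_FEATURES = [
    "freq_gprime_1rad",
    "freq_gprime_10rad",
    "freq_gdprime_1rad",
    "freq_gdprime_10rad",
    "freq_tand_1rad",
    "freq_tand_10rad",
    "amp_gprime_lve",
    "amp_lve_limit",
    "amp_flow_strain",
    "amp_gprime_flow",
    "amp_plasticity",
    "amp_tand_14p8",
    "amp_tand_21p7",
    "amp_tand_68p5",
    "amp_tand_100",
    "cy_eta0",
    "cy_eta_inf",
    "cy_lambda",
    "cy_a",
    "cy_n",
    "yield_sigma_peak",
    "yield_eta_peak",
    "itt_rec_5s",
    "itt_rec_10s",
    "itt_rec_30s",
    "iot_rec_5s",
    "iot_rec_10s",
    "iot_rec_30s",
]

FEATURE_SCHEMA = PRIMARY_FEATURES + [f + "_rel" for f in RATIOED_FEATURES]
assert len(FEATURE_SCHEMA) == 65

#: the 13 features the planted cohort structure makes informative
KEY_FEATURES = [
    "yield_eta_peak",
    "amp_plasticity",
    "cy_lambda",
    "print_flow_prop",
    "print_filament",
    "amp_tand_14p8",
    "amp_tand_21p7",
    "amp_tand_68p5",
    "amp_tand_100",
    "amp_flow_strain",
    "amp_lve_limit",
    "freq_tand_ratio_1_10",
    "amp_elastic_comb",
]


# ---------------------------------------------------------------------------
# Carreau-Yasuda fitting


@dataclass
class CarreauYasudaFit:
    eta0: float
    eta_inf: float
    lambda_cy: float
    a_cy: float
    n_cy: float
    rel_residual: float  # RMS of log-viscosity residuals
    at_boundary: bool  # some parameter pinned at a fit bound


def _loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(np.log(x), np.log(y), 1)[0])


def fit_carreau_yasuda(gdot, eta) -> CarreauYasudaFit:
    """Least-squares Carreau-Yasuda fit in log-viscosity space.

    eta(gdot) = eta_inf + (eta0 - eta_inf) [1 + (lam gdot)^a]^((n-1)/a)

    Deterministic: a fixed set of data-driven starts is polished and the
    lowest-cost solution returned.  A constant-viscosity (Newtonian) curve is
    returned directly with ``eta0 == eta_inf`` and the boundary flag set.
    """
    gdot = np.asarray(gdot, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if gdot.size < 8:
        raise ValueError("need at least 8 flow-curve points")
    if np.any(np.diff(gdot) <= 0):
        raise ValueError("shear rates must be strictly increasing")
    if np.any(eta <= 0):
        raise ValueError("viscosities must be positive")
    log_eta = np.log(eta)
    if np.ptp(log_eta) < 1e-6:
        m = float(eta.mean())
        return CarreauYasudaFit(m, m, 1.0 / gdot[-1], 2.0, 1.0, float(np.std(log_eta)), True)

    lo = np.array([math.log(eta.max() * 0.2), math.log(1e-8), math.log(1e-3 / gdot[-1]), math.log(0.1), math.log(0.01)])
    hi = np.array([math.log(eta.max() * 50.0), math.log(eta.min() * 0.999), math.log(1e3 / gdot[0]), math.log(10.0), 0.0])

    def resid(x):
        e0, ei, lam, a, n = np.exp(x)
        return np.log(carreau_yasuda(gdot, e0, ei, lam, a, n)) - log_eta

    # data-driven start: terminal slope gives n, the half-decay point gives lam
    n0 = min(max(1.0 + _loglog_slope(gdot[-6:], eta[-6:]), 0.02), 0.95)
    mid = math.sqrt(eta.max() * eta.min())
    i_mid = int(np.argmin(np.abs(eta - mid)))
    lam0 = 1.0 / gdot[i_mid]
    starts = [
        [eta[0] * 1.05, eta.min() * 1e-3, lam0, 2.0, n0],
        [eta[0] * 1.05, eta.min() * 1e-2, lam0 * 5.0, 1.0, n0],
        [eta[0] * 2.0, eta.min() * 1e-3, lam0 / 5.0, 4.0, 0.5],
    ]
    best = None
    for s in starts:
        x0 = np.clip(np.log(s), lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover - optimizer failure fallback
        raise RuntimeError("Carreau-Yasuda fit failed")
    e0, ei, lam, a, n = np.exp(best.x)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    at_bound = bool(np.any(best.x <= lo + 1e-6) or np.any(best.x >= hi - 1e-6))
    return CarreauYasudaFit(float(e0), float(ei), float(lam), float(a), float(n), rms, at_bound)


# ---------------------------------------------------------------------------
# yield-peak detection


@dataclass
class YieldFeatures:
    has_peak: bool
    sigma_peak: float | None
    eta_peak: float | None


def detect_yield_peak(sigma, eta, prominence: float = PEAK_PROMINENCE) -> YieldFeatures:
    """Detect the interior viscosity maximum of the stress ramp.

    The ramp is 3-point median smoothed (killing single-sample spikes); the
    smoothed maximum must be interior, exceed the first sample by the
    prominence factor, and the raw sample at the refined position must be
    strictly greater than both raw neighbors.
    """
    sigma = np.asarray(sigma, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if sigma.size < 3:
        raise ValueError("need at least 3 ramp points")
    sm = eta.copy()
    sm[1:-1] = np.median(np.column_stack([eta[:-2], eta[1:-1], eta[2:]]), axis=1)
    j = int(np.argmax(sm))
    if sm[j] <= prominence * eta[0]:
        return YieldFeatures(False, None, None)
    # refine to the raw argmax among the smoothed maximum's neighborhood
    cand = range(max(j - 1, 0), min(j + 2, eta.size))
    i = max(cand, key=lambda k: eta[k])
    if i == 0 or i == eta.size - 1:
        return YieldFeatures(False, None, None)
    if not (eta[i] > eta[i - 1] and eta[i] > eta[i + 1]):
        return YieldFeatures(False, None, None)
    return YieldFeatures(True, float(sigma[i]), float(eta[i]))


# ---------------------------------------------------------------------------
# amplitude-sweep features


@dataclass
class AmplitudeFeatures:
    lve_limit: float  # % strain
    g_lve: float  # Pa, plateau storage modulus
    flow_strain: float | None  # % strain at G' = G'' (None: no crossover)
    g_flow: float | None  # Pa
    tan_delta: dict[float, float]  # at TAN_DELTA_STRAINS
    g_low: float  # G' at the lowest in-window strain (0.1 %)


def _loginterp(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Log-log linear interpolation, exact at the sample points."""
    return float(np.exp(np.interp(math.log(x), np.log(xs), np.log(ys))))


def amplitude_features(
    gamma, gp, gpp, clip: tuple[float, float] = STRAIN_CLIP, lve_tol: float = LVE_TOL
) -> AmplitudeFeatures:
    """Features of the amplitude sweep, computed on the clipped window only.

    The LVE plateau is the geometric mean of G' over the window's lowest
    decade; the LVE limit is the strain where G' first drops ``lve_tol``
    below it (log-log interpolated, clip edge if never).  The flow point is
    the first G' = G'' crossover, located by log-log interpolation between
    the bracketing samples.
    """
    gamma = np.asarray(gamma, dtype=float)
    gp = np.asarray(gp, dtype=float)
    gpp = np.asarray(gpp, dtype=float)
    sel = (gamma >= clip[0]) & (gamma <= clip[1])
    if sel.sum() < 4:
        raise ValueError("amplitude sweep does not cover the clip window")
    g = gamma[sel]
    sp = gp[sel]
    spp = gpp[sel]
    low_decade = g <= clip[0] * 10.0
    plateau = float(np.exp(np.mean(np.log(sp[low_decade]))))
    th = (1.0 - lve_tol) * plateau
    below = np.where(sp < th)[0]
    if below.size == 0:
        lve_limit = float(clip[1])
    else:
        i = int(below[0])
        if i == 0:
            lve_limit = float(g[0])
        else:
            lg = np.log(g)
            ls = np.log(sp)
            t = (math.log(th) - ls[i - 1]) / (ls[i] - ls[i - 1])
            lve_limit = float(np.exp(lg[i - 1] + t * (lg[i] - lg[i - 1])))
    ltan = np.log(spp) - np.log(sp)
    cross = np.where((ltan[:-1] < 0) & (ltan[1:] >= 0))[0]
    if ltan[0] >= 0:
        flow_strain = float(g[0])
        g_flow = float(sp[0])
    elif cross.size == 0:
        flow_strain = None
        g_flow = None
    else:
        i = int(cross[0])
        lg = np.log(g)
        t = (0.0 - ltan[i]) / (ltan[i + 1] - ltan[i])
        flow_strain = float(np.exp(lg[i] + t * (lg[i + 1] - lg[i])))
        g_flow = _loginterp(flow_strain, g, sp)
    tan_d = {s: _loginterp(s, g, spp / sp) for s in TAN_DELTA_STRAINS if clip[0] <= s <= clip[1]}
    return AmplitudeFeatures(
        lve_limit=lve_limit,
        g_lve=plateau,
        flow_strain=flow_strain,
        g_flow=g_flow,
        tan_delta=tan_d,
        g_low=float(sp[0]),
    )


# ---------------------------------------------------------------------------
# frequency-sweep features and the flow proportionality index


def frequency_features(omega, gp, gpp, clip: tuple[float, float] = FREQ_CLIP) -> dict[str, float]:
    omega = np.asarray(omega, dtype=float)
    gp = np.asarray(gp, dtype=float)
    gpp = np.asarray(gpp, dtype=float)
    sel = (omega >= clip[0]) & (omega <= clip[1])
    if sel.sum() < 3:
        raise ValueError("frequency sweep does not cover the clip window")
    w = omega[sel]
    p = gp[sel]
    pp = gpp[sel]
    g1 = _loginterp(clip[0], w, p)
    g10 = _loginterp(clip[1], w, p)
    gg1 = _loginterp(clip[0], w, pp)
    gg10 = _loginterp(clip[1], w, pp)
    t1 = gg1 / g1
    t10 = gg10 / g10
    return {
        "freq_gprime_1rad": g1,
        "freq_gprime_10rad": g10,
        "freq_gdprime_1rad": gg1,
        "freq_gdprime_10rad": gg10,
        "freq_tand_1rad": t1,
        "freq_tand_10rad": t10,
        "freq_tand_ratio_1_10": t1 / t10,
        "freq_gprime_slope": _loglog_slope(w, p),
        "freq_gstar_1rad": math.hypot(g1, gg1),
    }


def flow_proportionality_index(record: PrintRecord) -> float:
    """Extruded mass rate per unit applied pressure, mg/s/kPa."""
    if record.pressure <= 0:
        raise ValueError("pressure must be positive")
    return record.mass_rate / record.pressure


# ---------------------------------------------------------------------------
# assembling the table


def extract_primary_features(
    bundle: RheologyBundle, record: PrintRecord | None = None
) -> dict[str, float]:
    """The 37 primary features of one measurement bundle (print features 0
    when no print record is given, as for base references)."""
    out: dict[str, float] = {}
    out.update(frequency_features(bundle.freq_omega, bundle.freq_gp, bundle.freq_gpp))
    amp = amplitude_features(bundle.amp_gamma, bundle.amp_gp, bundle.amp_gpp)
    out["amp_gprime_lve"] = amp.g_lve
    out["amp_lve_limit"] = amp.lve_limit
    out["amp_flow_strain"] = amp.flow_strain if amp.flow_strain is not None else 0.0
    out["amp_gprime_flow"] = amp.g_flow if amp.g_flow is not None else 0.0
    out["amp_plasticity"] = (
        amp.g_flow / amp.g_lve if amp.g_flow is not None else 0.0
    )
    out["amp_tand_14p8"] = amp.tan_delta[14.8]
    out["amp_tand_21p7"] = amp.tan_delta[21.7]
    out["amp_tand_68p5"] = amp.tan_delta[68.5]
    out["amp_tand_100"] = amp.tan_delta[100.0]
    out["amp_gprime_01"] = amp.g_low
    out["amp_flow_missing"] = float(amp.flow_strain is None)
    out["amp_elastic_comb"] = 0.0  # filled in against the base reference
    cy = fit_carreau_yasuda(bundle.flow_gdot, bundle.flow_eta)
    out["cy_eta0"] = cy.eta0
    out["cy_eta_inf"] = cy.eta_inf
    out["cy_lambda"] = cy.lambda_cy
    out["cy_a"] = cy.a_cy
    out["cy_n"] = cy.n_cy
    yld = detect_yield_peak(bundle.stress_sigma, bundle.stress_eta)
    out["yield_sigma_peak"] = yld.sigma_peak if yld.has_peak else 0.0
    out["yield_eta_peak"] = yld.eta_peak if yld.has_peak else 0.0
    out["yield_missing"] = float(not yld.has_peak)
    for key, t in zip(("itt_rec_5s", "itt_rec_10s", "itt_rec_30s"), bundle.itt_recovery):
        out[key] = float(t)
    for key, t in zip(("iot_rec_5s", "iot_rec_10s", "iot_rec_30s"), bundle.iot_recovery):
        out[key] = float(t)
    if record is not None:
        out["print_flow_prop"] = flow_proportionality_index(record)
        out["print_filament"] = float(record.filament_formed)
    else:
        out["print_flow_prop"] = 0.0
        out["print_filament"] = 0.0
    return out


def extract_features(
    bundle: RheologyBundle,
    base_bundle: RheologyBundle,
    record: PrintRecord,
) -> dict[str, float]:
    """Full 65-feature vector of one formulation against its base reference."""
    f = extract_primary_features(bundle, record)
    b = extract_primary_features(base_bundle, None)
    # elasticity combinatorial: (G'_flow / G'@0.1%) x G'_base@0.1%
    if f["amp_flow_missing"] == 0.0:
        f["amp_elastic_comb"] = f["amp_gprime_flow"] / f["amp_gprime_01"] * b["amp_gprime_01"]
    for name in RATIOED_FEATURES:
        denom = b[name]
        f[name + "_rel"] = f[name] / denom if denom != 0.0 else 0.0
    return f


def build_feature_table_from_parts(
    pairs: list[tuple[str, str]],
    bundles: dict[str, RheologyBundle],
    base_bundles: dict[str, RheologyBundle],
    records: dict[str, PrintRecord],
    scores: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Assemble the 65-column table from (id, base_id) pairs and bundles.

    ``scores`` must carry one row per formulation id with ``score`` and
    ``printable`` columns (the output of the scoring stage).  Rows are
    shuffled with ``seed`` (left in input order when None).  The result is
    indexed by formulation id with exactly the canonical 65 feature columns
    plus ``score`` and ``printable``; hidden generator truths never enter.
    """
    scores = scores.set_index("id") if "id" in scores.columns else scores
    rows = {}
    for ident, base_id in pairs:
        if base_id not in base_bundles:
            raise KeyError(f"no base reference bundle for {ident} ({base_id})")
        if ident not in scores.index:
            raise KeyError(f"no printability score for {ident}")
        feats = extract_features(bundles[ident], base_bundles[base_id], records[ident])
        feats["score"] = float(scores.loc[ident, "score"])
        feats["printable"] = bool(scores.loc[ident, "printable"])
        rows[ident] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[FEATURE_SCHEMA + ["score", "printable"]]
    if list(table.columns[:65]) != FEATURE_SCHEMA:  # pragma: no cover
        raise RuntimeError("feature schema mismatch")
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(table))
        table = table.iloc[order]
    table.index.name = "id"
    return table


def build_feature_table(
    cohort: Cohort, scores: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """`build_feature_table_from_parts` for an in-memory synthetic cohort."""
    pairs = [(f.id, f.base_id) for f in cohort.formulations]
    return build_feature_table_from_parts(
        pairs, cohort.bundles, cohort.base_bundles, cohort.records, scores, seed
    )


def write_schema(path) -> None:
    """Write the canonical schema as JSON (an artifact of the extract stage)."""
    with open(path, "w") as fh:
        json.dump({"features": FEATURE_SCHEMA, "key_features": KEY_FEATURES}, fh, indent=1)
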