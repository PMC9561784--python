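"""Seeded synthetic cohorts of hydrogel formulations.

Each formulation is driven by a single latent network strength ``S``
(log-uniform on [0.1, 10]): the rheological parameter maps below are
log-linear in ``S`` with multiplicative log-normal jitter, so that a fixed
set of 13 quantities carries a monotone relationship with printability while
the remaining measured features are independent of ``S``.  Each formulation
has a matched base-polymer reference with ``S_base = S / factor``,
``factor ~ U[2, 8]``; because the informative maps are log-linear, the
formulation-to-base ratio features depend only on the random factor and stay
uninformative, mirroring how ratio features behave when additives strengthen
a base polymer multiplicatively.

The planted monotone directions (before jitter/noise):

    yield viscosity (+), apparent yield stress (+), plasticity G'_flow/G'_LVE (-),
    Carreau-Yasuda lambda (+), mass rate / pressure (-), filament probability (+),
    LVE limit (+), flow strain (+), tan d @ 14.8 / 21.7 % (-),
    tan d @ 68.5 / 100 % (+), tan d(1 rad/s)/tan d(10 rad/s) -> 1 (-).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .grid import GridDesign, build_grid_design, rasterize_print

# ---------------------------------------------------------------------------
# measurement grids of the 7-step protocol

FREQ_GRID = np.concatenate(
    [
        np.geomspace(0.1, 1.0, 7)[:-1],
        np.geomspace(1.0, 10.0, 13)[:-1],
        np.geomspace(10.0, 100.0, 7),
    ]
)  # rad/s, contains 1 and 10 exactly
AMP_GRID = np.concatenate(
    [
        np.geomspace(0.01, 0.1, 9)[:-1],
        np.geomspace(0.1, 100.0, 37)[:-1],
        np.geomspace(100.0, 500.0, 7),
    ]
)  # % strain, contains 0.1 and 100 exactly
STRESS_GRID = np.arange(1.0, 100.0 + 0.25, 0.5)  # Pa, 0.5 Pa increments
FLOW_GRID = np.geomspace(0.1, 100.0, 31)  # 1/s
RECOVERY_TIMES = np.array([5.0, 10.0, 30.0])  # s

# ---------------------------------------------------------------------------
# latent parameter maps: value = scale * S**slope * exp(N(0, sd))
# sd values are quoted at the default latent_jitter_sd of 0.15 and scale
# proportionally when the config changes it.

_BASE_JITTER = 0.15

# tan-delta master curve of the amplitude sweep: tan d(g) = T(g) * S**beta(g)
# T is a log-log ramp (slope per decade of strain) between two plateaus and
# beta interpolates between an elastic low-strain and viscous high-strain
# exponent, so tan d at any fixed strain is an exact power law in S.
_TAN_T_SLOPE = 0.25
_TAN_T_AT = 12.0  # % strain where T = 1
_TAN_T_LO = 0.40
_TAN_T_HI = 2.6
_TAN_BETA_LO = -0.15
_TAN_BETA_HI = 0.16
_TAN_BETA_CENTER = 35.0  # % strain
_TAN_BETA_SHARP = 3.0


def _tan_T(gamma: np.ndarray) -> np.ndarray:
    logT = _TAN_T_SLOPE * np.log10(np.asarray(gamma, dtype=float) / _TAN_T_AT)
    return 10.0 ** np.clip(logT, math.log10(_TAN_T_LO), math.log10(_TAN_T_HI))


def _tan_beta(gamma: np.ndarray) -> np.ndarray:
    g = np.asarray(gamma, dtype=float)
    sig = 1.0 / (1.0 + (_TAN_BETA_CENTER / g) ** _TAN_BETA_SHARP)
    return _TAN_BETA_LO + (_TAN_BETA_HI - _TAN_BETA_LO) * sig


def tan_delta_amp(gamma, S: float, jitter: float = 1.0) -> np.ndarray:
    """Amplitude-sweep damping factor of a gel-state formulation."""
    return _tan_T(gamma) * S ** _tan_beta(gamma) * jitter


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    ``noise_sd`` is the multiplicative log-normal measurement noise applied
    to every curve point; ``latent_jitter_sd`` scales the formulation-to-
    formulation scatter of the parameter maps; ``spread_constant`` is the
    calibration constant of the filament-spreading map, chosen once so that
    default cohorts land near the ~14% printable prevalence.
    """

    noise_sd: float = 0.02
    latent_jitter_sd: float = _BASE_JITTER
    spread_constant: float = 1.98
    s_min: float = 0.1
    s_max: float = 10.0
    gel_threshold: float = 0.01
    yield_threshold: float = 0.12
    base_factor_min: float = 2.0
    base_factor_max: float = 8.0
    pressure_min: float = 60.0
    pressure_max: float = 250.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.latent_jitter_sd < 0:
            raise ValueError("latent_jitter_sd must be >= 0")


@dataclass
class LatentFormulation:
    """Hidden truth of one formulation (or base-polymer reference)."""

    id: str
    S: float
    base_id: str
    eta0: float  # Pa s
    eta_inf: float  # Pa s
    lambda_cy: float  # s
    n_cy: float
    a_cy: float
    G0: float  # Pa, LVE plateau storage modulus
    gamma_c: float  # % critical strain of the G' decay
    decay_r: float  # G' strain-decay sharpness (grows with network strength)
    tand_lve: float  # LVE damping factor (at 0.1 % strain)
    sigma_y: float | None  # Pa, absent for non-yielding samples
    spread: float  # µm filament width after spreading
    filament_p: float
    # secondary latents (uninformative by construction)
    eta_peak: float = 0.0  # Pa s, viscosity at the stress-ramp maximum
    tan_jitter: float = 1.0
    t0_freq: float = 0.5  # tan d at the 3 rad/s pivot of the frequency sweep
    q_freq: float = -0.2  # tan d frequency exponent (-> 0 for strong networks)
    p_freq: float = 0.1  # G' frequency exponent
    eta_ns: float = 20.0  # Pa s, stress-ramp level when non-yielding
    fpi: float = 0.1  # mg/s/kPa flow proportionality (pre-noise)
    pressure: float = 100.0  # kPa
    itt_plateau: float = 80.0
    itt_tau: float = 8.0
    iot_plateau: float = 80.0
    iot_tau: float = 8.0


@dataclass
class RheologyBundle:
    """The seven-step measurement bundle of one sample."""

    freq_omega: np.ndarray
    freq_gp: np.ndarray
    freq_gpp: np.ndarray
    amp_gamma: np.ndarray
    amp_gp: np.ndarray
    amp_gpp: np.ndarray
    stress_sigma: np.ndarray
    stress_eta: np.ndarray
    flow_gdot: np.ndarray
    flow_eta: np.ndarray
    itt_recovery: np.ndarray  # % of rest viscosity at 5/10/30 s
    iot_recovery: np.ndarray  # % of rest storage modulus at 5/10/30 s


@dataclass
class PrintRecord:
    """Printing observation: pressure, mass flow, filament flag, grid mask."""

    pressure: float  # kPa
    mass_rate: float  # mg/s over 20 s of extrusion
    filament_formed: bool
    mask: np.ndarray  # binary, ink = True


@dataclass
class Cohort:
    formulations: list[LatentFormulation]
    bundles: dict[str, RheologyBundle]  # id -> bundle
    base_latents: dict[str, LatentFormulation]
    base_bundles: dict[str, RheologyBundle]  # base_id -> bundle
    records: dict[str, PrintRecord]
    design: GridDesign
    config: GeneratorConfig
    seed: int


def carreau_yasuda(gdot, eta0: float, eta_inf: float, lam: float, a: float, n: float):
    """eta(gdot) = eta_inf + (eta0 - eta_inf) [1 + (lam gdot)^a]^((n-1)/a)."""
    gdot = np.asarray(gdot, dtype=float)
    return eta_inf + (eta0 - eta_inf) * (1.0 + (lam * gdot) ** a) ** ((n - 1.0) / a)


def _jit(rng: np.random.Generator, sd: float, scale: float) -> float:
    """One multiplicative log-normal jitter draw (always consumes the stream)."""
    z = rng.standard_normal()
    return math.exp(sd * scale * z)


def sample_latent(
    rng: np.random.Generator,
    ident: str,
    S: float,
    base_id: str,
    config: GeneratorConfig,
    is_base: bool = False,
) -> LatentFormulation:
    """Draw one latent formulation at strength ``S`` from the parameter maps."""
    c = config.latent_jitter_sd / _BASE_JITTER
    eta0 = 60.0 * _jit(rng, 0.80, c)
    eta_inf = 0.002 * _jit(rng, 0.30, c)
    lam = 0.8 * S**0.5 * _jit(rng, 0.15, c)
    a = 1.8 * _jit(rng, 0.15, c)
    n = min(max(0.30 * _jit(rng, 0.20, c), 0.05), 0.95)
    G0 = 400.0 * _jit(rng, 0.85, c)
    gamma_c = 1.4 * S**0.18 * _jit(rng, 0.06, c)
    decay_r = 2.6 * _jit(rng, 0.06, c)
    tan_jitter = _jit(rng, 0.06, c)
    sigma_y_draw = 9.0 * S**0.15 * _jit(rng, 0.30, c)
    eta_peak = 30.0 * S**0.9 * _jit(rng, 0.10, c)
    t0_freq = 0.5 * _jit(rng, 0.25, c)
    q_freq = -0.25 * S**-0.25 * _jit(rng, 0.12, c)
    p_freq = 0.10 * _jit(rng, 0.30, c)
    eta_ns = 20.0 * _jit(rng, 0.50, c)
    fpi = 0.12 * S**-0.6 * _jit(rng, 0.15, c)
    pressure = rng.uniform(config.pressure_min, config.pressure_max)
    spread = 410.0 * (1.0 + config.spread_constant * S**-0.5 * _jit(rng, 0.05, c))
    itt_plateau = rng.uniform(30.0, 120.0)
    itt_tau = math.exp(rng.uniform(math.log(2.0), math.log(20.0)))
    iot_plateau = rng.uniform(30.0, 120.0)
    iot_tau = math.exp(rng.uniform(math.log(2.0), math.log(20.0)))
    yielding = (not is_base) and S >= config.yield_threshold
    return LatentFormulation(
        id=ident,
        S=S,
        base_id=base_id,
        eta0=eta0,
        eta_inf=eta_inf,
        lambda_cy=lam,
        n_cy=n,
        a_cy=a,
        G0=G0,
        gamma_c=gamma_c,
        decay_r=decay_r,
        tand_lve=float(tan_delta_amp(AMP_GRID[0], S, tan_jitter)),
        sigma_y=sigma_y_draw if yielding else None,
        spread=spread,
        filament_p=1.0 / (1.0 + (S / 3.2) ** -3.5),
        eta_peak=eta_peak,
        tan_jitter=tan_jitter,
        t0_freq=t0_freq,
        q_freq=q_freq,
        p_freq=p_freq,
        eta_ns=eta_ns,
        fpi=fpi,
        pressure=pressure,
        itt_plateau=itt_plateau,
        itt_tau=itt_tau,
        iot_plateau=iot_plateau,
        iot_tau=iot_tau,
    )


def _noise(rng: np.random.Generator | None, sd: float, shape) -> np.ndarray:
    if rng is None or sd == 0:
        return np.ones(shape)
    return np.exp(sd * rng.standard_normal(shape))


def generate_rheology_bundle(
    latent: LatentFormulation,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
    gel_threshold: float = 0.01,
) -> RheologyBundle:
    """Render the 7-step measurement curves of one latent formulation.

    With ``noise_sd == 0`` every curve-shape postcondition holds exactly:
    the flow curve is the closed Carreau-Yasuda form, the amplitude-sweep
    G' is a non-increasing decay from the plateau ``G0`` and a single
    G' = G'' crossover exists iff ``S`` exceeds the gel threshold, and the
    stress ramp has a single interior maximum at ``sigma_y`` iff present.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and rng is None:
        rng = np.random.default_rng(0)
    S = latent.S
    # frequency sweep (0.1% strain): G' ~ omega^p, tan d ~ (omega/3)^q
    gp_f = 0.85 * latent.G0 * (FREQ_GRID / 3.1623) ** latent.p_freq
    tand_f = latent.t0_freq * (FREQ_GRID / 3.1623) ** latent.q_freq
    freq_gp = gp_f * _noise(rng, noise_sd, FREQ_GRID.shape)
    freq_gpp = gp_f * tand_f * _noise(rng, noise_sd, FREQ_GRID.shape)
    # amplitude sweep at 10 rad/s
    amp_gp_clean = (
        latent.G0 * (1.0 + (AMP_GRID / latent.gamma_c) ** latent.decay_r) ** -0.7
    )
    if S < gel_threshold:
        # sol state: viscous everywhere, no crossover in the window
        tand_a = 1.3 * (AMP_GRID / AMP_GRID[0]) ** 0.02
    else:
        tand_a = tan_delta_amp(AMP_GRID, S, latent.tan_jitter)
    amp_gp = amp_gp_clean * _noise(rng, noise_sd, AMP_GRID.shape)
    amp_gpp = amp_gp_clean * tand_a * _noise(rng, noise_sd, AMP_GRID.shape)
    # stress ramp: single interior maximum at sigma_y when yielding
    if latent.sigma_y is not None:
        u = STRESS_GRID / latent.sigma_y
        bump = u**2 / (1.0 + u**4)  # max at u = 1 (a = b = 2)
        ramp = latent.eta_peak * bump / 0.5
    else:
        ramp = latent.eta_ns * (1.0 + STRESS_GRID / 20.0) ** -0.8
    stress_eta = ramp * _noise(rng, noise_sd, STRESS_GRID.shape)
    # steady flow curve
    flow_clean = carreau_yasuda(
        FLOW_GRID, latent.eta0, latent.eta_inf, latent.lambda_cy, latent.a_cy, latent.n_cy
    )
    flow_eta = flow_clean * _noise(rng, noise_sd, FLOW_GRID.shape)
    # three-interval recovery tests, reported as percentages
    itt = latent.itt_plateau * (1.0 - np.exp(-RECOVERY_TIMES / latent.itt_tau))
    iot = latent.iot_plateau * (1.0 - np.exp(-RECOVERY_TIMES / latent.iot_tau))
    itt = itt * _noise(rng, noise_sd, itt.shape)
    iot = iot * _noise(rng, noise_sd, iot.shape)
    return RheologyBundle(
        freq_omega=FREQ_GRID.copy(),
        freq_gp=freq_gp,
        freq_gpp=freq_gpp,
        amp_gamma=AMP_GRID.copy(),
        amp_gp=amp_gp,
        amp_gpp=amp_gpp,
        stress_sigma=STRESS_GRID.copy(),
        stress_eta=stress_eta,
        flow_gdot=FLOW_GRID.copy(),
        flow_eta=flow_eta,
        itt_recovery=itt,
        iot_recovery=iot,
    )


def generate_print_record(
    latent: LatentFormulation,
    design: GridDesign,
    rng: np.random.Generator,
    noise_sd: float = 0.02,
) -> PrintRecord:
    """Printing observation: mass rate proportional to pressure through the
    flow proportionality index (decreasing in S), a Bernoulli filament flag,
    and the grid mask rasterized at the spread filament width."""
    mass_rate = latent.fpi * latent.pressure * float(_noise(rng, noise_sd, ()))
    filament = bool(rng.random() < latent.filament_p)
    mask = rasterize_print(design, latent.spread)
    return PrintRecord(
        pressure=latent.pressure,
        mass_rate=mass_rate,
        filament_formed=filament,
        mask=mask,
    )


def sample_cohort(
    n_formulations: int,
    seed: int,
    config: GeneratorConfig | None = None,
    design: GridDesign | None = None,
) -> Cohort:
    """Generate a seeded cohort of formulations with matched base references.

    Identical ``(seed, config)`` reproduce the cohort bit for bit.  With the
    default config the printable fraction of a default-size cohort lies in
    the calibrated ~14% band.
    """
    if n_formulations <= 0:
        raise ValueError("n_formulations must be positive")
    config = config or GeneratorConfig()
    design = design or build_grid_design()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    formulations: list[LatentFormulation] = []
    bundles: dict[str, RheologyBundle] = {}
    base_latents: dict[str, LatentFormulation] = {}
    base_bundles: dict[str, RheologyBundle] = {}
    records: dict[str, PrintRecord] = {}
    log_lo, log_hi = math.log(config.s_min), math.log(config.s_max)
    for i in range(n_formulations):
        ident = f"F{i:04d}"
        base_id = f"B{i:04d}"
        S = math.exp(rng.uniform(log_lo, log_hi))
        factor = rng.uniform(config.base_factor_min, config.base_factor_max)
        latent = sample_latent(rng, ident, S, base_id, config)
        base = sample_latent(rng, base_id, S / factor, base_id, config, is_base=True)
        formulations.append(latent)
        base_latents[base_id] = base
        bundles[ident] = generate_rheology_bundle(
            latent, config.noise_sd, rng, config.gel_threshold
        )
        base_bundles[base_id] = generate_rheology_bundle(
            base, config.noise_sd, rng, config.gel_threshold
        )
        records[ident] = generate_print_record(latent, design, rng, config.noise_sd)
    return Cohort(
        formulations=formulations,
        bundles=bundles,
        base_latents=base_latents,
        base_bundles=base_bundles,
        records=records,
        design=design,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# analytic helpers used for calibration and threshold-recovery checks


def analytic_score(width_um: float, design: GridDesign | None = None) -> float:
    """Closed-form printability index of a print with filament width w:
    each included cell resolves max(0, (L - w))^2 / (L - Di)^2."""
    design = design or build_grid_design()
    di = design.di_um
    num = 0.0
    den = 0.0
    for cell in design.included_cells():
        L = cell.spacing
        w_c = 1.0 / cell.multiplier
        r = min(1.0, max(0.0, (L - width_um)) ** 2 / (L - di) ** 2)
        num += w_c * r
        den += w_c
    return num / den


def printable_strength_threshold(config: GeneratorConfig | None = None) -> float:
    """Latent strength S* at which the jitter-free spread map crosses the
    0.33 printability cutoff; the planted decision boundary of the cohort."""
    from scipy.optimize import brentq

    config = config or GeneratorConfig()
    design = build_grid_design()

    def f(logS: float) -> float:
        S = math.exp(logS)
        w = 410.0 * (1.0 + config.spread_constant * S**-0.5)
        return analytic_score(w, design) - 0.33

    lo, hi = math.log(config.s_min), math.log(config.s_max)
    return math.exp(brentq(f, lo, hi))


def replace_config(config: GeneratorConfig, **kw) -> GeneratorConfig:
    return replace(config, **kw)
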