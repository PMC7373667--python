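"""Synthetic clot formation / lysis curves with known ground truth.

The generator emulates the turbidimetric assay: absorbance at 405 nm read
every 12 s for 1 h, with a lag phase, a sigmoidal aggregation rise to a
plateau, and — in the t-PA arm — exponential lysis after clot completion.
A dose-response layer maps assay conditions (FVIII-deficient plasma plus
SIA / aPCC / rFVIIa at given concentrations) to latent kinetics with a
multiplicative SIA x aPCC synergy, so the waveform and potentials stages
have a ground-truth oracle spanning realistic parameter ranges.

The latent kinetics (``lag_s``, ``rise_rate_au_per_min``, ``max_rise_au``)
are defined in terms of what the waveform analyzer measures: the curve is
built so that, noise-free and at default detection settings, the detected
onset falls at ``lag_s``, the detected plateau at ``lag_s`` + rise
duration, and the fitted growth slope at ``rise_rate_au_per_min``.  This
is achieved by a short fixed-point calibration of the profile anchors
against a continuous model of the detector (see ``_calibrated_anchors``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .io_formats import AssayCondition, KineticCurve, Plasma, ValidationError
from .waveform import DetectionConfig

__all__ = [
    "ClotKinetics",
    "Hill",
    "AgentResponse",
    "Synergy",
    "DoseResponseModel",
    "default_model",
    "condition_to_kinetics",
    "simulate_curve",
    "simulate_condition_set",
]


@dataclass(frozen=True)
class ClotKinetics:
    """Latent parameters of one well's clot formation / lysis curve."""

    baseline_au: float = 0.05
    lag_s: float = math.inf          # inf encodes "no aggregation"
    rise_rate_au_per_min: float = 0.03
    max_rise_au: float = 0.18        # 0 iff no aggregation
    lysis_onset_s: float = math.inf  # inf when t-PA absent
    lysis_rate_per_min: float = 0.0
    noise_sd_au: float = 0.0

    def __post_init__(self) -> None:
        if self.max_rise_au < 0 or self.noise_sd_au < 0 or self.lysis_rate_per_min < 0:
            raise ValidationError("ClotKinetics: max_rise, noise_sd and lysis_rate must be >= 0")
        if self.lag_s < 0:
            raise ValidationError("ClotKinetics: lag_s must be >= 0")
        if self.rise_rate_au_per_min <= 0:
            raise ValidationError("ClotKinetics: rise_rate_au_per_min must be > 0")
        if math.isfinite(self.lag_s) and math.isfinite(self.lysis_onset_s):
            if not self.lag_s < self.lysis_onset_s:
                raise ValidationError("ClotKinetics: lag_s must precede lysis_onset_s")

    @property
    def aggregates(self) -> bool:
        return self.max_rise_au > 0 and math.isfinite(self.lag_s)

    @property
    def rise_duration_s(self) -> float:
        return self.max_rise_au / self.rise_rate_au_per_min * 60.0


# ---------------------------------------------------------------------------
# aggregation profile, calibrated against the waveform detector

_KAPPA = 0.10          # corner fraction of the rise support
_REF_DETECT = DetectionConfig()
_FINE_DT = 1.0         # s, resolution of the calibration grid


def _ramp_profile(t: np.ndarray, t0: float, T: float) -> np.ndarray:
    """Sigmoidal 0->1 profile: linear ramp with smooth quadratic corners.

    The slope profile is trapezoidal (up over ``c``, flat, down over ``c``
    with ``c = _KAPPA * T``), which integrates to a C1 S-shape that is flat
    before ``t0`` and exactly 1 after ``t0 + T``.
    """
    c = _KAPPA * T
    r = 1.0 / (T - c)
    u = t - t0
    out = np.zeros_like(u)
    m = (u > 0) & (u <= c)
    out[m] = r * u[m] ** 2 / (2 * c)
    m = (u > c) & (u <= T - c)
    out[m] = r * (u[m] - c / 2)
    m = (u > T - c) & (u < T)
    out[m] = 1.0 - r * (T - u[m]) ** 2 / (2 * c)
    out[u >= T] = 1.0
    return out


def _box_smooth(y: np.ndarray, half_width_s: float) -> np.ndarray:
    w = max(1, int(round(2 * half_width_s / _FINE_DT)) + 1)
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="same")


def _predict_detection(t0: float, T: float, theta: float, interval_s: float,
                       cfg: DetectionConfig = _REF_DETECT):
    """Continuous-model prediction of the detector's onset / plateau times."""
    half = (cfg.smoothing_window_n - 1) / 2 * interval_s
    lo = max(0.0, t0 - 4 * half - 10)
    hi = t0 + T + 4 * half + 10
    t = np.arange(lo, hi, _FINE_DT)
    g = _ramp_profile(t, t0, T)
    gs = _box_smooth(g, half)
    above = np.flatnonzero(gs >= theta)
    t_lag = t[above[0]] if len(above) else math.nan
    slope = _box_smooth(np.gradient(gs, t), half)
    ipk = int(np.argmax(slope))
    thr = cfg.plateau_slope_fraction * slope[ipk]
    flat = np.flatnonzero(slope[ipk:] <= thr)
    t_ttp = t[ipk + flat[0]] if len(flat) else math.nan
    return t_lag, t_ttp


def _calibrated_anchors(kin: ClotKinetics, sampling=(12.0, 3600.0),
                        cfg: DetectionConfig = _REF_DETECT):
    """Profile anchors (t0, T) such that the noise-free detector recovers
    ``lag_s`` and ``lag_s + rise_duration`` (up to reading quantization).

    Two stages: a fixed-point loop against a continuous model of the
    detector aims the threshold crossings at the mid-point of the sampling
    cell containing the target, then a short refinement loop runs the
    actual discrete detectors on the noise-free curve and absorbs any
    residual beyond half a reading.
    """
    from . import waveform  # local import: waveform does not import simulate

    interval_s, duration_s = float(sampling[0]), float(sampling[1])
    theta = cfg.onset_threshold_au / kin.max_rise_au
    T_rise = kin.rise_duration_s
    if theta >= 0.9:
        # rise too small for onset detection; anchors are nominal
        return kin.lag_s, T_rise
    # aim the continuous threshold crossings half a reading before their
    # targets so the detected reading (the first grid point past the
    # crossing) quantizes to within half a sampling interval either way
    t0, T = kin.lag_s - 0.12 * T_rise, T_rise
    lag_aim = kin.lag_s - interval_s / 2
    ttp_aim = kin.lag_s + T_rise - interval_s / 2
    for _ in range(4):
        t_lag, t_ttp = _predict_detection(t0, T, theta, interval_s, cfg)
        if not (math.isfinite(t_lag) and math.isfinite(t_ttp)):
            break
        t0_new = t0 + (lag_aim - t_lag)
        end_new = (t0 + T) + (ttp_aim - t_ttp)
        if end_new - t0_new < 1.0:
            break
        t0, T = t0_new, end_new - t0_new
        if abs(lag_aim - t_lag) < 0.25 and abs(ttp_aim - t_ttp) < 0.25:
            break
    # discrete refinement against the real detector
    times = np.arange(0.0, duration_s + interval_s / 2, interval_s)
    for _ in range(5):
        a = kin.baseline_au + kin.max_rise_au * _ramp_profile(times, t0, T)
        curve = KineticCurve(times=times, absorbances=a, well_id="cal",
                             sampling_interval=interval_s, duration=duration_s)
        lag_det = waveform.detect_lag(curve, cfg)
        if lag_det is None:
            break
        ttp_det, _ = waveform.detect_plateau(curve, cfg, lag_det)
        if ttp_det is None:
            break
        e_lag = lag_det - kin.lag_s
        e_ttp = ttp_det - (kin.lag_s + T_rise)
        half = interval_s / 2
        if abs(e_lag) <= half and abs(e_ttp) <= half:
            break
        new_t0 = t0 - (e_lag if abs(e_lag) > half else 0.0)
        new_end = (t0 + T) - (e_ttp if abs(e_ttp) > half else 0.0)
        if new_end - new_t0 < 1.0:
            break
        t0, T = new_t0, new_end - new_t0
    return t0, T


def simulate_curve(kin: ClotKinetics, sampling=(12.0, 3600.0), seed: int = 0,
                   well_id: str = "sim") -> KineticCurve:
    """One synthetic kinetic curve under ``kin``, sampled ``(interval, duration)``.

    The deterministic part is baseline + max_rise * g(t) * l(t) with g the
    calibrated aggregation profile and l the lysis factor (1 before
    ``lysis_onset_s``, exponential decay at ``lysis_rate_per_min`` after).
    Noise is i.i.d. Gaussian; the same seed always yields the same curve.
    """
    interval_s, duration_s = float(sampling[0]), float(sampling[1])
    if interval_s <= 0:
        raise ValueError("sampling interval must be > 0")
    if duration_s < interval_s:
        raise ValueError("duration must be at least one sampling interval")
    t = np.arange(0.0, duration_s + interval_s / 2, interval_s)
    a = np.full_like(t, kin.baseline_au)
    if kin.aggregates:
        t0, T = _calibrated_anchors(kin, (interval_s, duration_s))
        g = _ramp_profile(t, t0, T)
        lys = np.ones_like(t)
        if math.isfinite(kin.lysis_onset_s) and kin.lysis_rate_per_min > 0:
            after = t > kin.lysis_onset_s
            lys[after] = np.exp(-kin.lysis_rate_per_min * (t[after] - kin.lysis_onset_s) / 60.0)
        a = a + kin.max_rise_au * g * lys
    if kin.noise_sd_au > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, kin.noise_sd_au, size=len(t))
    return KineticCurve(times=t, absorbances=a, well_id=well_id,
                        sampling_interval=interval_s, duration=duration_s)


# ---------------------------------------------------------------------------
# dose-response layer


@dataclass(frozen=True)
class Hill:
    """Saturating Hill drive: amplitude * c^n / (c^n + k^n); 0 at c = 0."""

    amplitude: float
    k: float
    n: float = 1.0

    def __call__(self, conc: float) -> float:
        if conc < 0:
            raise ValidationError(f"negative concentration: {conc!r}")
        if conc == 0:
            return 0.0
        cn = conc ** self.n
        return self.amplitude * cn / (cn + self.k ** self.n)


@dataclass(frozen=True)
class AgentResponse:
    """One agent's dose-response drives for lag shortening, rate and max rise."""

    lag: Hill
    rate: Hill
    max_rise: Hill


@dataclass(frozen=True)
class Synergy:
    """SIA x aPCC interaction term.

    The product of two unit-amplitude Hill shapes scales an extra drive
    that shortens lag, accelerates clotting and (matching the observed
    turbidity drop of dense thin-fiber clots) suppresses the max rise.
    """

    sia_shape: Hill
    apcc_shape: Hill
    gamma_lag: float
    gamma_rate: float
    gamma_max: float

    def activation(self, sia_nM: float, apcc_mU_per_mL: float) -> float:
        return self.sia_shape(sia_nM) * self.apcc_shape(apcc_mU_per_mL)


@dataclass(frozen=True)
class DoseResponseModel:
    """Maps assay conditions to latent clot kinetics.

    FVIII-deficient plasma with no agent sits at the deficient reference
    (onset far beyond any practical recording window, i.e. no
    aggregation).  Each agent contributes an additive Hill-type drive; the
    lag shortens as lag_def / (1 + total drive) and the rate and max rise
    grow from their deficient references.  Conditions whose latent lag
    stays at or beyond ``no_aggregation_lag_s`` are emitted as flat
    no-aggregation kinetics.
    """

    pnp: ClotKinetics
    deficient_lag_s: float
    deficient_rate_au_per_min: float
    deficient_max_rise_au: float
    baseline_au: float
    sia: AgentResponse
    apcc: AgentResponse
    rfviia: AgentResponse
    synergy: Synergy
    lysis_rate_per_min: float
    noise_sd_au: float
    no_aggregation_lag_s: float = 7200.0


def condition_to_kinetics(condition: AssayCondition,
                          model: Optional[DoseResponseModel] = None) -> ClotKinetics:
    """Deterministic latent kinetics for one assay condition."""
    model = model or default_model()
    if condition.plasma is Plasma.PNP:
        kin = model.pnp
    else:
        s, a, r = condition.sia_nM, condition.apcc_mU_per_mL, condition.rfviia_ug_per_mL
        syn = model.synergy.activation(s, a)
        lag_drive = (model.sia.lag(s) + model.apcc.lag(a) + model.rfviia.lag(r)
                     + model.synergy.gamma_lag * syn)
        rate_drive = (model.sia.rate(s) + model.apcc.rate(a) + model.rfviia.rate(r)
                      + model.synergy.gamma_rate * syn)
        max_drive = model.sia.max_rise(s) + model.apcc.max_rise(a) + model.rfviia.max_rise(r)
        lag = model.deficient_lag_s / (1.0 + lag_drive)
        if lag >= model.no_aggregation_lag_s:
            return ClotKinetics(baseline_au=model.baseline_au, lag_s=math.inf,
                                max_rise_au=0.0, noise_sd_au=model.noise_sd_au)
        kin = ClotKinetics(
            baseline_au=model.baseline_au,
            lag_s=lag,
            rise_rate_au_per_min=model.deficient_rate_au_per_min * (1.0 + rate_drive),
            max_rise_au=model.deficient_max_rise_au * (1.0 + max_drive)
            / (1.0 + model.synergy.gamma_max * syn),
            noise_sd_au=model.noise_sd_au,
        )
    if condition.tpa_present and kin.aggregates:
        kin = replace(kin, lysis_onset_s=kin.lag_s + kin.rise_duration_s,
                      lysis_rate_per_min=model.lysis_rate_per_min)
    return kin


def simulate_condition_set(conditions, model=None, sampling=(12.0, 3600.0), seed: int = 0):
    """Simulate one curve per condition entry (replicates differ only by noise).

    Per-curve seeds are derived deterministically from the master seed, so
    the whole batch is reproducible and individual curves can be
    regenerated in isolation.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("simulate_condition_set: empty condition list")
    model = model or default_model()
    child_seeds = np.random.SeedSequence(seed).generate_state(len(conditions))
    out = []
    for i, (cond, sub) in enumerate(zip(conditions, child_seeds)):
        kin = condition_to_kinetics(cond, model)
        curve = simulate_curve(kin, sampling, seed=int(sub), well_id=f"W{i:03d}")
        out.append((cond, curve))
    return out


# ---------------------------------------------------------------------------
# default calibration (loosely fitted to the reference assay means; see
# clotwave.reference and docs/methods.md)

_DEFAULTS: dict = dict(
    deficient_lag_s=7200.0,
    deficient_rate_au_per_min=0.002,
    deficient_max_rise_au=0.10,
    baseline_au=0.05,
    lysis_rate_per_min=0.06,
    noise_sd_au=0.003,
    sia=AgentResponse(lag=Hill(8.13, 30.0, 2.0),
                      rate=Hill(8.16, 300.0, 0.7),
                      max_rise=Hill(1.05, 30.0, 2.0)),
    apcc=AgentResponse(lag=Hill(20.1, 330.0, 2.0),
                       rate=Hill(31.1, 1000.0, 1.3),
                       max_rise=Hill(2.08, 800.0, 1.0)),
    rfviia=AgentResponse(lag=Hill(9.89, 3.5, 4.0),
                         rate=Hill(4.79, 3.5, 4.0),
                         max_rise=Hill(3.11, 3.5, 4.0)),
    synergy=Synergy(sia_shape=Hill(1.0, 86.0, 1.52),
                    apcc_shape=Hill(1.0, 1.0e6, 0.4),
                    gamma_lag=1590.0, gamma_rate=830.0, gamma_max=36.6),
)


def default_model(noise_sd_au: Optional[float] = None,
                  lysis_rate_per_min: Optional[float] = None) -> DoseResponseModel:
    """The default dose-response calibration.

    Reference kinetics for pooled normal plasma analyze to lag ~10 min,
    TTP ~16 min and clotting rate ~0.03 AU/min; agent drives are loose
    fits to the reference condition means.  The calibration is a
    convenience for exercising the pipeline, not a mechanistic model.
    """
    d = dict(_DEFAULTS)
    if noise_sd_au is not None:
        d["noise_sd_au"] = noise_sd_au
    if lysis_rate_per_min is not None:
        d["lysis_rate_per_min"] = lysis_rate_per_min
    pnp = ClotKinetics(baseline_au=d["baseline_au"], lag_s=600.0,
                       rise_rate_au_per_min=0.03, max_rise_au=0.18,
                       noise_sd_au=d["noise_sd_au"])
    return DoseResponseModel(pnp=pnp, **d)
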