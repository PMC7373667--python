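"""Turbidity curve parameters from a single clot-formation record.

A fibrin aggregation curve read at 405 nm has a lag phase at optical
baseline, a roughly sigmoidal rise as protofibrils aggregate into fibers,
and a plateau once polymerization completes.  From one curve this module
extracts the five standard turbidity parameters plus the Abs-sum area
under the curve:

* ``lag time`` — onset of turbidity growth (min),
* ``max Abs`` — plateau turbidity minus the turbidity at the lag point (AU),
* ``clotting rate`` — least-squares slope of the growth phase (AU/min),
* ``time to plateau`` — time at which the plateau is reached (min),
* ``slope time`` — duration of the growth phase, TTP − lag (min),
* ``Abs-sum`` — baseline-subtracted summation of the readings (AU-sum).

Curves in which no aggregation onset (or no plateau) can be found within
the recording window are *nondetectable* (ND); ND is a value, not an
error, and propagates into condition-level reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import KineticCurve

__all__ = [
    "DetectionConfig",
    "TurbidityParams",
    "abs_sum_auc",
    "raw_abs_sum",
    "detect_lag",
    "detect_plateau",
    "clotting_rate",
    "turbidity_params",
]

ND = None  # nondetectable sentinel: detection functions return None


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the onset/plateau detectors.

    baseline_window_n
        Readings used for the Abs-sum baseline (median of the first n).
    onset_threshold_au
        Rise above baseline (AU) that counts as aggregation onset.
    onset_min_consecutive
        Readings the smoothed signal must stay above threshold for the
        onset to be accepted (rejects single-reading noise spikes).
    plateau_slope_fraction
        The plateau is reached when the local slope falls below this
        fraction of the peak growth-phase slope.
    smoothing_window_n
        Width (odd, readings) of the centered moving average applied
        before threshold tests.
    """

    baseline_window_n: int = 10
    onset_threshold_au: float = 0.01
    onset_min_consecutive: int = 3
    plateau_slope_fraction: float = 0.05
    smoothing_window_n: int = 5

    def __post_init__(self) -> None:
        if min(self.baseline_window_n, self.onset_min_consecutive, self.smoothing_window_n) < 1:
            raise ValueError("DetectionConfig window sizes must be positive")
        if self.onset_threshold_au <= 0 or self.plateau_slope_fraction <= 0:
            raise ValueError("DetectionConfig thresholds must be positive")
        if self.smoothing_window_n % 2 == 0:
            raise ValueError("smoothing_window_n must be odd")


@dataclass(frozen=True)
class TurbidityParams:
    """Per-well turbidity parameters; kinetic fields are None when nd.

    ``abs_sum_auc`` is reported even for nondetectable curves (it is then a
    diagnostic of residual optical drift, not a clot measurement).
    """

    lag_time_min: Optional[float]
    max_abs_au: Optional[float]
    clotting_rate_au_per_min: Optional[float]
    time_to_plateau_min: Optional[float]
    slope_time_min: Optional[float]
    abs_sum_auc: float
    nd: bool


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows shrink symmetrically at the edges."""
    if window <= 1:
        return values.astype(float)
    half = window // 2
    cum = np.cumsum(np.concatenate(([0.0], values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (cum[hi + 1] - cum[lo]) / (hi - lo + 1)


def _baseline(curve: KineticCurve, cfg: DetectionConfig) -> float:
    n = min(cfg.baseline_window_n, len(curve))
    return float(np.median(curve.absorbances[:n]))


def abs_sum_auc(curve: KineticCurve, cfg: DetectionConfig = DetectionConfig()) -> float:
    """Baseline-subtracted Abs-sum: sum of max(A_i - baseline, 0).

    The baseline is the median of the first ``baseline_window_n`` readings.
    This is a plain summation over readings (no trapezoidal weighting), so
    its unit is "summed AU" and its magnitude scales with the number of
    readings.
    """
    b = _baseline(curve, cfg)
    return float(np.sum(np.maximum(curve.absorbances - b, 0.0)))


def raw_abs_sum(curve: KineticCurve) -> float:
    """Un-subtracted summation of the readings, exposed for audit."""
    return float(np.sum(curve.absorbances))


def _detection_baseline(curve: KineticCurve, cfg: DetectionConfig):
    """Robust baseline for onset detection.

    A fast clot can start rising inside the nominal baseline window, which
    would inflate a plain first-n median.  We therefore take a provisional
    baseline from the *minimum* of the smoothed early window, locate the
    provisional threshold crossing, and re-estimate the baseline as the
    median of all readings clearly before that crossing.  On flat or
    slow-onset curves this collapses to the plain median (over a longer,
    hence less noisy, pre-onset stretch).
    """
    a = curve.absorbances
    s = _smooth(a, cfg.smoothing_window_n)
    n0 = min(cfg.baseline_window_n, len(curve))
    b0 = float(np.min(s[:n0]))
    above = s > b0 + cfg.onset_threshold_au
    run = _first_run(above, cfg.onset_min_consecutive)
    if run is None:
        return float(np.median(a[:n0])), s
    pre = max(1, run - 2)
    b = float(np.median(a[:pre]))
    return b, s


def _first_run(mask: np.ndarray, m: int) -> Optional[int]:
    """Index of the first reading opening a run of >= m consecutive True."""
    if m <= 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if len(hits) else None
    ok = np.ones(len(mask) - m + 1, dtype=bool) if len(mask) >= m else np.zeros(0, dtype=bool)
    for k in range(m):
        ok &= mask[k: len(mask) - m + 1 + k]
    hits = np.flatnonzero(ok)
    return int(hits[0]) if len(hits) else None


def detect_lag(curve: KineticCurve, cfg: DetectionConfig = DetectionConfig()) -> Optional[float]:
    """Time (s) of aggregation onset, or None (ND).

    Onset is the first reading at which the smoothed absorbance exceeds
    baseline + ``onset_threshold_au`` and stays above it for
    ``onset_min_consecutive`` readings.  ND if no such sustained crossing
    fits inside the recording window.
    """
    b, s = _detection_baseline(curve, cfg)
    above = s > b + cfg.onset_threshold_au
    run = _first_run(above, cfg.onset_min_consecutive)
    if run is None:
        return ND
    t = curve.times[run]
    if t > curve.duration - cfg.onset_min_consecutive * curve.sampling_interval:
        return ND
    return float(t)


def _local_slopes(curve: KineticCurve, cfg: DetectionConfig) -> np.ndarray:
    """Local slope (AU/s) of the smoothed curve, lightly re-smoothed."""
    s = _smooth(curve.absorbances, cfg.smoothing_window_n)
    g = np.gradient(s, curve.times)
    return _smooth(g, cfg.smoothing_window_n)


def detect_plateau(curve: KineticCurve, cfg: DetectionConfig, lag_s: float):
    """(time-to-plateau s, max Abs AU) after a detected onset; (None, None) if ND.

    The plateau is the first run of three consecutive readings after the lag
    whose local slope is at most ``plateau_slope_fraction`` of the peak
    growth-phase slope.  Max Abs is the median of those three readings minus
    the lag turbidity (the optical level of the lag phase, i.e. the detection
    baseline); TTP is the first reading of the run.
    """
    if lag_s is None:
        raise ValueError("detect_plateau called with ND lag (contract violation)")
    t = curve.times
    lag_idx = int(np.searchsorted(t, lag_s))
    slopes = _local_slopes(curve, cfg)
    post = slopes[lag_idx:]
    if len(post) < 3:
        return ND, ND
    peak = float(np.max(post))
    if peak <= 0:
        return ND, ND
    thr = cfg.plateau_slope_fraction * peak
    # search strictly after the onset reading so the pre-lag flat stretch
    # (slope ~ 0 by construction) can never masquerade as the plateau
    flat = post[1:] <= thr
    run = _first_run(flat, 3)
    if run is None:
        return ND, ND
    i = lag_idx + 1 + run
    lag_turbidity, _ = _detection_baseline(curve, cfg)
    max_abs = float(np.median(curve.absorbances[i: i + 3]) - lag_turbidity)
    return float(t[i]), max_abs


def clotting_rate(curve: KineticCurve, lag_s: float, ttp_s: float) -> Optional[float]:
    """Least-squares slope (AU/min) of absorbance vs time over [lag, TTP]."""
    if lag_s is None or ttp_s is None:
        raise ValueError("clotting_rate requires detected lag and TTP")
    if not lag_s < ttp_s:
        raise ValueError(f"clotting_rate: lag ({lag_s:g} s) must precede TTP ({ttp_s:g} s)")
    m = (curve.times >= lag_s) & (curve.times <= ttp_s)
    if int(m.sum()) < 2:
        return ND
    slope_per_s = np.polyfit(curve.times[m], curve.absorbances[m], 1)[0]
    return float(slope_per_s * 60.0)


def turbidity_params(curve: KineticCurve, cfg: DetectionConfig = DetectionConfig()) -> TurbidityParams:
    """All turbidity parameters of one curve; nd=True when the record is ND.

    A record is nondetectable when no aggregation onset is found, when the
    curve never plateaus within the window, or when the growth phase spans
    fewer than two readings.  Abs-sum is always reported.
    """
    auc = abs_sum_auc(curve, cfg)
    lag_s = detect_lag(curve, cfg)
    if lag_s is None:
        return TurbidityParams(None, None, None, None, None, auc, True)
    ttp_s, max_abs = detect_plateau(curve, cfg, lag_s)
    if ttp_s is None:
        return TurbidityParams(None, None, None, None, None, auc, True)
    rate = clotting_rate(curve, lag_s, ttp_s) if ttp_s > lag_s else ND
    if rate is None or rate <= 0:
        return TurbidityParams(None, None, None, None, None, auc, True)
    return TurbidityParams(
        lag_time_min=lag_s / 60.0,
        max_abs_au=max_abs,
        clotting_rate_au_per_min=rate,
        time_to_plateau_min=ttp_s / 60.0,
        slope_time_min=(ttp_s - lag_s) / 60.0,
        abs_sum_auc=auc,
        nd=False,
    )
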