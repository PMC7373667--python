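"""Overall coagulation / hemostasis / fibrinolysis potentials (OCP/OHP/OFP).

The assay runs each condition in two arms: without t-PA (clot formation
only) and with t-PA (formation plus lysis).  OCP is the Abs-sum AUC of
the no-t-PA curve, OHP the Abs-sum AUC of the t-PA curve, and

    OFP = ((OCP - OHP) / OCP) x 100 %

is the fraction of the coagulation potential removed by fibrinolysis.
Replicates aggregate to mean +/- SD per condition; the OFP is formed from
the replicate means, with its SD propagated to first order from the OCP
and OHP spreads.  A condition is nondetectable (ND) when the majority of
its no-t-PA replicates show no aggregation onset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .waveform import DetectionConfig, abs_sum_auc, detect_lag

__all__ = [
    "MeanSD",
    "HemostasisPotential",
    "NormalRange",
    "compute_potentials",
    "normal_range",
    "nd_majority",
    "NORMAL_RANGE_PARAMS",
]


@dataclass(frozen=True)
class MeanSD:
    mean: float
    sd: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.mean, self.sd)


@dataclass(frozen=True)
class HemostasisPotential:
    """Condition-level OCP/OHP (Abs-sum) and OFP (%), mean +/- SD."""

    ocp: Optional[MeanSD]
    ohp: Optional[MeanSD]
    ofp_percent: Optional[MeanSD]
    n_replicates: int
    nd: bool


def _mean_sd(values) -> MeanSD:
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return MeanSD(float(np.mean(v)), sd)


def nd_majority(nd_flags) -> bool:
    """Condition-level ND rule: ND when at least half the replicates are ND.

    With the assay's standard triplicates this fires at >= 2 of 3.
    """
    flags = list(nd_flags)
    return sum(flags) * 2 >= len(flags)


def compute_potentials(no_tpa_curves, tpa_curves,
                       cfg: DetectionConfig = DetectionConfig()) -> HemostasisPotential:
    """OCP, OHP and OFP for one condition from its paired +/- t-PA curve sets.

    ``no_tpa_curves`` and ``tpa_curves`` are replicate lists of
    ``KineticCurve``; pairing is by condition identity, not well position,
    so the lists need not be equally long.  When the replicate-mean OCP is
    zero the OFP ratio is undefined and reported as ND rather than raised.
    """
    no_tpa_curves, tpa_curves = list(no_tpa_curves), list(tpa_curves)
    if not no_tpa_curves or not tpa_curves:
        raise ValueError("compute_potentials: both curve sets must be non-empty")
    for c in no_tpa_curves + tpa_curves:
        if abs(c.sampling_interval - no_tpa_curves[0].sampling_interval) > 1e-9:
            raise ValueError("compute_potentials: curves must share the sampling interval")
    n = len(no_tpa_curves)
    nd = nd_majority(detect_lag(c, cfg) is None for c in no_tpa_curves)
    if nd:
        return HemostasisPotential(None, None, None, n, True)
    ocp = _mean_sd([abs_sum_auc(c, cfg) for c in no_tpa_curves])
    ohp = _mean_sd([abs_sum_auc(c, cfg) for c in tpa_curves])
    ofp = _ofp_from_means(ocp, ohp)
    return HemostasisPotential(ocp, ohp, ofp, n, False)


def _ofp_from_means(ocp: MeanSD, ohp: MeanSD) -> Optional[MeanSD]:
    if ocp.mean == 0:
        return None
    mean = (ocp.mean - ohp.mean) / ocp.mean * 100.0
    # first-order (delta-method) propagation, OCP and OHP independent
    d_ocp = 100.0 * ohp.mean / ocp.mean ** 2
    d_ohp = -100.0 / ocp.mean
    sd = math.hypot(d_ocp * ocp.sd, d_ohp * ohp.sd)
    return MeanSD(mean, sd)


NORMAL_RANGE_PARAMS = ("ocp", "ohp", "ofp", "lag", "ttp", "rate", "slope_time", "max_abs")


@dataclass(frozen=True)
class NormalRange:
    """Per-parameter (min, max) envelope over repeated PNP runs.

    ``ranges`` maps parameter name -> (min, max); a parameter observed in
    no run at all is absent from the mapping.
    """

    ranges: dict[str, tuple[float, float]]
    n_runs: int

    def __getitem__(self, param: str) -> tuple[float, float]:
        return self.ranges[param]

    def __contains__(self, param: str) -> bool:
        return param in self.ranges


def normal_range(pnp_runs) -> NormalRange:
    """Min-max normal ranges from repeated pooled-normal-plasma runs.

    ``pnp_runs`` is a list of per-run records: mappings from parameter name
    (subset of ``NORMAL_RANGE_PARAMS``) to a value or None (ND).  ND runs
    are excluded per parameter with a warning; at least two runs overall
    are required for a range to be meaningful.
    """
    runs = list(pnp_runs)
    if len(runs) < 2:
        raise ValueError("normal_range: need at least 2 PNP runs (range undefined)")
    ranges: dict[str, tuple[float, float]] = {}
    for param in NORMAL_RANGE_PARAMS:
        vals = [run[param] for run in runs if param in run and run[param] is not None]
        dropped = sum(1 for run in runs if param in run and run[param] is None)
        if dropped:
            warnings.warn(f"normal_range: {dropped} ND PNP run(s) excluded for {param!r}")
        if vals:
            ranges[param] = (float(min(vals)), float(max(vals)))
    return NormalRange(ranges=ranges, n_runs=len(runs))
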