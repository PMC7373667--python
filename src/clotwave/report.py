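"""Condition-level summary tables, fold-changes and range classification.

Builds the familiar assay-report shape: one row per condition (pooled
normal plasma first, then single agents and combinations, doses
descending), each cell a mean +/- SD or the literal string ``ND``.
Fold-change is directional and explicit: a "2.5-fold shortening" of the
lag means reference / value = 2.5, while a "2-fold increase" of a rate
means value / reference = 2; the direction is always an argument, never
inferred from the numbers.  Classification against a min-max normal
range is inclusive at the bounds and carries no clinical interpretation
by itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import AssayCondition, Plasma
from .potentials import HemostasisPotential, MeanSD, nd_majority
from .waveform import TurbidityParams

__all__ = [
    "Direction",
    "Classification",
    "ConditionSummary",
    "fold_change",
    "round_fold",
    "classify",
    "summarize_condition",
    "build_condition_table",
    "PARAM_ORDER",
]


class Direction(str, enum.Enum):
    INCREASE = "increase"
    SHORTENING = "shortening"


class Classification(str, enum.Enum):
    BELOW_RANGE = "below_range"
    IN_RANGE = "in_range"
    ABOVE_RANGE = "above_range"


def fold_change(value: float, reference: float, direction: Direction) -> float:
    """Directional fold-change of ``value`` against ``reference``.

    ``SHORTENING`` (or any decrease) reports reference / value, so that a
    lag dropping from 10 to 4 minutes is a 2.5-fold shortening;
    ``INCREASE`` reports value / reference.
    """
    if not reference > 0:
        raise ValueError(f"fold_change: reference must be > 0, got {reference!r}")
    direction = Direction(direction)
    if direction is Direction.SHORTENING:
        if not value > 0:
            raise ValueError(f"fold_change: shortening needs value > 0, got {value!r}")
        return reference / value
    return value / reference


def round_fold(fold: float, integer_style: bool = False) -> float:
    """Rounding convention for prose fold-change claims.

    Decimal claims ("2.5-fold") round to 1 decimal; integer-style claims
    ("two-fold") round to the nearest 0.5 first.
    """
    if integer_style:
        return round(fold * 2.0) / 2.0
    return round(fold, 1)


def classify(value: float, bounds: tuple[float, float]) -> Classification:
    """Position of a value against an inclusive (min, max) range."""
    lo, hi = bounds
    if not lo <= hi:
        raise ValueError(f"classify: invalid range {bounds!r}")
    if value < lo:
        return Classification.BELOW_RANGE
    if value > hi:
        return Classification.ABOVE_RANGE
    return Classification.IN_RANGE


# parameters reported per condition, in column order
PARAM_ORDER = ("ocp", "ohp", "lag", "ttp", "rate", "slope_time", "max_abs", "ofp")

_COLUMN_TITLES = {
    "ocp": "OCP (Abs-sum)",
    "ohp": "OHP (Abs-sum)",
    "lag": "Lag time (min)",
    "ttp": "Time to peak (min)",
    "rate": "Slope (AU/min)",
    "slope_time": "Slope time (min)",
    "max_abs": "Max Abs (AU)",
    "ofp": "OFP (%)",
}

# whether a short value of the parameter points toward hypercoagulability;
# reporting metadata only, not used by classify()
HYPERCOAGULABLE_WHEN = {
    "lag": "below_range",
    "ttp": "below_range",
    "slope_time": "below_range",
    "rate": "above_range",
    "ocp": "above_range",
    "ohp": "above_range",
    "max_abs": "above_range",
    "ofp": "below_range",
}


@dataclass(frozen=True)
class ConditionSummary:
    """One condition's aggregated parameters (mean +/- SD or ND)."""

    condition: AssayCondition
    params: dict  # name -> MeanSD | None
    n_replicates: int
    classifications: dict = field(default_factory=dict)  # name -> Classification
    fold_changes: dict = field(default_factory=dict)     # name -> float

    @property
    def label(self) -> str:
        return self.condition.label()


def _aggregate(values) -> Optional[MeanSD]:
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    arr = np.asarray(vals, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return MeanSD(float(np.mean(arr)), sd)


def summarize_condition(condition: AssayCondition, turbidity: list[TurbidityParams],
                        potential: HemostasisPotential,
                        normal=None, reference: Optional[dict] = None) -> ConditionSummary:
    """Aggregate one condition's replicate turbidity records and potentials.

    The turbidity block is ND (all kinetic cells ND) when the majority of
    replicates are ND, mirroring the potentials rule.  ``normal`` is an
    optional NormalRange for classification; ``reference`` an optional
    mapping of parameter -> reference mean for fold-changes (shortening
    for the time parameters, increase otherwise).
    """
    nd_block = nd_majority(tp.nd for tp in turbidity) if turbidity else True
    params: dict = {
        "ocp": potential.ocp,
        "ohp": potential.ohp,
        "ofp": potential.ofp_percent,
    }
    fields = {
        "lag": "lag_time_min",
        "ttp": "time_to_plateau_min",
        "rate": "clotting_rate_au_per_min",
        "slope_time": "slope_time_min",
        "max_abs": "max_abs_au",
    }
    for name, attr in fields.items():
        if nd_block:
            params[name] = None
        else:
            params[name] = _aggregate(getattr(tp, attr) for tp in turbidity if not tp.nd)
    classifications = {}
    if normal is not None:
        for name, ms in params.items():
            if ms is not None and name in normal:
                classifications[name] = classify(ms.mean, normal[name])
    folds = {}
    if reference:
        for name, ref in reference.items():
            ms = params.get(name)
            if ms is None or ref is None or not ref > 0 or not ms.mean > 0:
                continue
            direction = (Direction.SHORTENING if name in ("lag", "ttp", "slope_time")
                         else Direction.INCREASE)
            folds[name] = fold_change(ms.mean, ref, direction)
    n = len(turbidity) or potential.n_replicates
    return ConditionSummary(condition=condition, params=params, n_replicates=n,
                            classifications=classifications, fold_changes=folds)


def _sort_key(cond: AssayCondition):
    """Published row order: PNP, deficient plasma, SIA, aPCC, aPCC+SIA,
    rFVIIa, rFVIIa+SIA; within a block doses descend (SIA level first)."""
    s, a, r = cond.sia_nM, cond.apcc_mU_per_mL, cond.rfviia_ug_per_mL
    if cond.plasma is Plasma.PNP:
        group = 0
    elif not (s or a or r):
        group = 1
    elif s and not a and not r:
        group = 2
    elif a and not s:
        group = 3
    elif a and s:
        group = 4
    elif r and not s:
        group = 5
    else:
        group = 6
    return (group, -s, -a, -r)


def _fmt(ms: Optional[MeanSD], digits: int = 3) -> str:
    if ms is None:
        return "ND"
    return f"{ms.mean:.{digits}g} ± {ms.sd:.2g}"


def build_condition_table(summaries, fmt_digits: int = 3) -> pd.DataFrame:
    """Deterministic condition x parameter table with ND rendered literally.

    Row order follows the published arrangement (see ``_sort_key``); the
    same inputs always render to byte-identical output.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("build_condition_table: need at least one summary")
    ordered = sorted(summaries, key=lambda s: _sort_key(s.condition))
    rows = []
    for s in ordered:
        row = {"Condition": s.label}
        for p in PARAM_ORDER:
            row[_COLUMN_TITLES[p]] = _fmt(s.params.get(p), fmt_digits)
        rows.append(row)
    return pd.DataFrame(rows, columns=["Condition"] + [_COLUMN_TITLES[p] for p in PARAM_ORDER])
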