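"""Fibrin fiber thickness summaries and a synthetic measurement generator.

SEM analysis of a fixed clot yields a set of individual fiber thickness
measurements (nominally 50 randomly selected fibers per clot).  This
module reduces such sets to the reported mean +/- SD and provides a
truncated-normal generator so that cross-clot thickness ratios (e.g. the
thin-fiber phenotype of dense hypercoagulable clots versus normal plasma)
can be exercised without microscopy data.  Units are treated as opaque
lengths; ratios are unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FiberMeasurementSet",
    "FiberSummary",
    "summarize_fibers",
    "generate_fiber_set",
    "read_fiber_table",
    "write_fiber_table",
]

# physical floor for a measurable fiber, in the (opaque) length unit;
# published SDs are large relative to means, so an untruncated normal
# would produce non-physical non-positive thicknesses
_MIN_THICKNESS = 1.0


@dataclass(frozen=True)
class FiberMeasurementSet:
    """Individual fiber thickness measurements of one clot."""

    label: str
    thicknesses: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thicknesses, dtype=float)
        object.__setattr__(self, "thicknesses", t)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError(f"clot {self.label!r}: need a 1-D, non-empty measurement list")
        if not np.all(t > 0):
            raise ValueError(f"clot {self.label!r}: all thicknesses must be positive")

    @property
    def n(self) -> int:
        return len(self.thicknesses)


@dataclass(frozen=True)
class FiberSummary:
    label: str
    mean: float
    sd: float
    n: int


def summarize_fibers(measurements: FiberMeasurementSet) -> FiberSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of one clot's fibers."""
    if measurements.n < 2:
        raise ValueError(
            f"clot {measurements.label!r}: at least 2 measurements needed for a summary"
        )
    t = measurements.thicknesses
    return FiberSummary(label=measurements.label, mean=float(np.mean(t)),
                        sd=float(np.std(t, ddof=1)), n=measurements.n)


def generate_fiber_set(mean: float, sd: float, n: int = 50, seed: int = 0,
                       label: str = "synthetic") -> FiberMeasurementSet:
    """Draw ``n`` synthetic thicknesses from Normal(mean, sd) truncated below.

    The truncation floor is one length unit; draws are by rejection, which
    is cheap at the means/SDs of real clots.  Deterministic under ``seed``.
    """
    if not mean > 0:
        raise ValueError(f"generate_fiber_set: mean must be > 0, got {mean!r}")
    if sd < 0:
        raise ValueError(f"generate_fiber_set: sd must be >= 0, got {sd!r}")
    if n < 1:
        raise ValueError(f"generate_fiber_set: n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    if sd == 0:
        vals = np.full(n, float(mean))
    else:
        vals = np.empty(0)
        while len(vals) < n:
            draw = rng.normal(mean, sd, size=2 * n)
            vals = np.concatenate([vals, draw[draw >= _MIN_THICKNESS]])
        vals = vals[:n]
    return FiberMeasurementSet(label=label, thicknesses=vals)


def read_fiber_table(source) -> list[FiberMeasurementSet]:
    """Read a measurement CSV (columns ``clot_label, thickness``)."""
    df = pd.read_csv(source, comment="#")
    missing = [c for c in ("clot_label", "thickness") if c not in df.columns]
    if missing:
        raise ValueError(f"fiber table: missing column(s) {missing}")
    out = []
    for label in df["clot_label"].astype(str).drop_duplicates():
        vals = df.loc[df["clot_label"].astype(str) == label, "thickness"].to_numpy(dtype=float)
        out.append(FiberMeasurementSet(label=label, thicknesses=vals))
    return out


def write_fiber_table(sets, sink, header_lines=()) -> None:
    """Write measurement sets as the ``clot_label, thickness`` CSV."""
    sets = list(sets)
    if not sets:
        raise ValueError("write_fiber_table: no measurement sets")
    frames = [pd.DataFrame({"clot_label": s.label, "thickness": s.thicknesses}) for s in sets]
    text = "".join(f"# {line}\n" for line in header_lines)
    text += pd.concat(frames, ignore_index=True).to_csv(index=False, float_format="%.10g")
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
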