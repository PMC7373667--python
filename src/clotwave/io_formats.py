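"""Kinetic plate-reader tables and per-well condition metadata.

The on-disk dialect is deliberately plain: comma-separated UTF-8 text with a
header row, readable by any spreadsheet.  Two layouts are supported for the
kinetic table:

``long``
    columns ``well_id, time_s, abs_au`` — one row per reading.
``wide``
    column ``time_s`` plus one absorbance column per well.

Condition metadata travels in a sidecar table with one row per well
(``well_id, plasma, sia_nM, apcc_mU_per_mL, rfviia_ug_per_mL, tpa,
replicate``).  Lines starting with ``#`` are treated as comments so that
pipeline outputs can carry provenance headers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Plasma",
    "AssayCondition",
    "KineticCurve",
    "FormatError",
    "ValidationError",
    "read_kinetic_table",
    "write_kinetic_table",
    "read_condition_table",
    "write_condition_table",
]


class FormatError(ValueError):
    """The table cannot be parsed at all (missing columns, bad header...)."""


class ValidationError(ValueError):
    """The table parsed but violates a data invariant (named in the message)."""


class Plasma(str, enum.Enum):
    PNP = "PNP"
    FVIII_DEFICIENT = "FVIII_deficient"


@dataclass(frozen=True)
class AssayCondition:
    """Agents spiked into one well, plus plasma type and replicate id.

    Concentrations are final concentrations in the reaction mix: SIA in nM,
    aPCC in mU/mL, rFVIIa in µg/mL.  ``tpa_present`` marks the fibrinolysis
    arm of the assay (t-PA at 300 ng/mL when true).
    """

    plasma: Plasma
    sia_nM: float = 0.0
    apcc_mU_per_mL: float = 0.0
    rfviia_ug_per_mL: float = 0.0
    tpa_present: bool = False
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("sia_nM", "apcc_mU_per_mL", "rfviia_ug_per_mL"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate!r}")

    @property
    def key(self) -> tuple:
        """Condition identity, ignoring replicate and t-PA arm."""
        return (self.plasma, self.sia_nM, self.apcc_mU_per_mL, self.rfviia_ug_per_mL)

    def label(self) -> str:
        if self.plasma is Plasma.PNP:
            return "Pooled normal plasma"
        parts = []
        if self.apcc_mU_per_mL > 0:
            parts.append(f"aPCC ({self.apcc_mU_per_mL:g} mU/mL)")
        if self.rfviia_ug_per_mL > 0:
            parts.append(f"rFVIIa ({self.rfviia_ug_per_mL:g} ug/mL)")
        if self.sia_nM > 0:
            parts.append(f"SIA ({self.sia_nM:g} nM)")
        return " + ".join(parts) if parts else "FVIII-deficient plasma"

    def with_tpa(self, tpa: bool) -> "AssayCondition":
        return replace(self, tpa_present=tpa)


@dataclass(frozen=True)
class KineticCurve:
    """One well's absorbance time series (405 nm), times in seconds."""

    times: np.ndarray
    absorbances: np.ndarray
    well_id: str = ""
    sampling_interval: float = field(default=0.0)
    duration: float = field(default=0.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)
        label = self.well_id or "<curve>"
        if t.ndim != 1 or a.ndim != 1 or len(t) != len(a):
            raise ValidationError(f"well {label}: times and absorbances must be 1-D and equal length")
        if len(t) < 2:
            raise ValidationError(f"well {label}: a kinetic curve needs at least 2 readings")
        dt = np.diff(t)
        if not np.all(dt > 0):
            i = int(np.argmin(dt))
            raise ValidationError(
                f"well {label}: times must be strictly increasing "
                f"(t[{i}]={t[i]:g} followed by t[{i + 1}]={t[i + 1]:g})"
            )
        if not np.all(np.isfinite(a)):
            bad = np.flatnonzero(~np.isfinite(a))
            raise ValidationError(f"well {label}: non-finite absorbance at reading index {bad[0]}")
        if not np.all(np.isfinite(t)):
            raise ValidationError(f"well {label}: non-finite time value")
        if self.sampling_interval == 0.0:
            object.__setattr__(self, "sampling_interval", float(np.median(dt)))
        elif self.sampling_interval <= 0:
            raise ValidationError(f"well {label}: sampling_interval must be > 0")
        if self.duration == 0.0:
            object.__setattr__(self, "duration", float(t[-1]))

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# kinetic tables

_LONG_COLS = ["well_id", "time_s", "abs_au"]


def _read_csv(source, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(source, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"could not parse {what}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _numeric(df: pd.DataFrame, col: str, what: str) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.index[vals.isna() & raw.notna()]
    if len(bad):
        # +2: header line and 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValidationError(f"{what}: non-numeric {col!r} value(s) at line(s) {lines}")
    nan = vals.index[raw.isna()]
    if len(nan):
        lines = ", ".join(str(i + 2) for i in nan[:10])
        raise ValidationError(f"{what}: missing {col!r} value(s) at line(s) {lines}")
    return vals.to_numpy(dtype=float)


def read_kinetic_table(source, layout: str = "long", metadata=None):
    """Read a kinetic CSV (and optional metadata sidecar).

    Parameters
    ----------
    source:
        Path or text stream holding the kinetic table.
    layout:
        ``"long"`` or ``"wide"`` (see module docstring).
    metadata:
        Optional path/stream of the condition sidecar table.  When absent,
        conditions are ``None``.

    Returns
    -------
    list of ``(AssayCondition | None, KineticCurve)`` pairs, one per well, in
    first-appearance order.
    """
    df = _read_csv(source, "kinetic table")
    if "time_s" not in df.columns:
        raise FormatError(f"kinetic table: missing time column 'time_s' (found {list(df.columns)})")
    curves: list[KineticCurve] = []
    if layout == "long":
        missing = [c for c in _LONG_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"kinetic table (long layout): missing column(s) {missing}")
        times = _numeric(df, "time_s", "kinetic table")
        absv = _numeric(df, "abs_au", "kinetic table")
        wells = df["well_id"].astype(str)
        for well in wells.drop_duplicates():
            m = (wells == well).to_numpy()
            curves.append(KineticCurve(times[m], absv[m], well_id=well))
    elif layout == "wide":
        times = _numeric(df, "time_s", "kinetic table")
        well_cols = [c for c in df.columns if c != "time_s"]
        if not well_cols:
            raise FormatError("kinetic table (wide layout): no well columns found")
        for well in well_cols:
            vals = _numeric(df, well, "kinetic table")
            curves.append(KineticCurve(times, vals, well_id=well))
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")

    conditions: dict[str, AssayCondition] = {}
    if metadata is not None:
        conditions = read_condition_table(metadata)
        for _, curve in _iter_named(curves):
            if curve.well_id not in conditions:
                raise ValidationError(f"metadata table has no row for well {curve.well_id!r}")
    return [(conditions.get(c.well_id), c) for c in curves]


def _iter_named(curves):
    for c in curves:
        yield c.well_id, c


def write_kinetic_table(pairs, sink, layout: str = "long", metadata_sink=None,
                        precision: int = 10, header_lines=()) -> None:
    """Write ``(condition, curve)`` pairs as a kinetic CSV.

    ``precision`` is the number of significant digits used for the decimal
    text representation; the default round-trips float64 well below 1e-9 AU.
    An optional ``metadata_sink`` receives the condition sidecar table.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("write_kinetic_table: empty curve list")
    fmt = f"%.{precision}g"
    if layout == "long":
        frames = [
            pd.DataFrame({"well_id": curve.well_id, "time_s": curve.times, "abs_au": curve.absorbances})
            for _, curve in pairs
        ]
        out = pd.concat(frames, ignore_index=True)
    elif layout == "wide":
        t0 = pairs[0][1].times
        for _, curve in pairs:
            if len(curve.times) != len(t0) or not np.array_equal(curve.times, t0):
                raise ValidationError("wide layout requires all wells to share the same time grid")
        out = pd.DataFrame({"time_s": t0})
        for _, curve in pairs:
            out[curve.well_id] = curve.absorbances
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    _write_csv(out, sink, fmt, header_lines)
    if metadata_sink is not None:
        conds = [(curve.well_id, cond) for cond, curve in pairs if cond is not None]
        write_condition_table(conds, metadata_sink, header_lines=header_lines)


def _write_csv(df: pd.DataFrame, sink, fmt: str, header_lines=()) -> None:
    text = "".join(f"# {line}\n" for line in header_lines)
    text += df.to_csv(index=False, float_format=fmt)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        try:
            with open(sink, "w", encoding="utf-8", newline="") as fh:
                fh.write(text)
        except OSError as exc:
            raise OSError(f"could not write table to {sink!r}: {exc}") from exc


_META_COLS = ["well_id", "plasma", "sia_nM", "apcc_mU_per_mL", "rfviia_ug_per_mL", "tpa", "replicate"]


def read_condition_table(source) -> dict[str, AssayCondition]:
    """Read the metadata sidecar; returns ``{well_id: AssayCondition}``."""
    df = _read_csv(source, "metadata table")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table: missing column(s) {missing}")
    out: dict[str, AssayCondition] = {}
    for i, row in df.iterrows():
        well = str(row["well_id"])
        try:
            plasma = Plasma(str(row["plasma"]))
        except ValueError:
            raise ValidationError(
                f"metadata table line {i + 2}: unknown plasma {row['plasma']!r} "
                f"(expected one of {[p.value for p in Plasma]})"
            ) from None
        out[well] = AssayCondition(
            plasma=plasma,
            sia_nM=float(row["sia_nM"]),
            apcc_mU_per_mL=float(row["apcc_mU_per_mL"]),
            rfviia_ug_per_mL=float(row["rfviia_ug_per_mL"]),
            tpa_present=bool(int(row["tpa"])),
            replicate=int(row["replicate"]),
        )
    return out


def write_condition_table(named_conditions, sink, header_lines=()) -> None:
    """Write ``(well_id, AssayCondition)`` pairs as the metadata sidecar."""
    rows = [
        {
            "well_id": well,
            "plasma": cond.plasma.value,
            "sia_nM": cond.sia_nM,
            "apcc_mU_per_mL": cond.apcc_mU_per_mL,
            "rfviia_ug_per_mL": cond.rfviia_ug_per_mL,
            "tpa": int(cond.tpa_present),
            "replicate": cond.replicate,
        }
        for well, cond in named_conditions
    ]
    if not rows:
        raise ValueError("write_condition_table: no conditions to write")
    _write_csv(pd.DataFrame(rows, columns=_META_COLS), sink, "%.10g", header_lines)
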