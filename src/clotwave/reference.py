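"""Published reference means for the in vitro hemophilia-A assay panel.

These are the condition-level summary values (mean +/- SD over triplicate
wells) reported for the combined OHP / fibrin-clot-turbidity assay in
FVIII-deficient plasma spiked with SIA, aPCC and rFVIIa, with pooled
normal plasma (PNP) as control, plus the SEM fiber-thickness summaries of
the representative clots.  They serve three purposes here:

* the condition grid for the synthetic generator (the study's panel),
* loose calibration targets for the default dose-response model,
* inputs for in-table fold-change and ratio checks in the report layer.

``None`` encodes ND (nondetectable: no significant fibrin aggregation
within the 1-hour window).  OCP/OHP are Abs-sum AUC values in the source
instrument's scale; lag and time-to-peak are minutes; the clotting rate
column is in AU/min by this package's convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io_formats import AssayCondition, Plasma

__all__ = [
    "ReferenceRow",
    "REFERENCE_PANEL",
    "REFERENCE_FIBERS",
    "reference_row",
    "reference_conditions",
    "condition_grid",
]


@dataclass(frozen=True)
class ReferenceRow:
    condition: AssayCondition
    ocp: Optional[float]
    ocp_sd: Optional[float]
    ohp: Optional[float]
    ohp_sd: Optional[float]
    lag_min: Optional[float]
    lag_sd: Optional[float]
    ttp_min: Optional[float]
    ttp_sd: Optional[float]
    rate: Optional[float]
    rate_sd: Optional[float]

    @property
    def nd(self) -> bool:
        return self.ocp is None


def _c(plasma=Plasma.FVIII_DEFICIENT, sia=0.0, apcc=0.0, rfviia=0.0) -> AssayCondition:
    return AssayCondition(plasma=plasma, sia_nM=sia, apcc_mU_per_mL=apcc, rfviia_ug_per_mL=rfviia)


_ND = (None,) * 10

REFERENCE_PANEL: tuple[ReferenceRow, ...] = (
    ReferenceRow(_c(plasma=Plasma.PNP), 239, 17, 92.2, 13.2, 10, 3, 16, 2, 0.03, 0.003),
    ReferenceRow(_c(), *_ND),
    ReferenceRow(_c(sia=600), 189, 17, 42.8, 7.8, 13, 0.5, 30, 3.1, 0.012, 0.0025),
    ReferenceRow(_c(sia=200), 165, 15, 36.3, 2.6, 14, 0.5, 36, 2.1, 0.009, 0.001),
    ReferenceRow(_c(sia=60), 125, 1, 29.6, 2.7, 16, 0.5, 48, 2.9, 0.006, 0.0001),
    ReferenceRow(_c(sia=10), *_ND),
    ReferenceRow(_c(apcc=1000), 258, 6, 74.5, 5.1, 5, 0.7, 12, 0.5, 0.03, 0.0019),
    ReferenceRow(_c(apcc=500), 254, 3, 73.0, 2.1, 8, 0.2, 17, 0.1, 0.02, 0.0002),
    ReferenceRow(_c(apcc=250), 210, 14, 58.9, 2.5, 11, 1.2, 26, 2.1, 0.01, 0.0009),
    ReferenceRow(_c(apcc=50), *_ND),
    ReferenceRow(_c(apcc=25), *_ND),
    ReferenceRow(_c(apcc=1000, sia=600), 157, 5, 58.3, 1.6, 0.7, 0.1, 1.9, 0.1, 0.08, 0.005),
    ReferenceRow(_c(apcc=500, sia=600), 170, 8, 59.9, 1.1, 1.1, 0.3, 2.3, 0.3, 0.09, 0.002),
    ReferenceRow(_c(apcc=250, sia=600), 188, 3, 63, 0.4, 1.8, 0.2, 3.3, 0.2, 0.08, 0.0021),
    ReferenceRow(_c(apcc=50, sia=600), 224, 5, 70.2, 1.7, 3.5, 0.3, 6.2, 0.5, 0.05, 0.002),
    ReferenceRow(_c(apcc=25, sia=600), 239, 5, 74.1, 4.5, 4.8, 0.2, 8.7, 0.3, 0.04, 0.002),
    ReferenceRow(_c(apcc=1000, sia=200), 166, 10, 66.2, 6.4, 0.9, 0.3, 2.1, 0.3, 0.09, 0.002),
    ReferenceRow(_c(apcc=500, sia=200), 188, 8, 65.5, 3.7, 1.7, 0.1, 3.1, 0.1, 0.08, 0.001),
    ReferenceRow(_c(apcc=250, sia=200), 206, 10, 73.9, 14.5, 2.3, 0.4, 4.0, 0.4, 0.07, 0.002),
    ReferenceRow(_c(apcc=50, sia=200), 240, 7, 73.6, 7.5, 4.0, 0.0, 8.3, 0.1, 0.04, 0.001),
    ReferenceRow(_c(apcc=25, sia=200), 253, 7, 74.4, 4.9, 5.9, 0.6, 10.8, 0.6, 0.04, 0.003),
    ReferenceRow(_c(rfviia=5.25), 37, 2, 1.3, 0.5, 13, 0.1, 49, 0.8, 0.01, 0.0004),
    ReferenceRow(_c(rfviia=1.75), *_ND),
    ReferenceRow(_c(rfviia=0.88), *_ND),
    ReferenceRow(_c(rfviia=5.25, sia=600), 226, 7, 50.4, 0.6, 11, 0.1, 18, 0.3, 0.03, 0.001),
    ReferenceRow(_c(rfviia=1.75, sia=600), 191, 8, 43, 0.8, 16, 1.1, 24, 1.8, 0.02, 0.003),
    ReferenceRow(_c(rfviia=0.88, sia=600), 172, 8, 40.3, 1.8, 17, 2, 27, 2.8, 0.02, 0.002),
    ReferenceRow(_c(rfviia=5.25, sia=200), 200, 4, 41.4, 2.5, 15, 0.2, 25, 0.35, 0.02, 0.0002),
    ReferenceRow(_c(rfviia=1.75, sia=200), 164, 3, 36.9, 0.9, 20, 0.4, 34, 0.64, 0.02, 0.001),
    ReferenceRow(_c(rfviia=0.88, sia=200), 136, 14, 34.3, 4.8, 24, 1.9, 37, 1.13, 0.01, 0.0004),
)

# SEM fiber thickness of the representative clots: label -> (mean, SD), in
# the length unit of the source measurements (presumed nm); None = ND.
REFERENCE_FIBERS: dict[tuple, Optional[tuple[float, float]]] = {
    _c(plasma=Plasma.PNP).key: (160, 63),
    _c().key: None,
    _c(sia=600).key: (155, 78),
    _c(sia=200).key: (171, 98),
    _c(apcc=500).key: (150, 41),
    _c(apcc=50).key: (220, 123),
    _c(apcc=500, sia=600).key: (81, 22),
    _c(apcc=500, sia=200).key: (92, 24),
    _c(apcc=50, sia=600).key: (96, 26),
    _c(apcc=50, sia=200).key: (111, 28),
    _c(rfviia=5.25).key: None,
    _c(rfviia=1.75).key: None,
    _c(rfviia=5.25, sia=600).key: (135, 68),
    _c(rfviia=5.25, sia=200).key: (129, 55),
    _c(rfviia=1.75, sia=600).key: (182, 77),
    _c(rfviia=1.75, sia=200).key: (132, 100),
}


def reference_row(condition: AssayCondition) -> ReferenceRow:
    """The reference panel row matching a condition (ignores t-PA/replicate)."""
    for row in REFERENCE_PANEL:
        if row.condition.key == condition.key:
            return row
    raise KeyError(f"no reference row for condition {condition.label()!r}")


def reference_conditions() -> list[AssayCondition]:
    """The panel's distinct conditions, in published row order."""
    return [row.condition for row in REFERENCE_PANEL]


def condition_grid(replicates: int = 3, tpa_arms=(False, True)) -> list[AssayCondition]:
    """The full simulation grid: panel conditions x t-PA arms x replicates."""
    from dataclasses import replace

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = []
    for cond in reference_conditions():
        for tpa in tpa_arms:
            for rep in range(1, replicates + 1):
                grid.append(replace(cond, tpa_present=tpa, replicate=rep))
    return grid
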