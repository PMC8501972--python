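"""Per-cell relative-fluorescence statistic, QC, and control normalization.

The per-cell statistic is

    raw_ratio = (Red_anchor - Red_nucleus) / (Green_anchor - Green_nucleus)

where each term is the arithmetic mean intensity (average gray value) over the
anchor mask or the whole-nucleus reference mask in the red (protein of interest) or
green (RNA trap) channel.  Subtracting the nucleus-wide means removes the diffuse
background of each channel; dividing by the green excess normalizes for the amount
of trap at the anchor, so the ratio is invariant to additive offsets in either
channel and scales linearly with the red channel only.

Each cell's ratio is then divided by the mean raw ratio of the no-RNA control
group, so the control group's normalized mean is exactly 1 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rf3h.io_formats import MultiChannelImage
from rf3h.segmentation import SegmentedCell

QC_PASS = "pass"
QC_NO_ANCHOR = "no_anchor"
QC_WEAK_TRAP = "weak_trap"
QC_AREA = "nucleus_area_out_of_bounds"


@dataclass
class CellMeasurement:
    """The four mean intensities of one cell plus the derived ratio and QC state."""

    green_anchor: float
    green_nucleus: float
    red_anchor: float
    red_nucleus: float
    nucleus_area_px: int = 0
    anchor_area_px: int = 0
    raw_ratio: float = math.nan
    normalized_value: float = math.nan
    qc_pass: bool = True
    qc_reason: str = QC_PASS
    condition: str = ""
    cell_label: int = 0
    source_id: str = ""


@dataclass
class QCRules:
    """Cell-level quality-control parameters.

    ``denom_floor_frac`` sets the denominator floor to this fraction of the cell's
    nucleus-wide green mean: a cell whose green anchor excess does not exceed it has
    no usable trap spot (untransfected or weak-trap cell) and is excluded.
    """

    denom_floor_frac: float = 0.05
    min_nucleus_area_px: float = 0.0
    max_nucleus_area_px: float = math.inf


@dataclass
class ConditionGroup:
    """Per-cell normalized values for one condition, with summary statistics."""

    label: str
    is_control: bool
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.n else math.nan

    @property
    def sd(self) -> float:
        # Sample SD (n-1 denominator); undefined for n < 2.
        return float(np.std(self.values, ddof=1)) if self.n >= 2 else math.nan


def measure_cell(
    image: MultiChannelImage, cell: SegmentedCell, condition: str = ""
) -> CellMeasurement:
    """Mean intensities over the anchor and whole-nucleus masks in both channels.

    An empty anchor mask flags the cell ``no_anchor``; the nucleus-wide means are
    still recorded.
    """
    if not cell.reference_mask.any():
        raise ValueError("reference_mask is empty")
    green = image.trap_green
    red = image.poi_red
    green_nuc = float(green[cell.reference_mask].mean())
    red_nuc = float(red[cell.reference_mask].mean())
    has_anchor = bool(cell.anchor_mask.any())
    if has_anchor:
        green_anchor = float(green[cell.anchor_mask].mean())
        red_anchor = float(red[cell.anchor_mask].mean())
    else:
        green_anchor = math.nan
        red_anchor = math.nan
    return CellMeasurement(
        green_anchor=green_anchor,
        green_nucleus=green_nuc,
        red_anchor=red_anchor,
        red_nucleus=red_nuc,
        nucleus_area_px=cell.nucleus_area_px,
        anchor_area_px=cell.anchor_area_px,
        qc_pass=has_anchor,
        qc_reason=QC_PASS if has_anchor else QC_NO_ANCHOR,
        condition=condition,
        cell_label=cell.cell_label,
        source_id=cell.source_id or image.source_id,
    )


def relative_fluorescence(m: CellMeasurement, denom_floor: float) -> float:
    """(Red_anchor - Red_nucleus) / (Green_anchor - Green_nucleus).

    Defined only when the green excess exceeds ``denom_floor`` (in the same
    arbitrary units as the image); otherwise the cell is flagged ``weak_trap`` and
    NaN is returned.  Negative ratios (a red dip at the anchor) are kept, not
    clipped.  The result is stored on ``m.raw_ratio``.
    """
    denom = m.green_anchor - m.green_nucleus
    if not math.isfinite(denom) or denom <= denom_floor:
        m.qc_pass = False
        if m.qc_reason == QC_PASS:
            m.qc_reason = QC_WEAK_TRAP
        m.raw_ratio = math.nan
        return math.nan
    m.raw_ratio = (m.red_anchor - m.red_nucleus) / denom
    return m.raw_ratio


def qc_filter(
    records: list[CellMeasurement], rules: QCRules | None = None
) -> tuple[list[CellMeasurement], list[CellMeasurement]]:
    """Apply QC, computing each cell's raw ratio along the way.

    Rejects cells with an empty anchor, a green excess at or below the denominator
    floor, or a nucleus area outside bounds.  Every rejection carries a reason code;
    kept + rejected partition the input.
    """
    rules = rules or QCRules()
    kept: list[CellMeasurement] = []
    rejected: list[CellMeasurement] = []
    for m in records:
        if m.qc_reason == QC_NO_ANCHOR or m.anchor_area_px == 0:
            m.qc_pass = False
            m.qc_reason = QC_NO_ANCHOR
            rejected.append(m)
            continue
        if not rules.min_nucleus_area_px <= m.nucleus_area_px <= rules.max_nucleus_area_px:
            m.qc_pass = False
            m.qc_reason = QC_AREA
            rejected.append(m)
            continue
        floor = rules.denom_floor_frac * m.green_nucleus
        relative_fluorescence(m, denom_floor=floor)
        if not m.qc_pass:
            rejected.append(m)
        else:
            kept.append(m)
    return kept, rejected


def group_measurements(
    records: list[CellMeasurement], control_label: str, labels: list[str] | None = None
) -> list[ConditionGroup]:
    """Collect QC-passing raw ratios into per-condition groups (still un-normalized)."""
    if labels is None:
        labels = list(dict.fromkeys(m.condition for m in records))
    groups = []
    for lab in labels:
        raws = [m.raw_ratio for m in records if m.condition == lab and m.qc_pass]
        groups.append(ConditionGroup(label=lab, is_control=(lab == control_label), values=raws))
    if sum(g.is_control for g in groups) != 1:
        raise ValueError(f"control label {control_label!r} matched {0} or >1 groups")
    return groups


def normalize_by_control(
    groups: list[ConditionGroup], records: list[CellMeasurement] | None = None
) -> list[ConditionGroup]:
    """Divide every cell's raw ratio by the control group's mean raw ratio.

    Requires exactly one control group with at least 3 QC-passing cells and a
    positive mean; the control's normalized mean is exactly 1 by construction.
    When ``records`` is given, each measurement's ``normalized_value`` is filled in
    as well.
    """
    controls = [g for g in groups if g.is_control]
    if len(controls) != 1:
        raise ValueError(f"exactly one control group required; found {len(controls)}")
    control = controls[0]
    if control.n < 3:
        raise ValueError(f"control group has {control.n} QC-passing cells; >= 3 required")
    divisor = control.mean
    if not (divisor > 0):
        raise ValueError(f"control mean raw ratio must be > 0 to normalize; got {divisor}")
    out = [
        ConditionGroup(label=g.label, is_control=g.is_control, values=g.values / divisor)
        for g in groups
    ]
    if records is not None:
        for m in records:
            if m.qc_pass and math.isfinite(m.raw_ratio):
                m.normalized_value = m.raw_ratio / divisor
    return out
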