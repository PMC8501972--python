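"""The relative-fluorescence statistic: hand oracles, invariances, QC, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rf3h.io_formats import MultiChannelImage
from rf3h.quantification import (
    CellMeasurement,
    ConditionGroup,
    QCRules,
    group_measurements,
    measure_cell,
    normalize_by_control,
    qc_filter,
    relative_fluorescence,
)
from rf3h.segmentation import SegmentedCell

ROLES = {"nuclear_stain": 0, "trap_green": 1, "poi_red": 2}


def _cell_fixture():
    """10-px nucleus, 2-px anchor; whole-nucleus means are 10 (green) and 5 (red)."""
    h, w = 8, 8
    nucleus = np.zeros((h, w), bool)
    nucleus[2, 2:7] = True
    nucleus[3, 2:7] = True  # 10 pixels
    anchor = np.zeros((h, w), bool)
    anchor[2, 3] = True
    anchor[2, 4] = True
    green = np.zeros((h, w))
    red = np.zeros((h, w))
    green[nucleus] = 5.0
    green[2, 3], green[2, 4] = 28.0, 32.0  # anchor mean 30; nucleus mean (60+40)/10 = 10
    red[nucleus] = 2.5
    red[2, 3], red[2, 4] = 14.0, 16.0  # anchor mean 15; nucleus mean (30+20)/10 = 5
    img = MultiChannelImage(np.stack([np.ones((h, w)), green, red]), ROLES, source_id="fx")
    cell = SegmentedCell(1, nucleus, anchor, nucleus.copy(), source_id="fx")
    return img, cell


def test_measure_cell_hand_oracle():
    img, cell = _cell_fixture()
    m = measure_cell(img, cell, condition="c")
    assert m.red_anchor == pytest.approx(15.0)
    assert m.red_nucleus == pytest.approx(5.0)
    assert m.green_anchor == pytest.approx(30.0)
    assert m.green_nucleus == pytest.approx(10.0)
    assert relative_fluorescence(m, denom_floor=0.5) == pytest.approx(0.5)


def test_uniform_image_gives_equal_means():
    img, cell = _cell_fixture()
    uniform = MultiChannelImage(np.full((3, 8, 8), 42.0), ROLES)
    m = measure_cell(uniform, cell)
    assert m.red_anchor == m.red_nucleus == 42.0
    assert m.green_anchor == m.green_nucleus == 42.0


def test_single_pixel_masks_return_pixel_values():
    img, _ = _cell_fixture()
    mask_n = np.zeros((8, 8), bool)
    mask_n[2, 3] = True
    cell = SegmentedCell(1, mask_n, mask_n.copy(), mask_n.copy())
    m = measure_cell(img, cell)
    assert m.green_anchor == 28.0 and m.red_anchor == 14.0


def test_empty_anchor_flags_no_anchor_but_keeps_reference_means():
    img, cell = _cell_fixture()
    cell.anchor_mask = np.zeros((8, 8), bool)
    m = measure_cell(img, cell)
    assert not m.qc_pass and m.qc_reason == "no_anchor"
    assert m.red_nucleus == pytest.approx(5.0)
    assert math.isnan(m.red_anchor)


def test_no_red_enrichment_gives_zero_ratio():
    m = CellMeasurement(green_anchor=30, green_nucleus=10, red_anchor=5, red_nucleus=5)
    assert relative_fluorescence(m, 0.5) == 0.0


@settings(derandomize=True, max_examples=60)
@given(offset=st.floats(-50, 500), scale=st.floats(0.01, 100))
def test_offset_invariance_and_red_scale_equivariance(offset, scale):
    base = dict(green_anchor=30.0, green_nucleus=10.0, red_anchor=15.0, red_nucleus=5.0)
    ref = relative_fluorescence(CellMeasurement(**base), 0.0)
    shifted = CellMeasurement(
        green_anchor=base["green_anchor"] + offset,
        green_nucleus=base["green_nucleus"] + offset,
        red_anchor=base["red_anchor"] + offset,
        red_nucleus=base["red_nucleus"] + offset,
    )
    assert relative_fluorescence(shifted, 0.0) == pytest.approx(ref, rel=1e-12)
    red_scaled = CellMeasurement(
        green_anchor=base["green_anchor"],
        green_nucleus=base["green_nucleus"],
        red_anchor=base["red_anchor"] * scale,
        red_nucleus=base["red_nucleus"] * scale,
    )
    assert relative_fluorescence(red_scaled, 0.0) == pytest.approx(ref * scale, rel=1e-12)


def test_weak_trap_rejected_when_denominator_at_floor():
    m = CellMeasurement(green_anchor=10.0, green_nucleus=10.0, red_anchor=9.0, red_nucleus=5.0)
    assert math.isnan(relative_fluorescence(m, denom_floor=0.5))
    assert not m.qc_pass and m.qc_reason == "weak_trap"


def test_normalized_values_invariant_when_all_cells_share_red_scaling():
    # duplicated image set: scaling the red channel by c scales every raw ratio by c
    # and leaves normalized values unchanged
    raws = np.array([0.4, 0.5, 0.6, 1.0, 1.1])
    conditions = ["ctl", "ctl", "ctl", "t", "t"]
    for c in (1.0, 7.3):
        groups = [
            ConditionGroup("ctl", True, c * raws[:3]),
            ConditionGroup("t", False, c * raws[3:]),
        ]
        normalized = normalize_by_control(groups)
        assert normalized[0].mean == pytest.approx(1.0)
        assert normalized[1].values == pytest.approx(raws[3:] / raws[:3].mean())
    del conditions


def test_normalize_by_control_examples_and_guards():
    groups = [
        ConditionGroup("ctl", True, [0.4, 0.5, 0.6]),  # mean 0.5
        ConditionGroup("t", False, [1.0]),
    ]
    out = normalize_by_control(groups)
    assert out[1].values[0] == pytest.approx(2.0)
    assert out[0].mean == pytest.approx(1.0)

    with pytest.raises(ValueError, match="> 0"):
        normalize_by_control(
            [ConditionGroup("ctl", True, [0.0, 0.0, 0.0]), ConditionGroup("t", False, [1.0])]
        )
    with pytest.raises(ValueError, match=">= 3"):
        normalize_by_control(
            [ConditionGroup("ctl", True, [0.4, 0.6]), ConditionGroup("t", False, [1.0])]
        )
    with pytest.raises(ValueError, match="exactly one control"):
        normalize_by_control([ConditionGroup("a", False, [1.0])])


def _passing_measurement(**overrides):
    fields = dict(
        green_anchor=30.0,
        green_nucleus=10.0,
        red_anchor=15.0,
        red_nucleus=5.0,
        nucleus_area_px=900,
        anchor_area_px=60,
        condition="c",
    )
    fields.update(overrides)
    return CellMeasurement(**fields)


def test_qc_filter_mixed_fixture_rejects_exactly_the_violations():
    records = [
        _passing_measurement(cell_label=1),
        _passing_measurement(cell_label=2, green_anchor=10.0),  # weak trap
        _passing_measurement(cell_label=3),
        _passing_measurement(cell_label=4, anchor_area_px=0, qc_pass=False,
                             qc_reason="no_anchor"),
        _passing_measurement(cell_label=5),
    ]
    kept, rejected = qc_filter(records, QCRules(denom_floor_frac=0.05))
    assert sorted(m.cell_label for m in kept) == [1, 3, 5]
    assert {m.cell_label: m.qc_reason for m in rejected} == {2: "weak_trap", 4: "no_anchor"}
    assert len(kept) + len(rejected) == len(records)
    for m in kept:
        assert m.raw_ratio == pytest.approx(0.5)


def test_qc_filter_all_passing_and_area_bounds():
    records = [_passing_measurement(cell_label=i) for i in range(3)]
    kept, rejected = qc_filter(records)
    assert rejected == []
    records = [_passing_measurement(nucleus_area_px=50)]
    kept, rejected = qc_filter(records, QCRules(min_nucleus_area_px=300))
    assert kept == [] and rejected[0].qc_reason == "nucleus_area_out_of_bounds"


def test_group_measurements_counts_only_qc_passing_cells():
    records = [
        _passing_measurement(condition="ctl", cell_label=i) for i in range(4)
    ] + [_passing_measurement(condition="t", green_anchor=10.0, cell_label=9)]
    kept, rejected = qc_filter(records)
    groups = group_measurements(kept + rejected, control_label="ctl", labels=["ctl", "t"])
    assert groups[0].n == 4
    assert groups[1].n == 0  # its only cell failed QC
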