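"""The synthetic-experiment generator: determinism, analytic oracle, presets."""

import dataclasses

import numpy as np
import pytest

from rf3h.quantification import measure_cell, relative_fluorescence
from rf3h.segmentation import SegmentedCell
from rf3h.simulate import (
    NoiseModel,
    NucleusModel,
    SimCondition,
    SimulationConfig,
    StructureModel,
    expected_normalized_value,
    expected_raw_ratio,
    figure_presets,
    preset_names,
    simulate_experiment,
)
from conftest import small_spot_config


def test_fixed_seed_gives_bit_identical_output():
    cfg = small_spot_config(seed=11, n_cells=4)
    a = simulate_experiment(cfg)
    b = simulate_experiment(cfg)
    for lab in a.images_by_condition:
        for ia, ib in zip(a.images_by_condition[lab], b.images_by_condition[lab]):
            assert np.array_equal(ia.pixels, ib.pixels)
    c = simulate_experiment(dataclasses.replace(cfg, seed=12))
    assert not np.array_equal(
        a.images_by_condition["control"][0].pixels,
        c.images_by_condition["control"][0].pixels,
    )


def test_images_are_finite_nonnegative_and_cells_disjoint():
    exp = simulate_experiment(small_spot_config(seed=3, n_cells=8))
    for images in exp.images_by_condition.values():
        for img in images:
            assert np.all(np.isfinite(img.pixels)) and np.all(img.pixels >= 0)
    by_img = {}
    for gt in exp.ground_truth:
        by_img.setdefault(gt.source_id, []).append(gt)
        assert not (gt.anchor_mask & ~gt.nucleus_mask).any()
        assert gt.anchor_mask.any()
    for gts in by_img.values():
        union = np.zeros_like(gts[0].nucleus_mask)
        for gt in gts:
            assert not (union & gt.nucleus_mask).any()
            union |= gt.nucleus_mask


def test_expected_ratio_independent_of_anchor_fraction_and_small_fraction_limit():
    cfg = small_spot_config(fold=2.0)
    vals = [expected_raw_ratio(cfg, "specific", anchor_fraction=f) for f in (1e-9, 0.05, 0.5)]
    assert vals[0] == pytest.approx(vals[1], rel=1e-9)
    assert vals[1] == pytest.approx(vals[2], rel=1e-9)
    # f -> 0 limit equals diffuse_red * (gain - 1) / green anchor excess
    g0 = cfg.red.nonspecific_gain
    gain = 1 + (g0 - 1) * 2.0
    d_r = cfg.red.diffuse_median * np.exp(cfg.red.expression_sigma**2 / 2)
    assert vals[0] == pytest.approx(d_r * (gain - 1) / cfg.green.anchor_excess, rel=1e-9)
    with pytest.raises(ValueError, match="degenerate"):
        expected_raw_ratio(cfg, "specific", anchor_fraction=0.0)


def test_null_fold_gives_unit_normalized_expectation():
    cfg = small_spot_config(fold=1.0)
    assert expected_normalized_value(cfg, "specific") == pytest.approx(1.0)
    assert expected_normalized_value(cfg, "control") == pytest.approx(1.0)


def test_doubling_binding_fold_doubles_normalized_expectation():
    for fold in (1.0, 1.5, 2.0, 3.0):
        cfg = small_spot_config(fold=fold)
        cfg2 = small_spot_config(fold=2 * fold)
        assert expected_normalized_value(cfg, "specific") == pytest.approx(fold, rel=1e-12)
        assert expected_normalized_value(cfg2, "specific") == pytest.approx(
            2 * expected_normalized_value(cfg, "specific"), rel=1e-12
        )


def test_noise_free_ratios_match_analytic_oracle_to_1e9():
    """With noise off and ground-truth masks injected, the pipeline statistic equals
    the closed-form per-cell expectation to 1e-9 relative error."""
    cfg = dataclasses.replace(
        small_spot_config(seed=7, n_cells=6), noise=NoiseModel(enabled=False)
    )
    exp = simulate_experiment(cfg)
    images = {
        img.source_id: img
        for imgs in exp.images_by_condition.values()
        for img in imgs
    }
    assert exp.ground_truth
    for gt in exp.ground_truth:
        cell = SegmentedCell(
            cell_label=gt.cell_index,
            nucleus_mask=gt.nucleus_mask,
            anchor_mask=gt.anchor_mask,
            reference_mask=gt.nucleus_mask.copy(),
            source_id=gt.source_id,
        )
        m = measure_cell(images[gt.source_id], cell, condition=gt.condition)
        ratio = relative_fluorescence(m, denom_floor=0.0)
        assert ratio == pytest.approx(gt.expected_raw_ratio, rel=1e-9)
        assert m.green_anchor == pytest.approx(gt.green_anchor, rel=1e-9)
        assert m.red_nucleus == pytest.approx(gt.red_nucleus, rel=1e-9)


def test_config_validation_catches_degenerate_geometry():
    with pytest.raises(ValueError, match="rim band"):
        SimulationConfig(
            conditions=[SimCondition("c", 4, 1.0, is_control=True)],
            geometry=figure_presets("F5_laminB1_INM").geometry,
            structure=StructureModel(rim_band_px=20),
            nucleus=NucleusModel(semi_axis_min_px=16, semi_axis_max_px=20),
        )
    with pytest.raises(ValueError, match="exactly one control"):
        SimulationConfig(conditions=[SimCondition("c", 4, 1.0)])
    with pytest.raises(ValueError, match="binding_fold = 1"):
        SimulationConfig(conditions=[SimCondition("c", 4, 2.0, is_control=True)])
    with pytest.raises(ValueError, match="nonspecific_gain"):
        cfg = small_spot_config()
        dataclasses.replace(cfg, red=dataclasses.replace(cfg.red, nonspecific_gain=1.0))


def test_figure_presets_match_reported_designs():
    f1 = figure_presets("F1_pp7_PCP")
    assert f1.geometry.kind == "single_spot"
    assert f1.condition("+ms2-pp7").n_cells == 24
    assert f1.condition("-RNA").is_control and f1.condition("-RNA").n_cells == 23
    assert expected_normalized_value(f1, "+ms2-pp7") == pytest.approx(2.0)

    f5 = figure_presets("F5_chromocenter_MCP")
    assert f5.geometry.kind == "multi_puncta"
    assert f5.condition("+ms2").n_cells == 26
    assert expected_normalized_value(f5, "+ms2") == pytest.approx(3.0)

    f2 = figure_presets("F2_polyA_PABPC1")
    assert expected_normalized_value(f2, "+ms2-polyA") == pytest.approx(2.0)
    f6 = figure_presets("F6_dCas13a_MCP")
    assert expected_normalized_value(f6, "+ms2 +gRNA") == pytest.approx(2.0)

    null = figure_presets("F1_pp7_PCP_null", seed=5)
    assert null.seed == 5
    for cond in null.conditions:
        assert expected_normalized_value(null, cond.label) == pytest.approx(1.0)

    with pytest.raises(KeyError, match="unknown preset"):
        figure_presets("F9_bogus")
    assert "F1_pp7_PCP_null" in preset_names()


def test_expression_sigma_leaves_normalized_expectation_invariant():
    for sigma in (0.1, 0.3, 0.5):
        cfg = small_spot_config(fold=2.0)
        cfg = dataclasses.replace(
            cfg, red=dataclasses.replace(cfg.red, expression_sigma=sigma)
        )
        assert expected_normalized_value(cfg, "specific") == pytest.approx(2.0, rel=1e-12)
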