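"""Config-driven end-to-end runner: images -> segmentation -> measurement -> QC ->
normalization -> statistics -> CSV artifacts, with a run log.

The run configuration is a single YAML/JSON document validated against a strict
schema (unknown keys rejected) before any computation.  ``run_simulate`` writes a
synthetic dataset that ``run_analysis`` consumes unchanged.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from rf3h import io_formats
from rf3h.io_formats import ExperimentManifest, ConditionSpec, MultiChannelImage
from rf3h.quantification import (
    CellMeasurement,
    ConditionGroup,
    QCRules,
    group_measurements,
    measure_cell,
    normalize_by_control,
    qc_filter,
)
from rf3h.segmentation import AnchorGeometry, segment_image
from rf3h.stats import TestResult, pairwise_vs_control, summarize_group
from rf3h.simulate import SimulationConfig, figure_presets, simulate_experiment


class PipelineConfigError(Exception):
    """Invalid run configuration (schema violation, bad control setup, ...)."""


class ControlGroupError(Exception):
    """The control group cannot support normalization (missing or too few cells)."""


class ImageReadError(Exception):
    """An input image is missing or unreadable."""


class ConditionSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    image_paths: list[str]
    is_control: bool = False


class GeometrySchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "single_spot"
    spot_sigma_px: float = 3.5
    puncta_min: int = 10
    puncta_max: int = 40
    rim_band_px: int = 4
    detect_snr: float = 3.0

    def to_geometry(self) -> AnchorGeometry:
        return AnchorGeometry(**self.model_dump())


class SegmentationSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_area: float = 300.0
    max_area: float = 8000.0
    smooth_sigma: float = 2.0


class QCSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    denom_floor_frac: float = 0.05

    def to_rules(self, seg: SegmentationSchema) -> QCRules:
        return QCRules(
            denom_floor_frac=self.denom_floor_frac,
            min_nucleus_area_px=seg.min_area,
            max_nucleus_area_px=seg.max_area,
        )


class StatsSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    welch: bool = False


class AnalysisConfig(BaseModel):
    """Schema of the ``rf3h analyze`` run configuration."""

    model_config = ConfigDict(extra="forbid")
    conditions: list[ConditionSchema]
    geometry: GeometrySchema = Field(default_factory=GeometrySchema)
    segmentation: SegmentationSchema = Field(default_factory=SegmentationSchema)
    qc: QCSchema = Field(default_factory=QCSchema)
    stats: StatsSchema = Field(default_factory=StatsSchema)
    channel_roles: dict[str, int] = Field(
        default_factory=lambda: {"nuclear_stain": 0, "trap_green": 1, "poi_red": 2}
    )

    @model_validator(mode="after")
    def _check_conditions(self) -> "AnalysisConfig":
        labels = [c.label for c in self.conditions]
        if any(not lab for lab in labels):
            raise ValueError("condition labels must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        n_control = sum(c.is_control for c in self.conditions)
        if n_control != 1:
            raise ValueError(f"exactly one control condition required; found {n_control}")
        return self

    @property
    def control_label(self) -> str:
        return next(c.label for c in self.conditions if c.is_control)


def load_config(path: str | os.PathLike) -> AnalysisConfig:
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return AnalysisConfig.model_validate(doc)
    except (OSError, ValueError) as exc:
        raise PipelineConfigError(str(exc)) from exc


@dataclass
class AnalysisResult:
    """In-memory result of one analysis run."""

    records: list[CellMeasurement]
    rejected: list[CellMeasurement]
    groups_raw: list[ConditionGroup]
    groups: list[ConditionGroup]
    tests: list[TestResult]
    log_lines: list[str] = field(default_factory=list)

    def group(self, label: str) -> ConditionGroup:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)


def analyze_images(
    images_by_condition: dict[str, list[MultiChannelImage]],
    control_label: str,
    geometry: AnchorGeometry,
    min_area: float = 300.0,
    max_area: float = 8000.0,
    smooth_sigma: float = 2.0,
    qc_rules: QCRules | None = None,
    welch: bool = False,
) -> AnalysisResult:
    """Run segmentation, measurement, QC, normalization and statistics in memory.

    This is the library entry point the CLI wraps; it accepts images grouped by
    condition label and returns the full :class:`AnalysisResult`.
    """
    if control_label not in images_by_condition:
        raise ControlGroupError(f"control condition {control_label!r} has no images")
    qc_rules = qc_rules or QCRules(
        min_nucleus_area_px=min_area, max_nucleus_area_px=max_area
    )
    log: list[str] = []
    records: list[CellMeasurement] = []
    n_segmented = 0
    for label, images in images_by_condition.items():
        n_cond = 0
        for image in images:
            cells = segment_image(
                image, geometry, min_area=min_area, max_area=max_area,
                smooth_sigma=smooth_sigma,
            )
            n_cond += len(cells)
            for cell in cells:
                records.append(measure_cell(image, cell, condition=label))
        n_segmented += n_cond
        log.append(f"condition {label}: {len(images)} images, {n_cond} nuclei segmented")

    kept, rejected = qc_filter(records, qc_rules)
    assert len(kept) + len(rejected) == n_segmented, "cell accounting failed"
    reasons = pd.Series([m.qc_reason for m in rejected]).value_counts().to_dict()
    log.append(
        f"QC: {len(kept)} kept, {len(rejected)} rejected "
        f"(reasons: {reasons or 'none'}); kept+rejected = {n_segmented} segmented"
    )

    groups_raw = group_measurements(
        kept, control_label, labels=list(images_by_condition)
    )
    control = next(g for g in groups_raw if g.is_control)
    if control.n < 3:
        raise ControlGroupError(
            f"control group {control_label!r} has only {control.n} QC-passing cells"
        )
    try:
        groups = normalize_by_control(groups_raw, records=kept)
    except ValueError as exc:
        raise ControlGroupError(str(exc)) from exc
    for g in groups:
        if g.n == 0:
            log.append(f"group {g.label}: n=0 (no QC-passing cells)")
            continue
        s = summarize_group(g)
        log.append(
            f"group {g.label}: n={s['n']} mean={s['mean']:.6g} sd={s['sd']:.6g}"
        )
    testable = [g for g in groups if g.is_control or g.n >= 2]
    tests = pairwise_vs_control(testable, welch=welch)
    for t in tests:
        log.append(
            f"t-test {t.group_a} vs {t.group_b}: t={t.t_statistic:.4g} "
            f"df={t.degrees_of_freedom:g} p={t.p_value:.4g} {t.stars}"
        )
    return AnalysisResult(
        records=kept + rejected,
        rejected=rejected,
        groups_raw=groups_raw,
        groups=groups,
        tests=tests,
        log_lines=log,
    )


def _write_outputs(
    result: AnalysisResult, out_dir: str, config_echo: dict, plots: bool = False
) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "per_cell": os.path.join(out_dir, "per_cell.csv"),
        "group_summary": os.path.join(out_dir, "group_summary.csv"),
        "stats": os.path.join(out_dir, "stats.csv"),
        "log": os.path.join(out_dir, "run_log.txt"),
    }
    records = sorted(result.records, key=lambda m: (m.condition, m.source_id, m.cell_label))
    io_formats.write_measurements(records, paths["per_cell"])
    pd.DataFrame(
        [
            {
                "condition": g.label,
                "is_control": g.is_control,
                "n": g.n,
                "mean": g.mean,
                "sd": g.sd,
                "normalized_values": ";".join(f"{v:.12g}" for v in g.values),
            }
            for g in result.groups
        ]
    ).to_csv(paths["group_summary"], index=False, float_format="%.12g")
    pd.DataFrame(
        [
            {
                "group_a": t.group_a,
                "group_b": t.group_b,
                "t": t.t_statistic,
                "df": t.degrees_of_freedom,
                "p_value": t.p_value,
                "stars": t.stars,
            }
            for t in result.tests
        ]
    ).to_csv(paths["stats"], index=False, float_format="%.12g")
    with open(paths["log"], "w") as fh:
        fh.write("parameters:\n")
        fh.write(yaml.safe_dump(config_echo, sort_keys=False))
        fh.write("\n".join(result.log_lines) + "\n")
    if plots:
        paths["plot"] = os.path.join(out_dir, "groups.png")
        _scatter_plot(result, paths["plot"])
    return paths


def _scatter_plot(result: AnalysisResult, path: str) -> None:
    """Scatter of per-cell normalized values with mean +/- SD bars and stars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(result.groups) + 1.5, 4))
    rng = np.random.default_rng(0)  # cosmetic x-jitter only
    stars = {t.group_b: t.stars for t in result.tests}
    for i, g in enumerate(result.groups):
        x = i + rng.uniform(-0.12, 0.12, g.n)
        ax.plot(x, g.values, "o", ms=4, alpha=0.6)
        ax.errorbar([i], [g.mean], yerr=[g.sd] if g.n > 1 else None,
                    fmt="_", ms=24, color="k", capsize=6, lw=1.5)
        if g.label in stars:
            ax.text(i, max(g.values) * 1.05, stars[g.label], ha="center")
    ax.set_xticks(range(len(result.groups)))
    ax.set_xticklabels([g.label for g in result.groups], rotation=20)
    ax.set_ylabel("normalized relative fluorescence")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_analysis(
    config: AnalysisConfig | str | os.PathLike,
    out_dir: str,
    base_dir: str | None = None,
    plots: bool = False,
) -> dict[str, str]:
    """Execute the full analysis described by a run configuration.

    Relative image paths are resolved against ``base_dir`` (default: the config
    file's directory, or the current directory for an in-memory config).  Returns
    the artifact paths.  Idempotent: re-running on the same inputs writes
    byte-identical CSVs.
    """
    if not isinstance(config, AnalysisConfig):
        config_path = str(config)
        if base_dir is None:
            base_dir = os.path.dirname(os.path.abspath(config_path))
        config = load_config(config_path)
    base_dir = base_dir or "."

    images_by_condition: dict[str, list[MultiChannelImage]] = {}
    for cond in config.conditions:
        images = []
        for rel in cond.image_paths:
            path = rel if os.path.isabs(rel) else os.path.join(base_dir, rel)
            try:
                images.append(
                    io_formats.read_image(path, config.channel_roles, source_id=rel)
                )
            except (FileNotFoundError, ValueError) as exc:
                raise ImageReadError(f"cannot read {path}: {exc}") from exc
        images_by_condition[cond.label] = images

    result = analyze_images(
        images_by_condition,
        control_label=config.control_label,
        geometry=config.geometry.to_geometry(),
        min_area=config.segmentation.min_area,
        max_area=config.segmentation.max_area,
        smooth_sigma=config.segmentation.smooth_sigma,
        qc_rules=config.qc.to_rules(config.segmentation),
        welch=config.stats.welch,
    )
    return _write_outputs(result, out_dir, config.model_dump(), plots=plots)


def run_simulate(
    preset: str | SimulationConfig, seed: int | None, out_dir: str
) -> dict[str, str]:
    """Write a complete synthetic dataset (TIFFs + run.yaml + ground truth CSV).

    The emitted ``run.yaml`` is directly consumable by :func:`run_analysis`.
    """
    if isinstance(preset, SimulationConfig):
        config = preset if seed is None else dataclasses.replace(preset, seed=seed)
    else:
        config = figure_presets(preset, seed=seed if seed is not None else 0)
    experiment = simulate_experiment(config)

    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    conditions = []
    for cond in config.conditions:
        rel_paths = []
        for image in experiment.images_by_condition[cond.label]:
            rel = os.path.join("images", f"{image.source_id}.tif")
            io_formats.write_image(image, os.path.join(out_dir, rel))
            rel_paths.append(rel)
        conditions.append(
            ConditionSpec(label=cond.label, image_paths=rel_paths, is_control=cond.is_control)
        )

    run_config = {
        "conditions": [
            {"label": c.label, "image_paths": c.image_paths, "is_control": c.is_control}
            for c in conditions
        ],
        "geometry": config.geometry.to_dict(),
    }
    paths = {
        "run_config": os.path.join(out_dir, "run.yaml"),
        "manifest": os.path.join(out_dir, "manifest.yaml"),
        "ground_truth": os.path.join(out_dir, "ground_truth.csv"),
    }
    with open(paths["run_config"], "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=False)
    io_formats.save_manifest(
        ExperimentManifest(conditions=conditions, geometry=config.geometry.to_dict()),
        paths["manifest"],
    )
    pd.DataFrame(
        [
            {
                "condition": gt.condition,
                "source_id": gt.source_id,
                "cell_index": gt.cell_index,
                "center_row": gt.center[0],
                "center_col": gt.center[1],
                "nucleus_area_px": int(gt.nucleus_mask.sum()),
                "anchor_area_px": int(gt.anchor_mask.sum()),
                "red_diffuse": gt.red_diffuse,
                "gain": gt.gain,
                "green_anchor": gt.green_anchor,
                "green_nucleus": gt.green_nucleus,
                "red_anchor": gt.red_anchor,
                "red_nucleus": gt.red_nucleus,
                "expected_raw_ratio": gt.expected_raw_ratio,
            }
            for gt in experiment.ground_truth
        ]
    ).to_csv(paths["ground_truth"], index=False, float_format="%.12g")
    return paths


def analyze_simulated(
    config: SimulationConfig, welch: bool = False
) -> AnalysisResult:
    """Simulate an experiment and analyze it in memory (no files written)."""
    experiment = simulate_experiment(config)
    return analyze_images(
        experiment.images_by_condition,
        control_label=config.control_label,
        geometry=config.geometry,
        welch=welch,
    )
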