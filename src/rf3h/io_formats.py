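"""Image, manifest and measurement-table I/O.

Images are plain multi-page TIFFs, one page per channel, with the channel-role
mapping carried in the run configuration rather than in embedded metadata.  Pixel
coordinates are 0-based row-major; intensities are processed as floating point with
no automatic bit-depth rescaling (the enrichment statistic is offset- and
unit-tolerant by construction).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNEL_ROLES = ("nuclear_stain", "trap_green", "poi_red")

#: Fixed column order of the per-cell measurement CSV.
MEASUREMENT_COLUMNS = [
    "source_id",
    "cell_label",
    "condition",
    "green_anchor",
    "green_nucleus",
    "red_anchor",
    "red_nucleus",
    "nucleus_area_px",
    "anchor_area_px",
    "raw_ratio",
    "normalized_value",
    "qc_pass",
    "qc_reason",
]


@dataclass
class MultiChannelImage:
    """One field of view: a (C, H, W) stack plus channel-role metadata.

    Parameters
    ----------
    pixels
        Channel-first intensity stack, finite and non-negative.
    channel_roles
        Mapping from each role in :data:`CHANNEL_ROLES` to a channel index.
    pixel_size_um
        Optional physical pixel size in micrometres.
    source_id
        Identifier used to key per-cell measurements back to this image.
    """

    pixels: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be (C, H, W); got shape {self.pixels.shape}")
        if set(self.channel_roles) != set(CHANNEL_ROLES):
            raise ValueError(f"channel_roles must map exactly {CHANNEL_ROLES}")
        indices = [self.channel_roles[r] for r in CHANNEL_ROLES]
        if len(set(indices)) != len(indices):
            raise ValueError("channel roles must refer to distinct channel indices")
        n_channels = self.pixels.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_channels:
                raise ValueError(
                    f"role {role!r} refers to channel {idx} of a {n_channels}-channel image"
                )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[self.channel_roles[role]]

    @property
    def nuclear_stain(self) -> np.ndarray:
        return self.channel("nuclear_stain")

    @property
    def trap_green(self) -> np.ndarray:
        return self.channel("trap_green")

    @property
    def poi_red(self) -> np.ndarray:
        return self.channel("poi_red")


@dataclass
class ConditionSpec:
    """One experimental condition: a label and the images belonging to it."""

    label: str
    image_paths: list[str]
    is_control: bool = False


@dataclass
class ExperimentManifest:
    """Groups images into conditions; exactly one condition is the no-RNA control."""

    conditions: list[ConditionSpec]
    geometry: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if any(not lab for lab in labels):
            raise ValueError("condition labels must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        n_control = sum(c.is_control for c in self.conditions)
        if n_control != 1:
            raise ValueError(f"exactly one control condition required; found {n_control}")

    @property
    def control_label(self) -> str:
        return next(c.label for c in self.conditions if c.is_control)


def read_image(
    path: str | os.PathLike,
    role_map: dict[str, int],
    pixel_size_um: float | None = None,
    source_id: str | None = None,
) -> MultiChannelImage:
    """Read a multi-page TIFF as a :class:`MultiChannelImage`.

    Intensities are cast to float64 without rescaling.  ``role_map`` indices must lie
    within the file's channel count and the file must have at least 3 channels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    stack = np.asarray(tifffile.imread(path))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < 3:
        raise ValueError(f"{path}: expected >= 3 channels, found {stack.shape[0]}")
    for role, idx in role_map.items():
        if not 0 <= idx < stack.shape[0]:
            raise ValueError(
                f"{path}: role {role!r} refers to channel {idx} of {stack.shape[0]}"
            )
    return MultiChannelImage(
        pixels=stack.astype(np.float64, copy=False),
        channel_roles=dict(role_map),
        pixel_size_um=pixel_size_um,
        source_id=source_id if source_id is not None else os.path.basename(str(path)),
    )


def write_image(image: MultiChannelImage, path: str | os.PathLike) -> None:
    """Write the channel stack as a multi-page TIFF, one page per channel."""
    tifffile.imwrite(path, np.asarray(image.pixels), photometric="minisblack")


def write_measurements(records: Sequence, path: str | os.PathLike) -> None:
    """Write per-cell measurements to CSV with the fixed :data:`MEASUREMENT_COLUMNS`."""
    rows = [
        {
            "source_id": m.source_id,
            "cell_label": m.cell_label,
            "condition": m.condition,
            "green_anchor": m.green_anchor,
            "green_nucleus": m.green_nucleus,
            "red_anchor": m.red_anchor,
            "red_nucleus": m.red_nucleus,
            "nucleus_area_px": m.nucleus_area_px,
            "anchor_area_px": m.anchor_area_px,
            "raw_ratio": m.raw_ratio,
            "normalized_value": m.normalized_value,
            "qc_pass": m.qc_pass,
            "qc_reason": m.qc_reason,
        }
        for m in records
    ]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.15g")


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def save_manifest(manifest: ExperimentManifest, path: str | os.PathLike) -> None:
    doc = {
        "conditions": [
            {"label": c.label, "image_paths": list(c.image_paths), "is_control": c.is_control}
            for c in manifest.conditions
        ],
        "geometry": manifest.geometry,
        "parameters": manifest.parameters,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_manifest(path: str | os.PathLike) -> ExperimentManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    conditions = [
        ConditionSpec(
            label=c["label"],
            image_paths=list(c["image_paths"]),
            is_control=bool(c.get("is_control", False)),
        )
        for c in doc.get("conditions", [])
    ]
    return ExperimentManifest(
        conditions=conditions,
        geometry=doc.get("geometry", {}) or {},
        parameters=doc.get("parameters", {}) or {},
    )
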