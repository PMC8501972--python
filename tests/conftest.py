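"""Shared fixtures: small, fast simulation configs and ground-truth matching."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from rf3h.simulate import SimCondition, SimulationConfig
from rf3h.segmentation import AnchorGeometry


def small_spot_config(seed: int = 0, fold: float = 2.0, n_cells: int = 8) -> SimulationConfig:
    """A two-condition single-spot experiment small enough for unit tests."""
    return SimulationConfig(
        conditions=[
            SimCondition("control", n_cells, 1.0, is_control=True),
            SimCondition("specific", n_cells, fold),
        ],
        geometry=AnchorGeometry(kind="single_spot", spot_sigma_px=3.5),
        seed=seed,
    )


@pytest.fixture
def spot_config() -> SimulationConfig:
    return small_spot_config()


def match_cells_to_truth(cells, ground_truth, source_id):
    """Pair segmented cells with simulator ground truth by nucleus-center containment."""
    gts = [gt for gt in ground_truth if gt.source_id == source_id]
    pairs = []
    for cell in cells:
        com = ndi.center_of_mass(cell.nucleus_mask)
        match = None
        for gt in gts:
            if gt.nucleus_mask[int(com[0]), int(com[1])]:
                match = gt
                break
        assert match is not None, f"no ground-truth nucleus contains {com}"
        pairs.append((cell, match))
    return pairs


def iou(a: np.ndarray, b: np.ndarray) -> float:
    return float((a & b).sum() / (a | b).sum())
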