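"""Shared fixtures: canonical ROIs and single-scene pipeline helpers.

Synthetic scenes reserve a label-free 64x64 patch in the top-left corner;
the background ROI used for threshold statistics sits inside it, matching
the workflow rule that threshold ROIs come from non-labeled regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import tracequant as tq

#: rectangle (x0, y0, x1, y1) kept free of label in synthetic scenes
PATCH = (0, 0, 64, 64)


@pytest.fixture
def bg_roi() -> tq.RoiSpec:
    return tq.RoiSpec("bg", "ipsi", ((4, 4), (58, 4), (58, 58), (4, 58)), "background")


@pytest.fixture
def full_roi() -> tq.RoiSpec:
    return tq.RoiSpec("all", "ipsi", ((0, 0), (255, 0), (255, 255), (0, 255)), "measurement")


def make_separated_retro_scene(seed: int, n_cells: int, radius: float = 3.5,
                               peak: float = 150.0) -> tuple[tq.Micrograph, tuple]:
    """One retrograde scene with blobs separated by > 4.5 radii."""
    rng = np.random.default_rng(seed)
    cells = tq.random_cell_truth(
        n_cells, (256, 256), radius=radius, peak=peak,
        min_separation=4.5 * radius, rng=rng, exclude=PATCH,
    )
    scene = tq.SyntheticScene(
        cells=cells, seed=seed, artifact_count=3, noise_sd=3.0,
        background_gradient=(0.05, 0.03), clear_patch=PATCH,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tq.make_retrograde_scene(scene)


def retro_binarize(m: tq.Micrograph, bg: tq.RoiSpec) -> tuple[tq.BinaryMask, tq.Micrograph]:
    """Retrograde preparation: subtract(20) -> smooth(3.5); threshold stats
    from the pre-smoothing image."""
    sub = tq.subtract_background(m, 20.0)
    sm = tq.smooth(sub, 3.5)
    ts = tq.threshold_stats(sub, bg)
    return tq.binarize(sm, ts), sm


def antero_binarize(m: tq.Micrograph, bg: tq.RoiSpec) -> tq.BinaryMask:
    """Anterograde preparation: subtract(20), no smoothing."""
    sub = tq.subtract_background(m, 20.0)
    ts = tq.threshold_stats(sub, bg)
    return tq.binarize(sub, ts)
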