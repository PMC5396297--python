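"""Seeded synthetic micrographs and cohort tables with known ground truth.

Real tract-tracing photomicrographs are rarely shareable, so every stage of
the pipeline is validated on synthetic images whose truth is known by
construction:

* **retrograde scenes** — compact, radially decaying blobs (fluorogold-style
  labeled somata) on a smooth background gradient with additive noise and a
  few small bright specks standing in for debris/artifacts;
* **anterograde scenes** — curvilinear bright strokes (BDA-style fibers)
  whose on-pixel fraction is driven to a target value, with the exact truth
  mask returned;
* **cohort count tables** — per-animal, per-area labeled-cell counts drawn
  around specified area proportions, with an effect structure that biases
  chosen areas toward one injection group.

All generators are deterministic given their seed.  Rasters are 8-bit-style
(0-255); blobs are isotropic 2-D Gaussians truncated at 3 radii so that a
scene's blobs are analytically countable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imgproc import LUMINANCE_MAX, BinaryMask, Micrograph, save_micrograph

__all__ = [
    "SyntheticScene",
    "SyntheticCohort",
    "CellTruth",
    "make_retrograde_scene",
    "make_anterograde_scene",
    "make_cohort_counts",
    "random_cell_truth",
    "write_scene",
]

#: default cohort sizes: five medial-SC and four lateral-SC injections
DEFAULT_N1 = 5
DEFAULT_N2 = 4


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one synthetic labeled soma."""

    x: float
    y: float
    radius: float
    peak: float  # peak intensity above background, luminance units


@dataclass
class SyntheticScene:
    """Parameters of one synthetic micrograph.

    ``background`` is (base level, (gx, gy)) — a plane ``base + gx*x + gy*y``
    in luminance units.  ``fiber_truth`` is the target on-pixel fraction for
    anterograde scenes and ignored for retrograde ones.
    """

    width: int = 256
    height: int = 256
    mode: str = "retrograde"  # "retrograde" | "anterograde"
    cells: tuple[CellTruth, ...] = ()
    fiber_truth: float = 0.0
    background_base: float = 20.0
    background_gradient: tuple[float, float] = (0.0, 0.0)
    texture_sd: float = 11.0  # tissue-mottle amplitude, luminance units
    texture_scale: float = 2.0  # mottle correlation length, pixels
    noise_sd: float = 3.0
    artifact_count: int = 0
    seed: int = 0
    fiber_tolerance: float = 0.02
    fiber_intensity: float = 200.0
    clear_patch: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1) kept label-free

    def __post_init__(self) -> None:
        if self.mode not in ("retrograde", "anterograde"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.fiber_truth <= 1.0:
            raise ValueError("fiber_truth must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.texture_sd < 0 or self.texture_scale <= 0:
            raise ValueError("texture_sd must be >= 0 and texture_scale > 0")
        for c in self.cells:
            if c.radius <= 0:
                raise ValueError("cell radii must be > 0")
            if not (0 <= c.x < self.width and 0 <= c.y < self.height):
                raise ValueError(f"cell centroid ({c.x}, {c.y}) outside raster")


@dataclass
class SyntheticCohort:
    """Per-animal, per-area expected label proportions for two injection groups.

    ``proportions`` maps area name -> baseline proportion (renormalized to
    sum to 1).  ``effect`` maps area name -> signed strength in [-1, 1]:
    positive values shift that area's share toward group 1, negative toward
    group 2, with the complement redistributed over the other areas.  An
    effect of magnitude 1 is a full group preference (the disfavored group
    gets no share of that area).  ``dispersion`` is the s.d. of the
    log-normal jitter applied to each animal's proportions before counts
    are realized; 0 means every animal matches its group profile exactly.
    """

    proportions: dict[str, float]
    n1: int = DEFAULT_N1
    n2: int = DEFAULT_N2
    effect: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.0
    cells_per_animal: int = 1000
    group_labels: tuple[str, str] = ("SCm", "SCl")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not self.proportions:
            raise ValueError("cohort needs at least one area")
        total = sum(self.proportions.values())
        if total <= 0:
            raise ValueError("area proportions must sum to a positive value")
        self.proportions = {a: p / total for a, p in self.proportions.items()}
        for a, e in self.effect.items():
            if a not in self.proportions:
                raise ValueError(f"effect names unknown area {a!r}")
            if not -1.0 <= e <= 1.0:
                raise ValueError("effect strengths must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

def _background_plane(scene: SyntheticScene, rng: np.random.Generator) -> np.ndarray:
    """Smooth gradient plus correlated tissue-mottle texture.

    The texture term emulates the structured autofluorescence background of
    real sections; it is what gives the mean-plus-variance threshold a
    non-trivial variance margin.
    """
    from scipy import ndimage as _ndi

    gx, gy = scene.background_gradient
    xs = np.arange(scene.width, dtype=float)
    ys = np.arange(scene.height, dtype=float)
    img = scene.background_base + gx * xs[None, :] + gy * ys[:, None]
    if scene.texture_sd > 0:
        tex = _ndi.gaussian_filter(
            rng.normal(0.0, 1.0, size=(scene.height, scene.width)), scene.texture_scale
        )
        sd = tex.std()
        if sd > 0:
            img = img + tex * (scene.texture_sd / sd)
    return img


def _patch_mask(scene: SyntheticScene) -> np.ndarray | None:
    if scene.clear_patch is None:
        return None
    x0, y0, x1, y1 = scene.clear_patch
    m = np.zeros((scene.height, scene.width), dtype=bool)
    m[y0:y1, x0:x1] = True
    return m


def _add_artifacts(img: np.ndarray, rng: np.random.Generator, count: int,
                   keep_clear: np.ndarray | None = None) -> None:
    """Small bright specks, 1-4 pixels, near-saturating."""
    h, w = img.shape
    for _ in range(count):
        while True:
            r = int(rng.integers(1, h - 1))
            c = int(rng.integers(1, w - 1))
            if keep_clear is None or not keep_clear[r, c]:
                break
        img[r, c] = LUMINANCE_MAX
        for _ in range(int(rng.integers(0, 3))):
            dr, dc = rng.integers(-1, 2, size=2)
            rr, cc = int(np.clip(r + dr, 0, h - 1)), int(np.clip(c + dc, 0, w - 1))
            if keep_clear is None or not keep_clear[rr, cc]:
                img[rr, cc] = LUMINANCE_MAX


def make_retrograde_scene(scene: SyntheticScene) -> tuple[Micrograph, list[CellTruth]]:
    """Render a retrograde scene: Gaussian blobs on a noisy gradient.

    Each truth cell contributes ``peak * exp(-d^2 / (2 radius^2))`` within
    3 radii of its centroid.  If more than 20% of cell pairs are closer
    than 4 radii apart a warning is recorded (counting validation assumes
    separable blobs).  Returns the rendered micrograph and the ground-truth
    cell list.
    """
    if scene.mode != "retrograde":
        raise ValueError("scene.mode must be 'retrograde'")
    rng = np.random.default_rng(scene.seed)
    img = _background_plane(scene, rng)
    patch = _patch_mask(scene)

    cells = list(scene.cells)
    if len(cells) > 1:
        close = 0
        pairs = 0
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                pairs += 1
                d = np.hypot(cells[i].x - cells[j].x, cells[i].y - cells[j].y)
                if d < 4.0 * max(cells[i].radius, cells[j].radius):
                    close += 1
        if pairs and close / pairs > 0.2:
            warnings.warn(
                f"{close}/{pairs} blob pairs closer than 4 radii; counts may merge",
                stacklevel=2,
            )

    for c in cells:
        trunc = 3.0 * c.radius
        c0 = max(int(np.floor(c.x - trunc)), 0)
        c1 = min(int(np.ceil(c.x + trunc)), scene.width - 1)
        r0 = max(int(np.floor(c.y - trunc)), 0)
        r1 = min(int(np.ceil(c.y + trunc)), scene.height - 1)
        xs = np.arange(c0, c1 + 1, dtype=float)
        ys = np.arange(r0, r1 + 1, dtype=float)
        d2 = (xs[None, :] - c.x) ** 2 + (ys[:, None] - c.y) ** 2
        blob = c.peak * np.exp(-d2 / (2.0 * c.radius**2))
        blob[d2 > trunc**2] = 0.0
        img[r0 : r1 + 1, c0 : c1 + 1] += blob

    _add_artifacts(img, rng, scene.artifact_count, keep_clear=patch)
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, LUMINANCE_MAX)
    return Micrograph(img, provenance=f"synthetic retrograde seed={scene.seed}"), cells


def make_anterograde_scene(scene: SyntheticScene) -> tuple[Micrograph, BinaryMask]:
    """Render an anterograde scene: dilated random-walk fiber strokes.

    Strokes are accumulated until the on-pixel fraction reaches
    ``fiber_truth``; single strokes are short enough that the overshoot
    stays within ``fiber_tolerance``.  Returns the micrograph and the
    ground-truth fiber mask.
    """
    if scene.mode != "anterograde":
        raise ValueError("scene.mode must be 'anterograde'")
    if scene.fiber_truth > 0.9:
        raise ValueError("fiber_truth > 0.9 is an unrealistic saturation level")
    rng = np.random.default_rng(scene.seed)
    h, w = scene.height, scene.width
    fiber = np.zeros((h, w), dtype=bool)
    patch = _patch_mask(scene)
    target_px = scene.fiber_truth * h * w

    from scipy import ndimage as _ndi

    # one stroke covers at most ~0.4% of a 256x256 frame, keeping the
    # realized fraction within tolerance of the target
    max_steps = max(16, int(0.0015 * h * w))
    while fiber.sum() < target_px:
        stroke = np.zeros((h, w), dtype=bool)
        r = float(rng.uniform(0, h))
        c = float(rng.uniform(0, w))
        heading = float(rng.uniform(0, 2 * np.pi))
        steps = int(rng.integers(max_steps // 2, max_steps + 1))
        for _ in range(steps):
            stroke[int(np.clip(r, 0, h - 1)), int(np.clip(c, 0, w - 1))] = True
            heading += float(rng.normal(0.0, 0.35))
            r += np.sin(heading)
            c += np.cos(heading)
        width_px = int(rng.integers(1, 4))  # dilate to 1-3 px line width
        if width_px > 1:
            stroke = _ndi.binary_dilation(stroke, iterations=width_px - 1)
        if patch is not None:
            stroke &= ~patch
        fiber |= stroke

    img = _background_plane(scene, rng)
    img[fiber] = scene.fiber_intensity
    _add_artifacts(img, rng, scene.artifact_count, keep_clear=patch)
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, LUMINANCE_MAX)
    m = Micrograph(img, provenance=f"synthetic anterograde seed={scene.seed}")
    return m, BinaryMask(mask=fiber, threshold_used=float("nan"))


def random_cell_truth(
    n: int,
    shape: tuple[int, int],
    radius: float,
    peak: float,
    min_separation: float,
    rng: np.random.Generator,
    margin: float | None = None,
    exclude: tuple[float, float, float, float] | None = None,
    region: tuple[float, float, float, float] | None = None,
    max_tries: int = 20000,
) -> tuple[CellTruth, ...]:
    """Rejection-sample ``n`` cell centroids at least ``min_separation`` apart.

    ``exclude`` is an optional (x0, y0, x1, y1) rectangle (plus a 3-radius
    halo) kept cell-free, e.g. the patch reserved for the background ROI;
    ``region`` restricts placement to a rectangle (e.g. one anatomical ROI).
    """
    h, w = shape
    if margin is None:
        margin = 3.0 * radius
    x_lo, y_lo, x_hi, y_hi = margin, margin, w - margin, h - margin
    if region is not None:
        x_lo = max(x_lo, region[0] + margin)
        y_lo = max(y_lo, region[1] + margin)
        x_hi = min(x_hi, region[2] - margin)
        y_hi = min(y_hi, region[3] - margin)
    if x_hi <= x_lo or y_hi <= y_lo:
        raise ValueError("placement region is empty after margins")
    pts: list[tuple[float, float]] = []
    tries = 0
    halo = 3.0 * radius
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n} cells with separation {min_separation}")
        x = float(rng.uniform(x_lo, x_hi))
        y = float(rng.uniform(y_lo, y_hi))
        if exclude is not None:
            x0, y0, x1, y1 = exclude
            if x0 - halo <= x <= x1 + halo and y0 - halo <= y <= y1 + halo:
                continue
        if all(np.hypot(x - px, y - py) > min_separation for px, py in pts):
            pts.append((x, y))
    return tuple(CellTruth(x=x, y=y, radius=radius, peak=peak) for x, y in pts)


def write_scene(m: Micrograph, truth: object, path: str | Path) -> None:
    """Write the scene as an 8-bit TIFF plus a JSON ground-truth sidecar."""
    path = Path(path)
    save_micrograph(m, path)
    if isinstance(truth, BinaryMask):
        payload = {"kind": "fiber_mask", "fraction": float(truth.mask.mean()),
                   "on_pixels": [[int(r), int(c)] for r, c in np.argwhere(truth.mask)]}
    else:
        payload = {"kind": "cells",
                   "cells": [{"x": c.x, "y": c.y, "radius": c.radius, "peak": c.peak} for c in truth]}
    path.with_suffix(".truth.json").write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def _group_profile(cohort: SyntheticCohort, group_index: int) -> dict[str, float]:
    """Area proportions for one injection group after applying the effect.

    For an effect e > 0 on area a, group 1 receives share p*(1+e) and group 2
    p*(1-e) (before renormalization); magnitude 1 therefore removes the area
    entirely from the disfavored group, guaranteeing complete modulation-
    index separation between the groups for that area against any unbiased
    complement.
    """
    sign = 1.0 if group_index == 1 else -1.0
    raw = {a: p * (1.0 + sign * cohort.effect.get(a, 0.0)) for a, p in cohort.proportions.items()}
    total = sum(raw.values())
    return {a: v / total for a, v in raw.items()}


def _integer_counts(props: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder rounding so per-animal counts sum exactly to total."""
    areas = list(props)
    exact = np.array([props[a] * total for a in areas])
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = total - int(base.sum())
    for i in np.argsort(-rem)[:short]:
        base[i] += 1
    return dict(zip(areas, (int(v) for v in base)))


def make_cohort_counts(cohort: SyntheticCohort) -> pd.DataFrame:
    """Realize per-animal integer labeled-cell counts for both groups.

    Returns a tidy frame with columns ``animal_id``, ``group``, ``area``,
    ``hemisphere`` and ``count``.  With ``dispersion`` 0, every animal of a
    group realizes that group's profile exactly.
    """
    rng = np.random.default_rng(cohort.seed)
    rows: list[dict] = []
    g1, g2 = cohort.group_labels
    for group_index, (label, n) in enumerate(((g1, cohort.n1), (g2, cohort.n2)), start=1):
        profile = _group_profile(cohort, group_index)
        for k in range(n):
            props = dict(profile)
            if cohort.dispersion > 0:
                jitter = {a: p * float(rng.lognormal(0.0, cohort.dispersion)) for a, p in props.items()}
                total = sum(jitter.values())
                props = {a: v / total for a, v in jitter.items()}
            counts = _integer_counts(props, cohort.cells_per_animal)
            animal = f"{label.lower()}_{k + 1:02d}"
            for area, cnt in counts.items():
                rows.append(
                    {"animal_id": animal, "group": label, "area": area,
                     "hemisphere": "ipsi", "count": cnt}
                )
    return pd.DataFrame(rows)
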