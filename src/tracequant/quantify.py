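"""Cell counts, percent area, percent-of-total and five-level categorization.

Retrograde data are quantified as labeled-cell counts per anatomical ROI,
normalized per animal to the percentage of all labeled cells in that animal
(percent-of-total), averaged across the cohort, and summarized on the
five-symbol ordinal scale "-", "+", "++", "+++", "++++".  Anterograde data
are quantified as the percentage of ROI area carrying fiber signal, with a
quantitative surrogate of the visual five-level score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .imgproc import BinaryMask, Micrograph, RoiSpec, roi_pixel_mask

__all__ = [
    "LEVELS",
    "CellDetection",
    "AreaQuantification",
    "count_cells",
    "percent_area",
    "percent_of_total",
    "categorize",
    "anterograde_level",
    "cohort_levels",
]

#: the five connectivity-strength symbols, weakest to strongest
LEVELS = ("-", "+", "++", "+++", "++++")

#: percent-of-total breakpoints for the retrograde categorization
CATEGORY_BREAKS = (2.5, 5.0, 7.5)

#: default cell-size filters at the synthetic image scale, in pixels
DEFAULT_MIN_CELL_AREA = 10
DEFAULT_MAX_CELL_AREA = 400


@dataclass(frozen=True)
class CellDetection:
    """One detected labeled soma."""

    centroid: tuple[float, float]  # (x, y) pixel coordinates
    area: int  # pixels
    mean_intensity: float  # luminance units; NaN when no intensity image given
    roi_name: str
    hemisphere: str


@dataclass(frozen=True)
class AreaQuantification:
    """One animal's measurement for one anatomical area."""

    animal_id: str
    area: str
    hemisphere: str
    measure_kind: str  # "cell_count" | "percent_area"
    raw_value: float
    percent_of_total: float | None = None  # retrograde only
    level: str | None = None  # cohort-level symbol, filled after aggregation


# ---------------------------------------------------------------------------
# Detection and area measures
# ---------------------------------------------------------------------------

def _split_component(comp: np.ndarray, intensity: np.ndarray | None, min_distance: int) -> np.ndarray:
    """Watershed-split one component into somata seeded at local maxima.

    Peaks are sought in the intensity image when available (labeled somata
    are intensity peaks), otherwise in the distance transform.  Secondary
    peaks below half the component's maximum are treated as texture ripple,
    not somata.  Returns an integer label image over the component raster.
    """
    if intensity is not None:
        relief = np.where(comp, intensity, 0.0)
    else:
        relief = ndimage.distance_transform_edt(comp)
    peaks = peak_local_max(
        relief, min_distance=min_distance, threshold_rel=0.5,
        labels=comp, exclude_border=False,
    )
    if len(peaks) <= 1:
        return comp.astype(int)
    markers = np.zeros(comp.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    return watershed(-relief, markers=markers, mask=comp)


def count_cells(
    mask: BinaryMask,
    roi: RoiSpec,
    min_area: int = DEFAULT_MIN_CELL_AREA,
    max_area: int = DEFAULT_MAX_CELL_AREA,
    image: Micrograph | None = None,
    split_min_distance: int = 7,
) -> list[CellDetection]:
    """Detect labeled somata inside one anatomical ROI.

    Foreground components are 8-connected.  A component counts toward this
    ROI when the majority (> 1/2) of its pixels lie inside the polygon, so
    a soma straddling a border is attributed to exactly one area.  Every
    component with more than one strong local maximum is split by
    local-maximum-seeded watershed (touching somata joined by dim bridges
    need not exceed ``max_area`` to be split); pieces outside
    [min_area, max_area] are rejected as debris or unresolvable clumps.
    """
    if min_area > max_area:
        raise ValueError(f"min_area {min_area} > max_area {max_area}")
    roi_mask = roi_pixel_mask(roi, mask.shape)
    lab, n = ndimage.label(mask.mask, structure=np.ones((3, 3), dtype=int))
    intensity = image.raster if image is not None else None

    detections: list[CellDetection] = []
    slices = ndimage.find_objects(lab)
    for i in range(1, n + 1):
        sl = slices[i - 1]
        comp = lab[sl] == i
        comp_area = int(comp.sum())
        if comp_area < min_area:
            continue
        pieces = _split_component(
            comp, intensity[sl] if intensity is not None else None, split_min_distance
        )
        piece_ids = [p for p in np.unique(pieces) if p != 0]
        for pid in piece_ids:
            piece_local = pieces == pid
            piece = np.zeros(mask.shape, dtype=bool)
            piece[sl] = piece_local
            area = int(piece_local.sum())
            if not (min_area <= area <= max_area):
                continue
            inside = int((piece & roi_mask).sum())
            if inside * 2 <= area:  # strict majority rule
                continue
            rr, cc = np.nonzero(piece)
            mean_int = float(intensity[piece].mean()) if intensity is not None else float("nan")
            detections.append(
                CellDetection(
                    centroid=(float(cc.mean()), float(rr.mean())),
                    area=area,
                    mean_intensity=mean_int,
                    roi_name=roi.name,
                    hemisphere=roi.hemisphere,
                )
            )
    return detections


def percent_area(mask: BinaryMask, roi: RoiSpec) -> float:
    """Percentage of ROI pixels carrying foreground (fiber) signal."""
    roi_mask = roi_pixel_mask(roi, mask.shape)
    total = int(roi_mask.sum())
    if total == 0:
        raise ValueError(f"ROI {roi.name!r} covers no pixels")
    return 100.0 * int((mask.mask & roi_mask).sum()) / total


# ---------------------------------------------------------------------------
# Normalization and categorization
# ---------------------------------------------------------------------------

def percent_of_total(counts: dict[str, float]) -> dict[str, float]:
    """Each area's share of all labeled cells in one animal, in percent.

    Both hemispheres' areas enter the denominator (they are distinct keys).
    An animal with no labeled cells cannot be normalized and raises.
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("animal has no labeled cells; excluded from percent-of-total")
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative counts")
    return {a: 100.0 * v / total for a, v in counts.items()}


def categorize(mean_percent: float) -> str:
    """Map a cohort-mean percent-of-total to the five-symbol scale.

    "-" iff exactly 0; "+" on (0, 2.5); "++" on [2.5, 5); "+++" on
    [5, 7.5]; "++++" above 7.5.
    """
    if not 0.0 <= mean_percent <= 100.0:
        raise ValueError(f"percentage out of range: {mean_percent}")
    if mean_percent == 0.0:
        return "-"
    if mean_percent < 2.5:
        return "+"
    if mean_percent < 5.0:
        return "++"
    if mean_percent <= 7.5:
        return "+++"
    return "++++"


def anterograde_level(pct: float, breaks: tuple[float, float, float, float] = (0.0, 2.5, 5.0, 7.5)) -> str:
    """Quantitative five-level surrogate for the visual fiber-density score.

    ``breaks`` are four ascending cut points (b0..b3) on the percent-area
    scale: values <= b0 map to "-", then half-open bins [b0,b1) -> "+",
    [b1,b2) -> "++", [b2,b3] -> "+++", above b3 -> "++++".  The default
    reuses the retrograde breakpoints with b0 = 0.
    """
    if list(breaks) != sorted(breaks) or len(set(breaks)) != 4:
        raise ValueError("breaks must be 4 strictly ascending cut points")
    if not (0.0 <= breaks[0] and breaks[3] <= 100.0):
        raise ValueError("breaks must lie within [0, 100]")
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage out of range: {pct}")
    b0, b1, b2, b3 = breaks
    if pct <= b0:
        return "-"
    if pct < b1:
        return "+"
    if pct < b2:
        return "++"
    if pct <= b3:
        return "+++"
    return "++++"


def cohort_levels(df: pd.DataFrame, measure_kind: str = "cell_count") -> pd.DataFrame:
    """Aggregate a tidy per-animal table into cohort-mean levels per area.

    ``df`` needs columns ``animal_id``, ``group``, ``area``, ``hemisphere``
    and ``count`` (retrograde) or ``percent`` (anterograde).  Retrograde
    counts are normalized to percent-of-total per animal; the level symbol
    is assigned to the across-animal mean percentage within each injection
    group, as in a cohort summary table.
    """
    df = df.copy()
    if measure_kind == "cell_count":
        parts = []
        for (animal, _group), sub in df.groupby(["animal_id", "group"]):
            key = sub["area"] + "|" + sub["hemisphere"]
            pct = percent_of_total(dict(zip(key, sub["count"].astype(float))))
            sub = sub.assign(percent=[pct[k] for k in key])
            parts.append(sub)
        df = pd.concat(parts, ignore_index=True)
    elif measure_kind != "percent_area":
        raise ValueError(f"unknown measure kind {measure_kind!r}")
    out = (
        df.groupby(["group", "area", "hemisphere"], as_index=False)["percent"]
        .mean()
        .rename(columns={"percent": "mean_percent"})
    )
    level_fn = categorize if measure_kind == "cell_count" else anterograde_level
    out["level"] = [level_fn(p) for p in out["mean_percent"]]
    return out
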