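"""Image preparation and luminance-statistics thresholding.

The quantification pipeline works on 8-bit-style grayscale micrographs
(luminance values on the 0-255 scale).  Preparation consists of grayscale
conversion, Gaussian-convoluted background subtraction, and optional
Gaussian smoothing.  Binarization uses an adaptive threshold computed from
a user-supplied *background* region of interest (a patch with no labeled
cells or fibers):

    L_thresh = L_mean(ROI) + L_var(ROI)

where ``L_mean`` is the mean luminance over the ROI and ``L_var`` its
population variance.  The formula is scale-dependent; every raster in this
package is therefore defined on the fixed 0-255 integer luminance scale
(16-bit input is rescaled on load).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path as _FsPath
from typing import Sequence

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage
from skimage import measure

__all__ = [
    "LUMINANCE_MAX",
    "Micrograph",
    "RoiSpec",
    "ThresholdStats",
    "BinaryMask",
    "Contour",
    "load_micrograph",
    "save_micrograph",
    "load_rois",
    "to_grayscale",
    "subtract_background",
    "smooth",
    "roi_pixel_mask",
    "threshold_stats",
    "binarize",
    "extract_contours",
    "rasterize_contour",
]

#: Top of the luminance scale all thresholds are defined on.
LUMINANCE_MAX = 255.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Micrograph:
    """A single 2-D fluorescence raster with pixel metadata.

    ``raster`` is float64 internally but always holds values on the 0-255
    luminance scale.  Multichannel input keeps a trailing channel axis until
    :func:`to_grayscale` collapses it.
    """

    raster: np.ndarray
    pixel_size: float | None = None  # microns per pixel, metadata only
    provenance: str = ""

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=np.float64)
        if self.raster.size == 0:
            raise ValueError("micrograph raster is empty")
        if self.raster.ndim not in (2, 3):
            raise ValueError(f"raster must be 2-D or 2-D+channels, got ndim={self.raster.ndim}")
        if self.raster.min() < 0 or self.raster.max() > LUMINANCE_MAX:
            raise ValueError("luminance values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape[:2]


@dataclass(frozen=True)
class RoiSpec:
    """A named polygon over one micrograph.

    Vertices are (x, y) pixel coordinates, x rightward, y downward, 0-based.
    ``purpose`` distinguishes anatomical measurement ROIs from the
    non-labeled background patches used for threshold statistics.
    """

    name: str
    hemisphere: str  # "ipsi" | "contra"
    polygon: tuple[tuple[float, float], ...]
    purpose: str = "measurement"  # "measurement" | "background"

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError(f"ROI {self.name!r}: polygon needs >= 3 vertices")
        if self.hemisphere not in ("ipsi", "contra"):
            raise ValueError(f"ROI {self.name!r}: hemisphere must be 'ipsi' or 'contra'")
        if self.purpose not in ("measurement", "background"):
            raise ValueError(f"ROI {self.name!r}: purpose must be 'measurement' or 'background'")
        object.__setattr__(self, "polygon", tuple((float(x), float(y)) for x, y in self.polygon))


@dataclass(frozen=True)
class ThresholdStats:
    """Mean, population variance and their sum over a background ROI."""

    l_mean: float
    l_var: float

    @property
    def l_thresh(self) -> float:
        return self.l_mean + self.l_var


@dataclass
class BinaryMask:
    """Boolean raster: True where processed luminance exceeded the threshold."""

    mask: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("binary mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class Contour:
    """An ordered boundary polyline in (x, y) pixel coordinates."""

    points: tuple[tuple[float, float], ...]
    closed: bool
    enclosed_area: float  # pixels of the traced component


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_micrograph(path: str | _FsPath, pixel_size: float | None = None) -> Micrograph:
    """Read a TIFF or PNG micrograph; 16-bit data are rescaled to 0-255."""
    path = _FsPath(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (LUMINANCE_MAX / 65535.0)
    provenance = str(path)
    return Micrograph(arr.astype(np.float64), pixel_size=pixel_size, provenance=provenance)


def save_micrograph(m: Micrograph, path: str | _FsPath) -> None:
    """Write an 8-bit single-channel TIFF (or PNG by extension)."""
    path = _FsPath(path)
    data = np.clip(np.rint(m.raster), 0, LUMINANCE_MAX).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def load_rois(path: str | _FsPath) -> list[RoiSpec]:
    """Read ROI polygons from a JSON or YAML file.

    The file holds a list of records with keys ``name``, ``hemisphere``,
    ``polygon`` (list of [x, y] vertices) and optional ``purpose``.
    """
    import json

    import yaml

    path = _FsPath(path)
    text = path.read_text()
    records = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return [
        RoiSpec(
            name=r["name"],
            hemisphere=r.get("hemisphere", "ipsi"),
            polygon=tuple((float(x), float(y)) for x, y in r["polygon"]),
            purpose=r.get("purpose", "measurement"),
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# Preparation
# ---------------------------------------------------------------------------

def to_grayscale(m: Micrograph) -> Micrograph:
    """Collapse a 3-channel raster to luminance by the unweighted channel mean.

    Single-channel input is returned unchanged (identity).
    """
    if m.raster.ndim == 2:
        return m
    if m.raster.ndim == 3 and m.raster.shape[2] == 3:
        gray = m.raster.mean(axis=2)
        return Micrograph(gray, pixel_size=m.pixel_size, provenance=m.provenance)
    raise ValueError(f"unsupported channel count: shape {m.raster.shape}")


def subtract_background(m: Micrograph, sigma: float = 20.0) -> Micrograph:
    """Gaussian-convoluted background subtraction.

    Subtracts a wide Gaussian blur of the image from the image itself and
    clamps to the valid luminance range, removing smooth illumination and
    biological background while retaining compact label.  Reflective
    padding avoids dark rims at the frame edge.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if m.raster.ndim != 2:
        raise ValueError("subtract_background expects a grayscale raster")
    blur = ndimage.gaussian_filter(m.raster, sigma=sigma, mode="reflect")
    out = np.clip(m.raster - blur, 0.0, LUMINANCE_MAX)
    return Micrograph(out, pixel_size=m.pixel_size, provenance=m.provenance)


def smooth(m: Micrograph, sigma: float = 3.5) -> Micrograph:
    """Gaussian low-pass filtering to suppress acquisition/biological artifacts.

    Reflective boundary handling conserves total intensity to floating-point
    tolerance.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if m.raster.ndim != 2:
        raise ValueError("smooth expects a grayscale raster")
    out = ndimage.gaussian_filter(m.raster, sigma=sigma, mode="reflect")
    return Micrograph(np.clip(out, 0.0, LUMINANCE_MAX), pixel_size=m.pixel_size, provenance=m.provenance)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def roi_pixel_mask(roi: RoiSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of pixels whose centers fall inside the ROI polygon.

    Membership uses the pixel-center rule: pixel (row r, col c) belongs to
    the ROI iff the point (c, r) lies inside the polygon.  For the simple
    (non-self-intersecting) polygons this package accepts, the even-odd and
    winding fill rules coincide.
    """
    h, w = shape
    verts = np.asarray(roi.polygon, dtype=float)
    if verts[:, 0].min() < -0.5 or verts[:, 0].max() > w - 0.5 or verts[:, 1].min() < -0.5 or verts[:, 1].max() > h - 0.5:
        raise ValueError(f"ROI {roi.name!r} exceeds image bounds {shape}")
    # restrict the point-in-polygon test to the polygon's bounding box
    c0 = max(int(np.floor(verts[:, 0].min())), 0)
    c1 = min(int(np.ceil(verts[:, 0].max())), w - 1)
    r0 = max(int(np.floor(verts[:, 1].min())), 0)
    r1 = min(int(np.ceil(verts[:, 1].max())), h - 1)
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    # an open Path is implicitly closed by contains_points; closed=True would
    # consume the final vertex as the CLOSEPOLY marker
    inside = _MplPath(verts).contains_points(pts)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rr.shape)
    return mask


def threshold_stats(m: Micrograph, background: RoiSpec) -> ThresholdStats:
    """Luminance statistics over a non-labeled background ROI.

    Returns the mean, the population variance (divide by N) and their sum,
    the adaptive threshold ``L_thresh = L_mean + L_var``.
    """
    if background.purpose != "background":
        raise ValueError(f"ROI {background.name!r} is not a background ROI")
    if m.raster.ndim != 2:
        raise ValueError("threshold_stats expects a grayscale raster")
    pix = m.raster[roi_pixel_mask(background, m.shape)]
    if pix.size < 2:
        raise ValueError(f"background ROI {background.name!r} covers fewer than 2 pixels")
    mean = float(pix.mean())
    var = float(pix.var(ddof=0))
    return ThresholdStats(l_mean=mean, l_var=var)


def binarize(m: Micrograph, t: ThresholdStats) -> BinaryMask:
    """Strict greater-than thresholding of the processed raster.

    The strict comparison makes a flat image at its own threshold come out
    empty rather than all-foreground.
    """
    if m.raster.ndim != 2:
        raise ValueError("binarize expects a grayscale raster")
    return BinaryMask(mask=m.raster > t.l_thresh, threshold_used=t.l_thresh)


# ---------------------------------------------------------------------------
# Injection-site contours
# ---------------------------------------------------------------------------

def extract_contours(mask: BinaryMask, min_area: int = 5) -> list[Contour]:
    """Trace one closed contour per 8-connected foreground component.

    Components smaller than ``min_area`` pixels are treated as speckle and
    skipped.  Boundaries run at the half-pixel level (marching squares on
    the padded component mask) and contours are ordered by descending
    component area.
    """
    lab, n = ndimage.label(mask.mask, structure=np.ones((3, 3), dtype=int))
    out: list[tuple[float, Contour]] = []
    for i in range(1, n + 1):
        comp = lab == i
        area = int(comp.sum())
        if area < min_area:
            continue
        padded = np.pad(comp.astype(float), 1)
        traces = measure.find_contours(padded, level=0.5)
        if not traces:
            continue
        # the longest trace is the outer boundary; holes are ignored
        tr = max(traces, key=len)
        pts = tuple((float(c - 1.0), float(r - 1.0)) for r, c in tr)  # (row,col) -> (x,y), unpad
        closed = bool(np.allclose(tr[0], tr[-1]))
        out.append((area, Contour(points=pts, closed=closed, enclosed_area=float(area))))
    out.sort(key=lambda t: -t[0])
    return [c for _, c in out]


def rasterize_contour(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed contour back into a pixel mask (pixel-center rule)."""
    verts = np.asarray(contour.points, dtype=float)
    h, w = shape
    cc, rr = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([cc.ravel(), rr.ravel()]).astype(float)
    inside = _MplPath(verts).contains_points(pts)
    return inside.reshape(h, w)


def contours_to_json(contours: Sequence[Contour]) -> list[dict]:
    """JSON-serializable point lists for saving or SVG overlay."""
    return [
        {"closed": c.closed, "area": c.enclosed_area, "points": [[x, y] for x, y in c.points]}
        for c in contours
    ]
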