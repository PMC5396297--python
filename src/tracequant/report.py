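"""Pipeline orchestration: configuration, cohort runs, connectivity tables.

``run_pipeline`` composes the full analysis for one cohort: load each
micrograph, prepare it (grayscale, background subtraction, smoothing),
threshold it against its background ROI, quantify every measurement ROI
(cell counts for retrograde cohorts, percent area for anterograde ones),
normalize, categorize on the five-level scale, and test the configured
region-pair preferences between the two injection groups.  Every parameter
used is echoed to a machine-readable log so each output value is traceable
to (image, ROI, parameters).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import imgproc, quantify, stats

__all__ = [
    "PipelineConfig",
    "ConnectivityTable",
    "run_pipeline",
    "render_connectivity_map",
    "load_manifest",
]

logger = logging.getLogger("tracequant")


@dataclass
class PipelineConfig:
    """All tunable parameters of a cohort run.

    Defaults are the published workflow's parameters: background
    subtraction sigma 20 px, smoothing sigma 3.5 px, the five-level
    breakpoints at 2.5/5/7.5% and alpha 0.05.  Smoothing is applied to
    retrograde images only by default; blurring 1-3 px fibers before
    thresholding inflates their apparent area.
    """

    mode: str = "retrograde"  # "retrograde" | "anterograde"
    sigma_subtract: float = 20.0
    sigma_smooth: float = 3.5
    smooth_anterograde: bool = False
    min_cell_area: int = quantify.DEFAULT_MIN_CELL_AREA
    max_cell_area: int = quantify.DEFAULT_MAX_CELL_AREA
    anterograde_breaks: tuple[float, float, float, float] = (0.0, 2.5, 5.0, 7.5)
    alpha: float = stats.DEFAULT_ALPHA
    seed: int = 0
    comparisons: tuple[tuple[str, str], ...] = ()  # region pairs (area_a, area_b)
    injection_sites: tuple[str, ...] = ()  # areas reported as N/A
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("retrograde", "anterograde"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ConnectivityTable:
    """Area x injection-group matrix of five-level symbols.

    ``levels`` is tidy (group, area, hemisphere, mean_percent, level);
    ``matrix`` is the wide symbol table with injection-site rows marked
    "N/A".  ``mode`` records whether columns summarize afferents to the
    injection site (retrograde) or efferents from it (anterograde).
    """

    levels: pd.DataFrame
    matrix: pd.DataFrame
    mode: str
    injection_sites: tuple[str, ...] = ()


def load_manifest(path: str | Path) -> list[dict]:
    """Read a cohort manifest (YAML): one record per image.

    Each record: ``path``, ``roi_path``, ``animal_id``, ``group``
    (injection target), optional ``hemisphere_of_interest``.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    images = doc.get("images", doc if isinstance(doc, list) else [])
    return list(images or [])


def _prepare(
    m: imgproc.Micrograph, config: PipelineConfig
) -> tuple[imgproc.Micrograph, imgproc.Micrograph]:
    """Grayscale + background subtraction, then optional smoothing.

    Returns (stats_image, final_image): threshold statistics are taken on
    the subtracted-but-unsmoothed image, whose ROI variance still carries
    the pixel-noise term that gives L_mean + L_var its margin; the
    binarized image is the smoothed one (they coincide when smoothing is
    off).
    """
    m = imgproc.to_grayscale(m)
    subtracted = imgproc.subtract_background(m, sigma=config.sigma_subtract)
    if config.mode == "retrograde" or config.smooth_anterograde:
        final = imgproc.smooth(subtracted, sigma=config.sigma_smooth)
    else:
        final = subtracted
    return subtracted, final


def _quantify_image(
    m: imgproc.Micrograph,
    rois: Sequence[imgproc.RoiSpec],
    config: PipelineConfig,
    animal_id: str,
    group: str,
    image_name: str,
) -> list[dict]:
    background = [r for r in rois if r.purpose == "background"]
    if not background:
        raise ValueError(f"image {image_name!r}: no background ROI for thresholding")
    stats_img, prepared = _prepare(m, config)
    tstats = imgproc.threshold_stats(stats_img, background[0])
    mask = imgproc.binarize(prepared, tstats)
    logger.info(
        "image=%s animal=%s group=%s L_mean=%.3f L_var=%.3f L_thresh=%.3f",
        image_name, animal_id, group, tstats.l_mean, tstats.l_var, tstats.l_thresh,
    )
    rows = []
    for roi in rois:
        if roi.purpose != "measurement":
            continue
        if config.mode == "retrograde":
            dets = quantify.count_cells(
                mask, roi, min_area=config.min_cell_area,
                max_area=config.max_cell_area, image=prepared,
            )
            value, kind = float(len(dets)), "cell_count"
        else:
            value, kind = quantify.percent_area(mask, roi), "percent_area"
        rows.append(
            {"animal_id": animal_id, "group": group, "area": roi.name,
             "hemisphere": roi.hemisphere, "measure_kind": kind,
             "raw_value": value, "image": image_name,
             "l_thresh": tstats.l_thresh}
        )
    return rows


def quantify_cohort_table(measurements: pd.DataFrame, config: PipelineConfig) -> ConnectivityTable:
    """Aggregate tidy per-animal measurements into a connectivity table."""
    df = measurements.copy()
    if config.mode == "retrograde":
        df = df.rename(columns={"raw_value": "count"})
        levels = quantify.cohort_levels(df, measure_kind="cell_count")
    else:
        df = df.rename(columns={"raw_value": "percent"})
        levels = quantify.cohort_levels(df, measure_kind="percent_area")
    wide = levels.pivot_table(
        index=["area", "hemisphere"], columns="group", values="level", aggfunc="first"
    ).astype(object)
    for site in config.injection_sites:
        matched = [ix for ix in wide.index if ix[0] == site]
        for ix in matched:
            wide.loc[ix] = "N/A"
        if not matched:
            for g in wide.columns:
                wide.loc[(site, "ipsi"), g] = "N/A"
    wide = wide.fillna("-").sort_index()
    return ConnectivityTable(
        levels=levels, matrix=wide, mode=config.mode,
        injection_sites=tuple(config.injection_sites),
    )


def compare_region_pairs(
    measurements: pd.DataFrame, config: PipelineConfig
) -> list[stats.GroupComparison]:
    """Per-animal modulation indices for each configured region pair, tested
    between the two injection groups."""
    results = []
    groups = list(dict.fromkeys(measurements["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two injection groups, found {groups}")
    for area_a, area_b in config.comparisons:
        cases_by_group: dict[str, list[stats.ModulationInput]] = {g: [] for g in groups}
        for (animal, group), sub in measurements.groupby(["animal_id", "group"], sort=False):
            by_area = sub.groupby("area")["raw_value"].sum()
            if area_a not in by_area.index or area_b not in by_area.index:
                continue
            cases_by_group[group].append(
                stats.ModulationInput(
                    q_a=float(by_area[area_a]), q_b=float(by_area[area_b]),
                    case_id=animal, region_pair=f"{area_a} vs {area_b}",
                )
            )
        results.append(stats.compare_preference(cases_by_group, alpha=config.alpha))
    return results


def run_pipeline(
    config: PipelineConfig, manifest: Sequence[dict]
) -> tuple[ConnectivityTable, list[stats.GroupComparison], pd.DataFrame]:
    """Run the full cohort analysis over a manifest of images.

    Returns the connectivity table, the region-pair comparisons, and the
    tidy per-animal measurement frame.  Deterministic for a fixed config;
    outputs (CSV/JSON) are written when ``config.output_dir`` is set.
    """
    if not manifest:
        raise ValueError("empty manifest: nothing to analyze")
    rows: list[dict] = []
    for entry in manifest:
        image_name = str(entry.get("path", "<in-memory>"))
        micrograph = entry.get("micrograph")
        if micrograph is None:
            p = Path(entry["path"])
            if not p.exists():
                raise FileNotFoundError(f"image {image_name!r} not found")
            micrograph = imgproc.load_micrograph(p)
        rois = entry.get("rois")
        if rois is None:
            roi_path = entry.get("roi_path")
            if not roi_path or not Path(roi_path).exists():
                raise FileNotFoundError(f"image {image_name!r}: ROI file missing ({roi_path})")
            rois = imgproc.load_rois(roi_path)
        rows.extend(
            _quantify_image(micrograph, rois, config, str(entry["animal_id"]),
                            str(entry["group"]), image_name)
        )
    measurements = pd.DataFrame(rows)
    table = quantify_cohort_table(measurements, config)
    comparisons = compare_region_pairs(measurements, config) if config.comparisons else []

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        measurements.to_csv(out / "measurements.csv", index=False)
        table.levels.to_csv(out / "cohort_levels.csv", index=False)
        table.matrix.to_csv(out / "connectivity_table.csv")
        (out / "comparisons.json").write_text(
            json.dumps([c.to_dict() for c in comparisons], indent=2)
        )
        (out / "parameters.json").write_text(json.dumps(asdict(config), indent=2, default=str))
    return table, comparisons, measurements


_WEIGHT_CLASS = {"+": 1, "++": 2, "+++": 3, "++++": 4}


def render_connectivity_map(
    tables: Sequence[ConnectivityTable],
) -> dict:
    """Node-edge description of the connectivity graph for plotting.

    Each non-"-" table entry becomes an edge between the injection target
    and the area, weighted 1-4 by level ("-" entries are omitted, "N/A"
    rows skipped).  Retrograde tables contribute afferent edges
    (area -> target), anterograde tables efferent edges (target -> area).
    Areas carrying both an afferent entry and an efferent entry above "-"
    are flagged as shared nodes.
    """
    edges: list[dict] = []
    afferent_areas: set[str] = set()
    efferent_areas: set[str] = set()
    for table in tables:
        for (area, hemi), row in table.matrix.iterrows():
            for target, symbol in row.items():
                if symbol in ("-", "N/A") or pd.isna(symbol):
                    continue
                w = _WEIGHT_CLASS[symbol]
                if table.mode == "retrograde":
                    edges.append({"source": area, "target": target, "hemisphere": hemi,
                                  "weight_class": w, "kind": "afferent"})
                    afferent_areas.add(area)
                else:
                    edges.append({"source": target, "target": area, "hemisphere": hemi,
                                  "weight_class": w, "kind": "efferent"})
                    efferent_areas.add(area)
    shared = sorted(afferent_areas & efferent_areas)
    nodes = sorted({e["source"] for e in edges} | {e["target"] for e in edges})
    return {"nodes": nodes, "edges": edges, "shared_nodes": shared}
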