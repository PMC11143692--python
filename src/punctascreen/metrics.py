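"""Per-cell and per-sample reporter statistics.

Implements the readouts of a puncta-reporter assay: puncta count and the
">10 puncta per cell" positivity rule, percent-positive per sample, mean
fluorescence intensity (MFI) on background-subtracted images with
saturation exclusion, the per-punctum degree of clustering (Dc, punctum
intensity over nearby cytosol), and puncta-size distributions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import morphology

from .detect import DetectionParams, SegmentationResult, flag_saturated_cells
from .images import FluorImage

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsParams",
    "classify_positive",
    "percent_positive",
    "field_background",
    "compute_mfi",
    "degree_of_clustering",
    "puncta_size_distribution",
    "quantify_field",
    "summarize_sample",
]


@dataclass
class MetricsParams:
    """Knobs of the per-cell statistics.

    positivity_threshold: a cell is positive iff puncta_count is strictly
    greater than this (default 10).
    annulus_width: width (px) of the cytosol reference ring around a punctum
    for Dc.
    dc_core_fraction / dc_peak_percentile: the Dc numerator averages the
    punctum pixels above ``baseline + core_fraction * (peak - baseline)``
    with ``peak`` a robust percentile of the punctum pixels — the detected
    mask includes the dim skirt of a spot and a plain mean over it would
    understate the contrast.
    min_cells_warn: samples with fewer included cells get a QC warning.
    """

    positivity_threshold: int = 10
    annulus_width: int = 3
    dc_core_fraction: float = 0.85
    dc_peak_percentile: float = 95.0
    min_cells_warn: int = 50

    def validate(self) -> None:
        if self.positivity_threshold < 0:
            raise ValueError("positivity_threshold must be >= 0")
        if self.annulus_width < 1:
            raise ValueError("annulus_width must be >= 1")
        if not (0.0 <= self.dc_core_fraction <= 1.0):
            raise ValueError("dc_core_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsParams":
        return cls(**d)


def classify_positive(puncta_count: int, threshold: int = 10) -> bool:
    """Positive iff strictly more than ``threshold`` puncta in the cell."""
    if puncta_count < 0:
        raise ValueError("puncta_count must be >= 0")
    return puncta_count > threshold


def percent_positive(cells: pd.DataFrame | list) -> float:
    """100 · (#positive / #cells) over included cells.

    An empty cell table is undefined and returns NaN (reported as missing,
    never as 0).
    """
    if isinstance(cells, pd.DataFrame):
        flags = cells["positive"].to_numpy(dtype=bool)
    else:
        flags = np.asarray([bool(getattr(c, "positive", c)) for c in cells], dtype=bool)
    if flags.size == 0:
        logger.warning("percent_positive of an empty cell list is undefined")
        return float("nan")
    return 100.0 * float(flags.sum()) / float(flags.size)


def field_background(image: FluorImage, cell_label_map: np.ndarray) -> float:
    """Background estimate for a field: median of non-cell pixels."""
    outside = cell_label_map == 0
    if not outside.any():
        logger.warning("no background pixels in field; assuming background 0")
        return 0.0
    return float(np.median(image.pixels[outside]))


def compute_mfi(image: FluorImage, cell_mask: np.ndarray, background: float) -> float:
    """Mean of (pixel − background) over the cell mask, floored at 0."""
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    return max(float(np.mean(image.pixels[cell_mask] - background)), 0.0)


def degree_of_clustering(
    image: FluorImage,
    cell_mask: np.ndarray,
    punctum_mask: np.ndarray,
    all_puncta_mask: np.ndarray,
    *,
    background: float = 0.0,
    annulus_width: int = 3,
    core_fraction: float = 0.85,
    peak_percentile: float = 95.0,
) -> float:
    """Dc of one punctum: bright-core mean over nearby-cytosol median.

    Both numerator and denominator are background-subtracted intensities.
    The cytosol reference is the median over an annulus of ``annulus_width``
    px dilated around the punctum, intersected with the parent cell and
    excluding all puncta pixels. A punctum with an empty annulus (or
    non-positive cytosol reference) has undefined Dc and returns NaN.
    """
    if not punctum_mask.any():
        raise ValueError("empty punctum mask")
    bs = image.pixels - background
    dilated = ndi.binary_dilation(punctum_mask, structure=morphology.disk(annulus_width))
    annulus = dilated & cell_mask & ~all_puncta_mask
    if not annulus.any():
        logger.warning("punctum has an empty cytosol annulus; Dc undefined")
        return float("nan")
    baseline = float(np.median(bs[annulus]))
    if baseline <= 0:
        logger.warning("non-positive cytosol reference; Dc undefined")
        return float("nan")
    vals = bs[punctum_mask]
    peak = float(np.percentile(vals, peak_percentile))
    if peak <= baseline:
        return float(np.mean(vals)) / baseline
    cut = baseline + core_fraction * (peak - baseline)
    core = vals[vals >= cut]
    if core.size == 0:
        core = vals
    return float(np.mean(core)) / baseline


def puncta_size_distribution(
    puncta: pd.DataFrame, pixel_size: float | None = None
) -> dict:
    """Pooled particle areas with median and interquartile range.

    Areas are in px², or µm² when ``pixel_size`` (µm/px) is given. An empty
    table yields an empty distribution with NaN summary statistics.
    """
    areas = puncta["area"].to_numpy(dtype=float) if len(puncta) else np.empty(0)
    unit = "px^2"
    if pixel_size is not None:
        areas = areas * pixel_size**2
        unit = "um^2"
    if areas.size == 0:
        return {"areas": areas, "median": float("nan"), "iqr": (float("nan"), float("nan")),
                "unit": unit}
    q1, med, q3 = np.percentile(areas, [25, 50, 75])
    return {"areas": areas, "median": float(med), "iqr": (float(q1), float(q3)), "unit": unit}


def quantify_field(
    image: FluorImage,
    seg: SegmentationResult,
    detection_params: DetectionParams | None = None,
    params: MetricsParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and per-punctum statistics for one segmented field.

    Returns ``(cells, puncta)``:

    * cells — cell_id, well_id, field_id, area, mfi (NaN when saturated),
      puncta_count, positive, saturated;
    * puncta — the detection table plus parent cell and Dc.

    Saturated cells keep their puncta counts (positivity is a count-based
    call) but carry no MFI, and their puncta carry no Dc.
    """
    detection_params = detection_params or DetectionParams()
    params = params or MetricsParams()
    params.validate()

    labels = seg.cell_label_map
    bg = field_background(image, labels)
    sat = flag_saturated_cells(image, labels, detection_params).set_index("label")

    counts = (
        seg.puncta.groupby("parent_cell").size() if len(seg.puncta) else pd.Series(dtype=int)
    )
    all_puncta_mask = seg.puncta_label_map > 0

    cell_rows = []
    objects = ndi.find_objects(labels)
    for lab in range(1, seg.n_cells + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        mask = labels == lab
        saturated = bool(sat.loc[lab, "saturated"])
        n_puncta = int(counts.get(lab, 0))
        cell_rows.append(
            {
                "cell_id": lab,
                "well_id": image.well_id,
                "field_id": image.field_id,
                "area": int(mask.sum()),
                "mfi": float("nan") if saturated else compute_mfi(image, mask, bg),
                "puncta_count": n_puncta,
                "positive": classify_positive(n_puncta, params.positivity_threshold),
                "saturated": saturated,
            }
        )
    cells_df = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "well_id", "field_id", "area", "mfi", "puncta_count",
                 "positive", "saturated"],
    )

    puncta_df = seg.puncta.copy()
    dcs = []
    pobjects = ndi.find_objects(seg.puncta_label_map)
    pad = params.annulus_width + 2
    h, w = labels.shape
    for row in puncta_df.itertuples(index=False):
        parent = int(row.parent_cell)
        if parent > 0 and bool(sat.loc[parent, "saturated"]):
            dcs.append(float("nan"))
            continue
        sl = pobjects[int(row.label) - 1]
        rs = slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, h))
        cs = slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, w))
        win = (rs, cs)
        sub_img = FluorImage(
            pixels=np.clip(image.pixels[win], 0, image.max_value),
            bit_depth=image.bit_depth,
        )
        dc = degree_of_clustering(
            sub_img,
            labels[win] == parent,
            seg.puncta_label_map[win] == int(row.label),
            all_puncta_mask[win],
            background=bg,
            annulus_width=params.annulus_width,
            core_fraction=params.dc_core_fraction,
            peak_percentile=params.dc_peak_percentile,
        )
        dcs.append(dc)
    puncta_df["dc"] = dcs
    puncta_df.insert(0, "well_id", image.well_id)
    puncta_df.insert(1, "field_id", image.field_id)
    return cells_df, puncta_df


def summarize_sample(
    cells: pd.DataFrame,
    puncta: pd.DataFrame,
    *,
    sample_id: str | None = None,
    pixel_size: float | None = None,
    params: MetricsParams | None = None,
) -> dict:
    """Sample-level summary over (possibly multi-field) cell tables.

    Saturated cells are excluded from MFI statistics but included in the
    positivity denominator. Fewer than ``min_cells_warn`` cells triggers a
    QC warning, not an error.
    """
    params = params or MetricsParams()
    n_cells = int(len(cells))
    warnings: list[str] = []
    if n_cells < params.min_cells_warn:
        msg = f"sample {sample_id or '?'}: only {n_cells} cells (< {params.min_cells_warn})"
        warnings.append(msg)
        logger.warning(msg)
    mfi = cells.loc[~cells["saturated"], "mfi"].to_numpy(dtype=float) if n_cells else np.empty(0)
    sizes = puncta_size_distribution(puncta, pixel_size)
    dc_vals = puncta["dc"].to_numpy(dtype=float) if "dc" in puncta else np.empty(0)
    dc_vals = dc_vals[np.isfinite(dc_vals)]
    return {
        "sample_id": sample_id,
        "n_cells": n_cells,
        "percent_positive": percent_positive(cells) if n_cells else float("nan"),
        "mfi_mean": float(np.mean(mfi)) if mfi.size else float("nan"),
        "mfi_sd": float(np.std(mfi, ddof=1)) if mfi.size > 1 else float("nan"),
        "median_puncta_area": sizes["median"],
        "puncta_area_iqr": sizes["iqr"],
        "mean_dc": float(np.mean(dc_vals)) if dc_vals.size else float("nan"),
        "warnings": warnings,
    }
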