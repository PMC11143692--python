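"""Cell segmentation and intracellular puncta detection.

The stages mirror a classic particle-analysis workflow: a smoothed global
threshold isolates cells, then a band-pass filter with a robust per-cell
threshold isolates bright puncta inside each cell, and connected components
within an area window become particles. Touching particles are optionally
split by a watershed seeded at band-pass maxima, the standard companion step
to particle analysis on dense fields.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.stats import median_abs_deviation
from skimage import measure, morphology, segmentation
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .images import FluorImage

logger = logging.getLogger(__name__)

__all__ = ["DetectionParams", "SegmentationResult", "segment_cells", "detect_puncta",
           "flag_saturated_cells"]


@dataclass
class DetectionParams:
    """Tunable operators of the detection stage.

    Cell segmentation: Gaussian smooth (``smooth_sigma``) then a global
    threshold — by default from background statistics (median + max(k·MAD,
    relative floor) of the smoothed image, robust when expression varies
    several-fold between cells), with Otsu and fixed thresholds as
    alternatives — then hole filling, small-object removal and optional
    border-cell discarding.

    Puncta detection: difference-of-Gaussians band-pass
    (``spot_sigma1``/``spot_sigma2``) thresholded per cell at
    ``median + max(k·noise_sd, floor)``, where ``noise_sd`` is the robust sd
    of the band-pass response over background pixels and the floor is
    ``spot_floor_frac`` of the cell's background-subtracted interior median
    intensity. Both terms scale with the image, so detection is invariant to
    intensity offsets and positive rescaling (up to clipping).
    """

    smooth_sigma: float = 2.0
    cell_threshold_method: str = "background"  # "background" | "otsu" | "fixed"
    cell_threshold: float | None = None
    cell_threshold_k: float = 5.0
    cell_floor_frac: float = 0.02
    min_cell_area: int = 500
    split_touching: bool = False
    discard_border_cells: bool = True

    spot_bandpass: str = "dog"  # "dog" | "tophat"
    spot_sigma1: float = 1.2
    spot_sigma2: float = 2.4
    spot_tophat_radius: float = 3.0
    spot_threshold_k: float = 5.0
    spot_floor_frac: float = 0.2
    edge_exclude_px: int = 7
    split_touching_puncta: bool = True
    peak_min_distance: int = 3
    min_puncta_area: int = 4
    max_puncta_area: int = 400

    saturation_fraction_max: float = 0.001

    def validate(self) -> None:
        if self.min_puncta_area < 1:
            raise ValueError("min_puncta_area must be >= 1")
        if self.max_puncta_area < self.min_puncta_area:
            raise ValueError("max_puncta_area must be >= min_puncta_area")
        if self.min_cell_area <= self.max_puncta_area:
            raise ValueError("min_cell_area must exceed max_puncta_area")
        if self.cell_threshold_method not in ("background", "otsu", "fixed"):
            raise ValueError(
                "cell_threshold_method must be 'background', 'otsu' or 'fixed'"
            )
        if self.cell_threshold_method == "fixed" and self.cell_threshold is None:
            raise ValueError("fixed thresholding requires cell_threshold")
        if self.spot_bandpass not in ("dog", "tophat"):
            raise ValueError("spot_bandpass must be 'dog' or 'tophat'")
        if not (0.0 <= self.saturation_fraction_max < 1.0):
            raise ValueError("saturation_fraction_max must lie in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


@dataclass
class SegmentationResult:
    """Cell and puncta label maps plus per-label measurements.

    Invariants: puncta pixels are a subset of cell pixels (each punctum has
    exactly one parent cell); labels are positive integers contiguous from 1.
    """

    cell_label_map: np.ndarray
    puncta_label_map: np.ndarray
    cells: pd.DataFrame   # label, area, integrated_intensity
    puncta: pd.DataFrame  # label, parent_cell, area, centroid_row/col, mean/max/integrated

    @property
    def n_cells(self) -> int:
        return int(self.cell_label_map.max())

    @property
    def n_puncta(self) -> int:
        return int(self.puncta_label_map.max())


def segment_cells(image: FluorImage, params: DetectionParams) -> np.ndarray:
    """Label cells in a field; background is 0.

    A blank field (no foreground after thresholding) returns an all-zero
    label map with a logged warning rather than raising.
    """
    params.validate()
    img = image.pixels
    smoothed = ndi.gaussian_filter(img, params.smooth_sigma)

    if params.cell_threshold_method == "fixed":
        thr = float(params.cell_threshold)  # type: ignore[arg-type]
    elif params.cell_threshold_method == "otsu":
        if np.isclose(smoothed.max(), smoothed.min()):
            logger.warning("blank field (constant image): no cells segmented")
            return np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
    else:
        # background statistics: with background the majority class, the
        # global median sits at the background level and the MAD estimates
        # its noise; a small relative floor covers the noise-free case.
        # Unlike Otsu this does not split dim cells off when expression
        # varies several-fold between cells.
        med = float(np.median(smoothed))
        mad = 1.4826 * float(median_abs_deviation(smoothed, axis=None))
        thr = med + max(params.cell_threshold_k * mad, params.cell_floor_frac * abs(med))

    fg = smoothed > thr
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        logger.warning("blank field: no foreground above threshold")
        return np.zeros(img.shape, dtype=np.int32)

    if params.split_touching:
        distance = ndi.distance_transform_edt(fg)
        coords = peak_local_max(
            distance, labels=measure.label(fg, connectivity=2),
            min_distance=int(np.sqrt(params.min_cell_area / np.pi)),
        )
        markers = np.zeros(fg.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = segmentation.watershed(-distance, markers, mask=fg)
    else:
        labels = measure.label(fg, connectivity=2)

    if params.discard_border_cells:
        labels = segmentation.clear_border(labels)

    # area filter may need re-applying after border clearing / splitting
    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts < params.min_cell_area)
    labels[np.isin(labels, too_small[too_small > 0])] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(np.int32)


def _bandpass(img: np.ndarray, params: DetectionParams) -> np.ndarray:
    if params.spot_bandpass == "dog":
        return ndi.gaussian_filter(img, params.spot_sigma1) - ndi.gaussian_filter(
            img, params.spot_sigma2
        )
    footprint = morphology.disk(int(round(params.spot_tophat_radius)))
    return morphology.white_tophat(img, footprint=footprint)


def detect_puncta(
    image: FluorImage, cell_label_map: np.ndarray, params: DetectionParams
) -> SegmentationResult:
    """Detect bright particles inside each segmented cell.

    Per cell, the band-pass response is thresholded at
    ``median + max(k·MAD, floor)`` computed over the cell's interior (the
    cell mask eroded by ``edge_exclude_px``, which suppresses the band-pass
    ripple at the cell boundary). Connected components within the area window
    become particles; components holding several band-pass maxima are split
    by watershed when ``split_touching_puncta``. A cell whose interior
    response has zero spread and zero floor yields no puncta.
    """
    params.validate()
    if cell_label_map.shape != image.pixels.shape:
        raise ValueError("cell_label_map must be aligned with the image")
    img = image.pixels
    labels = cell_label_map
    n_cells = int(labels.max())

    bp = _bandpass(img, params)
    inside = labels > 0
    outside = ~inside
    bg = float(np.median(img[outside])) if outside.any() else 0.0
    # band-pass noise level, measured where there is no structure: robust sd
    # of the response over background pixels (in-cell response adds spots and
    # their negative band-pass lobes, which corrupt any in-cell estimate)
    noise_sd = (
        1.4826 * float(median_abs_deviation(bp[outside], axis=None))
        if outside.any()
        else 0.0
    )

    # the smooth intensity ramp at the cell boundary has its own band-pass
    # response; threshold statistics are computed on the eroded interior,
    # and particles peaking inside the edge band are rejected afterwards
    interior = inside
    if params.edge_exclude_px > 0:
        interior = ndi.binary_erosion(inside, iterations=params.edge_exclude_px)

    mask = np.zeros(img.shape, dtype=bool)
    objects = ndi.find_objects(labels)
    for lab in range(1, n_cells + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        cell_sel = labels[sl] == lab
        det_sel = cell_sel & interior[sl]
        vals = bp[sl][det_sel]
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        # cytosol level from the interior only: the boundary ramp pixels
        # bias a whole-mask median low, weakening the floor
        cyto = float(np.median(img[sl][det_sel])) - bg
        floor = params.spot_floor_frac * max(cyto, 0.0)
        spread = max(params.spot_threshold_k * noise_sd, floor)
        if spread <= 0:
            continue  # zero-variance cell on a noise-free field: no puncta
        thr = med + spread
        mask[sl] |= cell_sel & (bp[sl] > thr)

    comp = measure.label(mask, connectivity=2)
    if params.split_touching_puncta and comp.max() > 0:
        coords = peak_local_max(
            bp, labels=comp, min_distance=params.peak_min_distance, exclude_border=False
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        ws = segmentation.watershed(-bp, markers, mask=mask)
        leftover = mask & (ws == 0)  # components that produced no seed
        if leftover.any():
            extra = measure.label(leftover, connectivity=2)
            extra[extra > 0] += ws.max()
            ws = ws + extra
        comp = ws

    # area filter ("Analyze Particle" semantics)
    areas = np.bincount(comp.ravel())
    bad = np.flatnonzero(
        (areas < params.min_puncta_area) | (areas > params.max_puncta_area)
    )
    comp[np.isin(comp, bad[bad > 0])] = 0
    # drop particles whose response peak lies in the boundary band
    if params.edge_exclude_px > 0 and comp.max() > 0:
        keep = np.zeros(int(comp.max()) + 1, dtype=bool)
        for prop in measure.regionprops(comp, intensity_image=bp):
            rr, cc = prop.coords[np.argmax(bp[tuple(prop.coords.T)])]
            keep[prop.label] = interior[rr, cc]
        comp[~keep[comp]] = 0
    comp, _, _ = segmentation.relabel_sequential(comp)
    puncta_labels = comp.astype(np.int32)

    # measurements
    puncta_rows = []
    for prop in measure.regionprops(puncta_labels, intensity_image=img):
        coords = prop.coords
        parent = int(labels[coords[0][0], coords[0][1]])
        puncta_rows.append(
            {
                "label": int(prop.label),
                "parent_cell": parent,
                "area": int(prop.area),
                "centroid_row": float(prop.centroid[0]),
                "centroid_col": float(prop.centroid[1]),
                "mean_intensity": float(prop.intensity_mean),
                "max_intensity": float(prop.intensity_max),
                "integrated_intensity": float(prop.intensity_mean * prop.area),
            }
        )
    puncta_df = pd.DataFrame(
        puncta_rows,
        columns=[
            "label", "parent_cell", "area", "centroid_row", "centroid_col",
            "mean_intensity", "max_intensity", "integrated_intensity",
        ],
    )

    cell_rows = []
    for prop in measure.regionprops(labels, intensity_image=img):
        cell_rows.append(
            {
                "label": int(prop.label),
                "area": int(prop.area),
                "integrated_intensity": float(prop.intensity_mean * prop.area),
            }
        )
    cells_df = pd.DataFrame(cell_rows, columns=["label", "area", "integrated_intensity"])

    return SegmentationResult(
        cell_label_map=labels.astype(np.int32),
        puncta_label_map=puncta_labels,
        cells=cells_df,
        puncta=puncta_df,
    )


def flag_saturated_cells(
    image: FluorImage, cell_label_map: np.ndarray, params: DetectionParams
) -> pd.DataFrame:
    """Flag cells whose saturated-pixel fraction strictly exceeds
    ``saturation_fraction_max``; flagged cells are excluded from MFI and Dc
    statistics downstream."""
    params.validate()
    sat = image.saturated_mask()
    n_cells = int(cell_label_map.max())
    rows = []
    for lab in range(1, n_cells + 1):
        sel = cell_label_map == lab
        area = int(sel.sum())
        frac = float(sat[sel].sum() / area) if area else 0.0
        rows.append(
            {
                "label": lab,
                "saturated_fraction": frac,
                "saturated": bool(frac > params.saturation_fraction_max),
            }
        )
    return pd.DataFrame(rows, columns=["label", "saturated_fraction", "saturated"])
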