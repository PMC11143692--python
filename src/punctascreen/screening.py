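"""Well-level screening statistics: reporter signal, normalization, Z′, hits.

The well readout ("TORSEL signal") is the ratio of summed puncta pixel
intensity to summed cell pixel intensity in a field; plates are normalized
both min–max (plate-level score in [0, 1]) and as percent of the mean
positive control (the reference for hit calling at the 30% threshold).
Assay quality is the Z′ factor, 1 − 3(σp + σn)/|µp − µn|, computed from the
positive- and negative-control wells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import SegmentationResult
from .images import FluorImage

logger = logging.getLogger(__name__)

__all__ = ["ScreenQC", "torsel_signal", "minmax_normalize", "z_prime", "call_hits",
           "screen_plate"]


@dataclass
class ScreenQC:
    """Control statistics and assay-quality summary for one plate."""

    mu_p: float
    sigma_p: float
    mu_n: float
    sigma_n: float
    z_prime: float
    n_positive: int
    n_negative: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mu_positive": self.mu_p,
            "sigma_positive": self.sigma_p,
            "mu_negative": self.mu_n,
            "sigma_negative": self.sigma_n,
            "z_prime": self.z_prime,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "warnings": list(self.warnings),
        }


def torsel_signal(seg: SegmentationResult, image: FluorImage) -> float:
    """Σ(puncta pixel intensity) / Σ(cell pixel intensity) for one field.

    The denominator runs over all cell pixels, puncta included, so the
    ratio lies in [0, 1]. A field without cell pixels has no signal and
    returns NaN with a warning (QC flag upstream).
    """
    cells = seg.cell_label_map > 0
    if not cells.any():
        logger.warning("field has no cell pixels; signal undefined")
        return float("nan")
    puncta = seg.puncta_label_map > 0
    den = float(image.pixels[cells].sum())
    if den <= 0:
        logger.warning("zero total cell intensity; signal undefined")
        return float("nan")
    num = float(image.pixels[puncta].sum())
    return num / den


def minmax_normalize(signals) -> np.ndarray:
    """(x − min) / (max − min) over a plate's well signals.

    Requires at least two distinct values; a degenerate (constant) input is
    undefined and raises rather than dividing by zero.
    """
    x = np.asarray(signals, dtype=float)
    if x.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    if hi == lo:
        raise ValueError("min-max normalization undefined: all values identical")
    return (x - lo) / (hi - lo)


def z_prime(positives, negatives) -> float:
    """Z′ factor = 1 − 3(σp + σn)/|µp − µn| with sample standard deviations."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("z_prime needs >= 2 wells per control arm")
    mu_p, mu_n = float(np.mean(pos)), float(np.mean(neg))
    if mu_p == mu_n:
        raise ValueError("z_prime undefined: control means are equal (assay failure)")
    sigma_p = float(np.std(pos, ddof=1))
    sigma_n = float(np.std(neg, ddof=1))
    return 1.0 - 3.0 * (sigma_p + sigma_n) / abs(mu_p - mu_n)


def call_hits(
    wells: pd.DataFrame, threshold: float = 0.30
) -> pd.DataFrame:
    """Express each well as percent of the mean positive control and flag hits.

    ``wells`` needs columns well_id, role, signal. Each well's
    ``percent_of_positive`` is 100 · signal / mean(positive-control signals);
    a sample well is a hit iff that percentage is >= 100·threshold
    (inclusive). Hit calling is refused without positive controls.
    """
    if not {"well_id", "role", "signal"} <= set(wells.columns):
        raise ValueError("wells table needs well_id, role and signal columns")
    pos = wells.loc[wells["role"] == "positive_control", "signal"].to_numpy(dtype=float)
    pos = pos[np.isfinite(pos)]
    if pos.size == 0:
        raise ValueError("hit calling refused: no measured positive-control wells")
    ref = float(np.mean(pos))
    if ref <= 0:
        raise ValueError("hit calling refused: non-positive reference signal")
    out = wells.copy()
    out["percent_of_positive"] = 100.0 * out["signal"].astype(float) / ref
    out["hit"] = (out["percent_of_positive"] >= 100.0 * threshold) & (
        out["role"] == "sample"
    )
    return out


def screen_plate(
    well_signals: pd.DataFrame, *, hit_threshold: float = 0.30
) -> tuple[pd.DataFrame, ScreenQC]:
    """Score a plate of per-well signals.

    ``well_signals`` needs columns well_id, role, signal (one row per well,
    signals already aggregated over fields). Emits both normalization
    conventions — min–max score over the plate and percent of the mean
    positive control — plus hit flags (called on percent-of-positive) and a
    :class:`ScreenQC` with control statistics and Z′.
    """
    warnings: list[str] = []
    roles = set(well_signals["role"])
    if "positive_control" not in roles or "negative_control" not in roles:
        raise ValueError("a plate needs >= 1 positive and >= 1 negative control well")

    wells = call_hits(well_signals, threshold=hit_threshold)

    try:
        wells["normalized_score"] = minmax_normalize(wells["signal"].to_numpy())
    except ValueError as exc:
        warnings.append(f"min-max normalization skipped: {exc}")
        wells["normalized_score"] = float("nan")

    pos = wells.loc[wells["role"] == "positive_control", "signal"].to_numpy(dtype=float)
    neg = wells.loc[wells["role"] == "negative_control", "signal"].to_numpy(dtype=float)
    nan_wells = wells.loc[~np.isfinite(wells["signal"].astype(float)), "well_id"]
    for wid in nan_wells:
        warnings.append(f"well {wid}: signal missing (no measurable cells)")

    zp = float("nan")
    try:
        zp = z_prime(pos, neg)
    except ValueError as exc:
        warnings.append(f"z_prime unavailable: {exc}")

    qc = ScreenQC(
        mu_p=float(np.mean(pos)) if pos.size else float("nan"),
        sigma_p=float(np.std(pos, ddof=1)) if pos.size > 1 else float("nan"),
        mu_n=float(np.mean(neg)) if neg.size else float("nan"),
        sigma_n=float(np.std(neg, ddof=1)) if neg.size > 1 else float("nan"),
        z_prime=zp,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        warnings=warnings,
    )
    return wells, qc
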