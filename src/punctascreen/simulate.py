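"""Seeded synthetic fluorescence fields with per-cell / per-punctum ground truth.

The generator emulates the imaging regime of a phase-separation puncta
reporter: cells carry a diffuse cytosolic signal drawn from an expression
tier, and "responding" cells additionally carry tens of discrete bright
puncta whose contrast over the local cytosol (the degree of clustering, Dc)
is fixed by construction. The rendered expectation image is corrupted by the
standard camera model — Poisson shot noise plus additive Gaussian read
noise — and clipped to the camera bit depth.

Every field is reproducible bit-for-bit from its :class:`SimConfig`
(including the seed), and ships with a :class:`GroundTruth` that downstream
detection and metrics stages are scored against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

from .images import FluorImage

__all__ = [
    "EXPRESSION_TIERS",
    "SimConfig",
    "GroundTruth",
    "GenerationError",
    "simulate_field",
    "simulate_plate",
    "plate_sim_config",
    "make_plate_map",
    "write_field",
]

#: Target mean ± sd of background-subtracted cytosolic intensity per
#: expression tier (low / medium / high reporter expression).
EXPRESSION_TIERS: dict[str, tuple[float, float]] = {
    "low": (19.6, 11.22),
    "medium": (74.08, 18.5),
    "high": (148.24, 22.18),
}

#: Minimum cytosolic intensity; tier draws below this are resampled.
_MIN_CYTOSOL = 2.0
#: Gap (px) required between neighbouring cell boundaries.
_CELL_GAP = 4.0
#: Extra slot width (px) granting jitter room to the cell placement grid.
_SLOT_SLACK = 8.0


class GenerationError(RuntimeError):
    """A field could not be generated under the requested configuration."""


@dataclass
class SimConfig:
    """Configuration of one synthetic field.

    Defaults reproduce the positive-control regime of the assay this package
    models: ~80% of cells respond with 10–100 puncta each, puncta contrast
    (Dc) uniform in [2, 4], medium reporter expression, and camera noise at
    a level where puncta are visually obvious.
    """

    image_shape: tuple[int, int] = (512, 512)
    bit_depth: int = 16
    n_cells: int = 4
    cell_radius_range: tuple[float, float] = (62.0, 72.0)
    cell_aspect_range: tuple[float, float] = (1.0, 1.5)
    cell_edge_width: float = 2.0
    expression_tier: str = "medium"
    responder_fraction: float = 0.8
    puncta_per_cell_range: tuple[int, int] = (10, 100)
    puncta_core_radius: float = 1.8
    puncta_sigma: float = 0.7
    puncta_grid_spacing: float = 8.0
    target_dc_range: tuple[float, float] = (2.0, 4.0)
    background_level: float = 100.0
    read_noise_sd: float = 4.0
    shot_noise: bool = True
    allow_border_cells: bool = False
    pixel_size: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must lie in [0, 1]")
        lo, hi = self.puncta_per_cell_range
        if lo < 0 or hi < lo:
            raise ValueError("puncta_per_cell_range must satisfy 0 <= lo <= hi")
        dlo, dhi = self.target_dc_range
        if dlo <= 1.0 or dhi < dlo:
            raise ValueError("target_dc_range lower bound must be > 1")
        rlo, rhi = self.cell_radius_range
        if rlo <= 0 or rhi < rlo:
            raise ValueError("cell_radius_range must be positive and ordered")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.expression_tier not in EXPRESSION_TIERS:
            raise ValueError(f"unknown expression tier: {self.expression_tier!r}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported bit depth: {self.bit_depth}")
        if self.puncta_grid_spacing <= 2 * self.puncta_core_radius:
            raise ValueError("puncta_grid_spacing must exceed the punctum diameter")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")

    # ---- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                kwargs[f.name] = tuple(kwargs[f.name])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Per-cell and per-punctum truth for one simulated field.

    ``cells`` columns: label, row, col, semi_major, semi_minor, angle,
    cytosol (true background-subtracted MFI of the plateau), responder,
    n_puncta, border.

    ``puncta`` columns: cell_label, row, col, amplitude, dc. ``dc`` is the
    amplitude-over-local-cytosol ratio ``(amplitude + cytosol) / cytosol``,
    exact by construction.
    """

    cell_label_map: np.ndarray
    cells: pd.DataFrame
    puncta: pd.DataFrame

    @property
    def total_puncta(self) -> int:
        return int(len(self.puncta))

    def puncta_of(self, label: int) -> pd.DataFrame:
        return self.puncta[self.puncta["cell_label"] == label]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _slot_grid(size: int, spacing: float, margin: float) -> np.ndarray:
    """1D slot centres with pairwise distance >= spacing, centred in the image."""
    usable = size - 2.0 * margin
    if usable < 0:
        return np.empty(0)
    n = int(usable // spacing) + 1
    offset = margin + (usable - spacing * (n - 1)) / 2.0
    return offset + spacing * np.arange(n)


def _place_cells(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Assign each cell an ellipse (centre, semi-axes, angle) on a jittered
    slot grid. Slots guarantee non-overlap with a minimum boundary gap;
    insufficient capacity raises :class:`GenerationError` rather than
    silently truncating."""
    if config.n_cells == 0:
        return []
    h, w = config.image_shape
    rlo, rhi = config.cell_radius_range
    alo, ahi = config.cell_aspect_range
    max_extent = rhi * np.sqrt(ahi)
    spacing = 2.0 * max_extent + _CELL_GAP + _SLOT_SLACK
    margin = 2.0 if config.allow_border_cells else max_extent + 2.0

    rows = _slot_grid(h, spacing, margin)
    cols = _slot_grid(w, spacing, margin)
    slots = [(r, c) for r in rows for c in cols]
    if len(slots) < config.n_cells:
        raise GenerationError(
            f"cannot place {config.n_cells} cells of radius <= {rhi:.0f} px in a "
            f"{h}x{w} field ({len(slots)} slots available); reduce n_cells or "
            "cell size, or enlarge the field"
        )
    order = rng.permutation(len(slots))[: config.n_cells]

    cells = []
    for slot_idx in order:
        r = rng.uniform(rlo, rhi)
        aspect = rng.uniform(alo, ahi)
        a = r * np.sqrt(aspect)  # semi-major
        b = r / np.sqrt(aspect)  # semi-minor
        angle = rng.uniform(0.0, np.pi)
        jitter = max((spacing - _CELL_GAP - a - max_extent) / 2.0, 0.0)
        cy, cx = slots[slot_idx]
        cy += rng.uniform(-jitter, jitter)
        cx += rng.uniform(-jitter, jitter)
        cells.append({"row": cy, "col": cx, "a": a, "b": b, "angle": angle})
    return cells


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _ellipse_frame(
    shape: tuple[int, int], cell: dict, pad: float
) -> tuple[tuple[slice, slice], np.ndarray, np.ndarray]:
    """Bounding-box slices plus (u, v) coordinates in the ellipse frame."""
    h, w = shape
    extent = max(cell["a"], cell["b"]) + pad
    r0 = max(int(np.floor(cell["row"] - extent)), 0)
    r1 = min(int(np.ceil(cell["row"] + extent)) + 1, h)
    c0 = max(int(np.floor(cell["col"] - extent)), 0)
    c1 = min(int(np.ceil(cell["col"] + extent)) + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - cell["row"]
    dx = cc - cell["col"]
    cos, sin = np.cos(cell["angle"]), np.sin(cell["angle"])
    u = dx * cos + dy * sin
    v = -dx * sin + dy * cos
    return (slice(r0, r1), slice(c0, c1)), u, v


def _puncta_positions(
    cell: dict, margin: float, spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """Candidate punctum centres: a randomly offset grid clipped to the
    margin-shrunken ellipse, jittered by ±0.5 px. Grid spacing bounds the
    minimum centre separation from below (spacing − √2)."""
    aa = cell["a"] - margin
    bb = cell["b"] - margin
    if aa <= 0 or bb <= 0:
        return np.empty((0, 2))
    off_u = rng.uniform(0, spacing)
    off_v = rng.uniform(0, spacing)
    us = np.arange(-aa + off_u, aa, spacing)
    vs = np.arange(-bb + off_v, bb, spacing)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    inside = (uu / aa) ** 2 + (vv / bb) ** 2 <= 1.0
    uu, vv = uu[inside], vv[inside]
    jitter = rng.uniform(-0.5, 0.5, size=(uu.size, 2))
    cos, sin = np.cos(cell["angle"]), np.sin(cell["angle"])
    rows = cell["row"] + uu * sin + vv * cos + jitter[:, 0]
    cols = cell["col"] + uu * cos - vv * sin + jitter[:, 1]
    return np.column_stack([rows, cols])


def _render_spot(
    expectation: np.ndarray,
    row: float,
    col: float,
    amplitude: float,
    core_radius: float,
    sigma: float,
) -> None:
    """Add a flat-core spot with a Gaussian edge at (row, col)."""
    h, w = expectation.shape
    extent = core_radius + 4.0 * sigma
    r0 = max(int(np.floor(row - extent)), 0)
    r1 = min(int(np.ceil(row + extent)) + 1, h)
    c0 = max(int(np.floor(col - extent)), 0)
    c1 = min(int(np.ceil(col + extent)) + 1, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rho = np.hypot(rr - row, cc - col)
    profile = np.where(
        rho <= core_radius,
        1.0,
        np.exp(-((rho - core_radius) ** 2) / (2.0 * sigma**2)),
    )
    expectation[r0:r1, c0:c1] += amplitude * profile


def puncta_margin(config: SimConfig, annulus_width: float = 3.0) -> float:
    """Distance puncta keep from the nominal cell boundary so that the
    contrast annulus sits on plateau cytosol."""
    return (
        config.puncta_core_radius
        + 3.0 * config.puncta_sigma
        + annulus_width
        + config.cell_edge_width
    )


# ---------------------------------------------------------------------------
# field simulation
# ---------------------------------------------------------------------------

def simulate_field(
    config: SimConfig,
    *,
    rng: np.random.Generator | None = None,
    well_id: str | None = None,
    field_id: str | None = None,
) -> tuple[FluorImage, GroundTruth]:
    """Render one field and its ground truth.

    The expectation image is background + smooth elliptical cells at their
    cytosolic level + flat-core puncta whose plateau amplitude realises the
    drawn target Dc exactly: ``amplitude = (dc - 1) * cytosol``. Poisson shot
    noise (on the expectation) and Gaussian read noise are then applied and
    the result is clipped to ``[0, 2**bit_depth - 1]``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    h, w = config.image_shape
    maxv = float(2**config.bit_depth - 1)
    tier_mean, tier_sd = EXPRESSION_TIERS[config.expression_tier]

    expectation = np.full((h, w), float(config.background_level))
    label_map = np.zeros((h, w), dtype=np.int32)

    cells = _place_cells(config, rng)
    margin = puncta_margin(config)
    n_lo, n_hi = config.puncta_per_cell_range

    cell_rows: list[dict] = []
    puncta_rows: list[dict] = []
    for label, cell in enumerate(cells, start=1):
        # cytosolic level from the expression tier, resampled above the floor
        cytosol = rng.normal(tier_mean, tier_sd)
        for _ in range(1000):
            if cytosol >= _MIN_CYTOSOL:
                break
            cytosol = rng.normal(tier_mean, tier_sd)
        else:  # pragma: no cover - 1000 draws below floor is unreachable
            raise GenerationError("could not draw a positive cytosolic intensity")

        box, u, v = _ellipse_frame((h, w), cell, pad=2.0 * config.cell_edge_width + 2.0)
        e = np.sqrt((u / cell["a"]) ** 2 + (v / cell["b"]) ** 2)
        r_geo = np.sqrt(cell["a"] * cell["b"])
        t = (1.0 - e) * r_geo / (2.0 * config.cell_edge_width) + 0.5
        expectation[box] += cytosol * _smoothstep(t)
        inside = e <= 1.0
        label_map[box][inside] = label
        border = bool(
            inside[0, :].any() or inside[-1, :].any()
            or inside[:, 0].any() or inside[:, -1].any()
        ) if (
            box[0].start == 0 or box[0].stop == h or box[1].start == 0 or box[1].stop == w
        ) else False

        responder = bool(rng.random() < config.responder_fraction)
        n_puncta = int(rng.integers(n_lo, n_hi + 1)) if responder else 0
        if n_puncta:
            candidates = _puncta_positions(cell, margin, config.puncta_grid_spacing, rng)
            if len(candidates) < n_puncta:
                raise GenerationError(
                    f"cell {label} can host at most {len(candidates)} puncta at "
                    f"{config.puncta_grid_spacing:.1f} px spacing but {n_puncta} were "
                    "requested; enlarge cells or reduce puncta_per_cell_range"
                )
            chosen = candidates[rng.choice(len(candidates), size=n_puncta, replace=False)]
            dcs = rng.uniform(*config.target_dc_range, size=n_puncta)
            for (prow, pcol), dc in zip(chosen, dcs):
                amplitude = (dc - 1.0) * cytosol
                _render_spot(
                    expectation, prow, pcol, amplitude,
                    config.puncta_core_radius, config.puncta_sigma,
                )
                puncta_rows.append(
                    {
                        "cell_label": label,
                        "row": float(prow),
                        "col": float(pcol),
                        "amplitude": float(amplitude),
                        "dc": float(dc),
                    }
                )

        cell_rows.append(
            {
                "label": label,
                "row": float(cell["row"]),
                "col": float(cell["col"]),
                "semi_major": float(cell["a"]),
                "semi_minor": float(cell["b"]),
                "angle": float(cell["angle"]),
                "cytosol": float(cytosol),
                "responder": responder,
                "n_puncta": n_puncta,
                "border": border,
            }
        )

    img = expectation
    if config.shot_noise:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, maxv)

    cells_df = pd.DataFrame(
        cell_rows,
        columns=[
            "label", "row", "col", "semi_major", "semi_minor", "angle",
            "cytosol", "responder", "n_puncta", "border",
        ],
    )
    puncta_df = pd.DataFrame(
        puncta_rows, columns=["cell_label", "row", "col", "amplitude", "dc"]
    )
    image = FluorImage(
        pixels=img,
        bit_depth=config.bit_depth,
        well_id=well_id,
        field_id=field_id,
        pixel_size=config.pixel_size,
    )
    return image, GroundTruth(cell_label_map=label_map, cells=cells_df, puncta=puncta_df)


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------

def plate_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """SimConfig preset for plate-scale screening fields: smaller cells and
    moderate puncta counts keep per-well throughput high while preserving
    the positive-control regime (~80% responders, Dc 2–4)."""
    defaults = dict(
        n_cells=9,
        cell_radius_range=(32.0, 40.0),
        puncta_per_cell_range=(12, 22),
        puncta_grid_spacing=6.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def make_plate_map(
    n_positive: int = 8,
    n_negative: int = 8,
    n_responder_samples: int = 20,
    n_null_samples: int = 60,
    *,
    positive_effect: float = 0.8,
    negative_effect: float = 0.02,
) -> pd.DataFrame:
    """Construct a 96-well style plate map table.

    Columns: well_id, compound, dose, role, effect. ``effect`` is the true
    per-well responder fraction driving the simulation; ``role`` is one of
    positive_control / negative_control / sample.
    """
    rows = []
    letters = "ABCDEFGH"
    idx = 0

    def next_well():
        nonlocal idx
        well = f"{letters[idx // 12]}{idx % 12 + 1:02d}"
        idx += 1
        return well

    for i in range(n_positive):
        rows.append((next_well(), "Torin1", 0.1, "positive_control", positive_effect))
    for i in range(n_negative):
        rows.append((next_well(), "DMSO", 0.0, "negative_control", negative_effect))
    for i in range(n_responder_samples):
        rows.append((next_well(), f"cmpd{i + 1:03d}", 10.0, "sample", positive_effect))
    for i in range(n_null_samples):
        rows.append(
            (next_well(), f"cmpd{n_responder_samples + i + 1:03d}", 10.0, "sample",
             negative_effect)
        )
    return pd.DataFrame(rows, columns=["well_id", "compound", "dose", "role", "effect"])


_ROLES = {"positive_control", "negative_control", "sample"}


def validate_plate_map(plate_map: pd.DataFrame) -> None:
    required = {"well_id", "role"}
    missing = required - set(plate_map.columns)
    if missing:
        raise ValueError(f"plate map is missing columns: {sorted(missing)}")
    dupes = plate_map["well_id"][plate_map["well_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate well IDs in plate map: {sorted(set(dupes))}")
    bad = set(plate_map["role"]) - _ROLES
    if bad:
        raise ValueError(f"unknown roles in plate map: {sorted(bad)}")


def simulate_plate(
    plate_map: pd.DataFrame,
    config: SimConfig,
    *,
    fields_per_well: int = 3,
) -> Iterator[tuple[str, str, FluorImage, GroundTruth]]:
    """Yield ``(well_id, field_id, image, truth)`` for every well and field.

    Each well's responder fraction comes from its ``effect`` column (falling
    back to ``config.responder_fraction`` for positive controls and 0 for
    wells without an effect). Per-field RNG streams are spawned from
    ``config.seed`` and the (well, field) index, so a plate is reproducible
    well-by-well and wells are statistically independent.
    """
    validate_plate_map(plate_map)
    config.validate()
    for wi, row in enumerate(plate_map.itertuples(index=False)):
        if "effect" in plate_map.columns and not pd.isna(getattr(row, "effect", None)):
            effect = float(row.effect)
        elif row.role == "positive_control":
            effect = config.responder_fraction
        else:
            effect = 0.0
        well_cfg = replace(config, responder_fraction=effect)
        for fi in range(fields_per_well):
            seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(wi, fi))
            rng = np.random.default_rng(seq)
            field_id = f"f{fi + 1}"
            image, truth = simulate_field(
                well_cfg, rng=rng, well_id=row.well_id, field_id=field_id
            )
            yield row.well_id, field_id, image, truth


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------

def write_field(
    outdir: str | Path,
    prefix: str,
    image: FluorImage,
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write image + label map as TIFF and ground truth as CSV tables."""
    from .images import save_tiff

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{prefix}.tif",
        "labels": outdir / f"{prefix}_labels.tif",
        "cells": outdir / f"{prefix}_cells.csv",
        "puncta": outdir / f"{prefix}_puncta.csv",
    }
    save_tiff(image, paths["image"])
    tifffile.imwrite(paths["labels"], truth.cell_label_map.astype(np.uint16))
    truth.cells.to_csv(paths["cells"], index=False)
    truth.puncta.to_csv(paths["puncta"], index=False)
    return paths
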