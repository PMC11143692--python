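"""End-to-end orchestration: config, plate processing, outputs, QC.

A run takes a plate map (CSV) plus images — either TIFF files referenced by
the plate map or fields simulated in place — and executes
segment → detect → per-cell metrics → per-well screening, writing per-cell,
per-punctum and per-well CSV tables, a QC JSON, and a config snapshot so a
run is reproducible from its own outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detect import DetectionParams, detect_puncta, segment_cells
from .images import FluorImage, load_tiff
from .metrics import MetricsParams, quantify_field, summarize_sample
from .screening import screen_plate, torsel_signal
from .simulate import SimConfig, simulate_plate, validate_plate_map

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

#: CSV float formatting — fixed so reruns are byte-identical.
_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A named, actionable validation failure raised before any computation."""


@dataclass
class PipelineConfig:
    """Flat, human-editable configuration with one section per stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    hit_threshold: float = 0.30
    fields_per_well: int = 3
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.detection.validate()
        self.metrics.validate()
        if not (0.0 < self.hit_threshold <= 1.0):
            raise ValueError("hit_threshold must lie in (0, 1]")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "detection": self.detection.to_dict(),
            "metrics": self.metrics.to_dict(),
            "hit_threshold": self.hit_threshold,
            "fields_per_well": self.fields_per_well,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            sim=SimConfig.from_dict(d.get("sim", {})),
            detection=DetectionParams.from_dict(d.get("detection", {})),
            metrics=MetricsParams.from_dict(d.get("metrics", {})),
            hit_threshold=d.get("hit_threshold", 0.30),
            fields_per_well=d.get("fields_per_well", 3),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _resolve_images(
    plate_map: pd.DataFrame, image_dir: Path
) -> dict[str, list[Path]]:
    """Map well → image paths from the plate map's ``image`` column; every
    referenced file must exist (named error per well before any work)."""
    if "image" not in plate_map.columns:
        raise PipelineError(
            "plate map has no 'image' column; provide image references or simulate"
        )
    resolved: dict[str, list[Path]] = {}
    for row in plate_map.itertuples(index=False):
        paths = [image_dir / p.strip() for p in str(row.image).split(";") if p.strip()]
        if not paths:
            raise PipelineError(f"well {row.well_id}: no image referenced")
        for p in paths:
            if not p.is_file():
                raise PipelineError(f"well {row.well_id}: image not found: {p}")
        resolved[row.well_id] = paths
    return resolved


def _field_records(config: PipelineConfig, image: FluorImage):
    labels = segment_cells(image, config.detection)
    seg = detect_puncta(image, labels, config.detection)
    cells, puncta = quantify_field(image, seg, config.detection, config.metrics)
    signal = torsel_signal(seg, image)
    coverage = float((labels > 0).mean())
    return cells, puncta, signal, coverage


def run_pipeline(
    config: PipelineConfig,
    plate_map: pd.DataFrame,
    outdir: str | Path,
    *,
    image_dir: str | Path | None = None,
    simulate: bool = False,
) -> dict:
    """Execute the full plate workflow and write the output bundle.

    With ``simulate=True`` fields are generated from ``config.sim`` per the
    plate map's roles/effects; otherwise the plate map's ``image`` column
    names TIFFs under ``image_dir``. Outputs: cells.csv, puncta.csv,
    wells.csv, qc.json, config.yaml (snapshot). Returns a summary dict with
    the per-well table, QC and an exit status (0 ok, 2 on QC failure).
    """
    config.validate()
    try:
        validate_plate_map(plate_map)
    except ValueError as exc:
        raise PipelineError(str(exc)) from exc
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    all_cells: list[pd.DataFrame] = []
    all_puncta: list[pd.DataFrame] = []
    field_signals: dict[str, list[float]] = {w: [] for w in plate_map["well_id"]}
    qc_per_well: dict[str, dict] = {}

    if simulate:
        stream = simulate_plate(
            plate_map, config.sim, fields_per_well=config.fields_per_well
        )
        for well_id, field_id, image, _truth in stream:
            cells, puncta, signal, coverage = _field_records(config, image)
            all_cells.append(cells)
            all_puncta.append(puncta)
            field_signals[well_id].append(signal)
            qc_per_well.setdefault(well_id, {"n_cells": 0, "coverage": []})
            qc_per_well[well_id]["n_cells"] += int(len(cells))
            qc_per_well[well_id]["coverage"].append(coverage)
    else:
        images = _resolve_images(plate_map, Path(image_dir or "."))
        for row in plate_map.itertuples(index=False):
            for fi, path in enumerate(images[row.well_id], start=1):
                image = load_tiff(path, well_id=row.well_id, field_id=f"f{fi}")
                cells, puncta, signal, coverage = _field_records(config, image)
                all_cells.append(cells)
                all_puncta.append(puncta)
                field_signals[row.well_id].append(signal)
                qc_per_well.setdefault(row.well_id, {"n_cells": 0, "coverage": []})
                qc_per_well[row.well_id]["n_cells"] += int(len(cells))
                qc_per_well[row.well_id]["coverage"].append(coverage)

    # multi-field aggregation: unweighted mean of field-level ratios
    signals = []
    for row in plate_map.itertuples(index=False):
        vals = np.asarray(field_signals[row.well_id], dtype=float)
        finite = vals[np.isfinite(vals)]
        signals.append(float(np.mean(finite)) if finite.size else float("nan"))
    well_signals = pd.DataFrame(
        {
            "well_id": plate_map["well_id"].to_numpy(),
            "compound": plate_map.get("compound", pd.Series([""] * len(plate_map))),
            "role": plate_map["role"].to_numpy(),
            "signal": signals,
        }
    )
    wells, qc = screen_plate(well_signals, hit_threshold=config.hit_threshold)

    all_cells = [df for df in all_cells if len(df)]
    all_puncta = [df for df in all_puncta if len(df)]
    cells_df = (
        pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    )
    puncta_df = (
        pd.concat(all_puncta, ignore_index=True) if all_puncta else pd.DataFrame()
    )

    cells_path = outdir / "cells.csv"
    puncta_path = outdir / "puncta.csv"
    wells_path = outdir / "wells.csv"
    cells_df.to_csv(cells_path, index=False, float_format=_FLOAT_FMT)
    puncta_df.to_csv(puncta_path, index=False, float_format=_FLOAT_FMT)
    wells.to_csv(wells_path, index=False, float_format=_FLOAT_FMT)

    qc_payload = {
        "screen": qc.to_dict(),
        "hit_calling": {
            "reference": "percent_of_positive",
            "threshold_percent": 100.0 * config.hit_threshold,
            "note": (
                "hits are called on percent-of-positive-control; min-max scores "
                "are emitted in wells.csv for audit"
            ),
        },
        "wells": {
            w: {
                "n_cells": info["n_cells"],
                "mean_coverage": float(np.mean(info["coverage"])),
            }
            for w, info in sorted(qc_per_well.items())
        },
        "seed": config.seed,
    }
    (outdir / "qc.json").write_text(json.dumps(qc_payload, indent=2, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")

    status = 2 if (qc.warnings and not np.isfinite(qc.z_prime)) else 0
    return {"wells": wells, "qc": qc, "status": status, "outdir": outdir}
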