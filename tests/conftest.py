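import numpy as np
import pandas as pd
import pytest

from punctascreen.detect import DetectionParams, detect_puncta, segment_cells
from punctascreen.simulate import SimConfig, simulate_field


@pytest.fixture(scope="session")
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture(scope="session")
def noisefree_field():
    """One all-responder field rendered without noise."""
    cfg = SimConfig(seed=3, responder_fraction=1.0, shot_noise=False, read_noise_sd=0.0)
    return simulate_field(cfg)


@pytest.fixture(scope="session")
def noisy_field():
    """One all-responder field at the default camera-noise level."""
    cfg = SimConfig(seed=3, responder_fraction=1.0)
    return simulate_field(cfg)


@pytest.fixture(scope="session")
def segmented_noisy(noisy_field, default_params):
    image, truth = noisy_field
    labels = segment_cells(image, default_params)
    seg = detect_puncta(image, labels, default_params)
    return image, truth, seg


def match_cells(cell_label_map: np.ndarray, truth) -> dict[int, int]:
    """Map each detected cell label to the ground-truth label it overlaps most."""
    mapping = {}
    for det_lab in range(1, int(cell_label_map.max()) + 1):
        overlap = np.bincount(truth.cell_label_map[cell_label_map == det_lab])
        mapping[det_lab] = int(overlap.argmax())
    return mapping


def per_cell_counts(seg, truth) -> pd.DataFrame:
    """Detected vs true puncta count per matched cell."""
    mapping = match_cells(seg.cell_label_map, truth)
    det_counts = (
        seg.puncta.groupby("parent_cell").size() if len(seg.puncta) else pd.Series(dtype=int)
    )
    true_counts = truth.cells.set_index("label")["n_puncta"]
    rows = [
        {
            "detected_label": d,
            "true_label": t,
            "detected": int(det_counts.get(d, 0)),
            "true": int(true_counts.loc[t]) if t in true_counts.index else 0,
        }
        for d, t in mapping.items()
        if t > 0
    ]
    return pd.DataFrame(rows)
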