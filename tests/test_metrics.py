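"""Per-cell statistics: positivity, MFI, Dc, size distributions."""

import numpy as np
import pandas as pd
import pytest

from punctascreen.detect import DetectionParams, detect_puncta, segment_cells
from punctascreen.images import FluorImage
from punctascreen.metrics import (
    MetricsParams,
    classify_positive,
    compute_mfi,
    degree_of_clustering,
    percent_positive,
    puncta_size_distribution,
    quantify_field,
    summarize_sample,
)
from punctascreen.simulate import SimConfig, simulate_field


@pytest.mark.parametrize(
    "count,expected", [(11, True), (10, False), (0, False), (1000, True)]
)
def test_positivity_threshold_is_strict(count, expected):
    assert classify_positive(count) is expected


def test_positivity_threshold_is_configurable():
    assert classify_positive(4, threshold=3)
    assert not classify_positive(3, threshold=3)
    with pytest.raises(ValueError):
        classify_positive(-1)


def test_percent_positive_arithmetic():
    cells = pd.DataFrame({"positive": [True] * 35 + [False] * 15})
    assert percent_positive(cells) == pytest.approx(70.0)
    assert percent_positive(pd.DataFrame({"positive": [False] * 5})) == 0.0
    assert percent_positive(pd.DataFrame({"positive": [True] * 5})) == 100.0


def test_percent_positive_of_empty_sample_is_missing():
    assert np.isnan(percent_positive(pd.DataFrame({"positive": []})))


def test_mfi_is_background_subtracted_mean():
    px = np.full((40, 40), 20.0)
    px[10:20, 10:20] = 120.0
    img = FluorImage(pixels=px, bit_depth=16)
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:20, 10:20] = True
    assert compute_mfi(img, mask, background=20.0) == pytest.approx(100.0)
    assert compute_mfi(img, ~mask & (px == 20.0), background=20.0) == 0.0
    with pytest.raises(ValueError):
        compute_mfi(img, np.zeros_like(mask), background=0.0)


def test_dc_of_constructed_punctum_is_exact_ratio():
    px = np.full((60, 60), 100.0)
    cell = np.zeros((60, 60), dtype=bool)
    cell[10:50, 10:50] = True
    punctum = np.zeros_like(cell)
    punctum[28:33, 28:33] = True
    px[punctum] = 300.0
    img = FluorImage(pixels=px, bit_depth=16)
    dc = degree_of_clustering(img, cell, punctum, punctum)
    assert dc == pytest.approx(3.0)


def test_dc_of_uniform_cell_is_one():
    px = np.full((60, 60), 150.0)
    cell = np.zeros((60, 60), dtype=bool)
    cell[10:50, 10:50] = True
    punctum = np.zeros_like(cell)
    punctum[25:30, 25:30] = True
    dc = degree_of_clustering(FluorImage(pixels=px, bit_depth=16), cell, punctum, punctum)
    assert dc == pytest.approx(1.0)


def test_dc_undefined_when_punctum_fills_the_cell():
    px = np.full((30, 30), 100.0)
    cell = np.zeros((30, 30), dtype=bool)
    cell[10:20, 10:20] = True
    dc = degree_of_clustering(FluorImage(pixels=px, bit_depth=16), cell, cell, cell)
    assert np.isnan(dc)


def test_dc_recovery_on_noisefree_field(default_params):
    cfg = SimConfig(seed=41, responder_fraction=1.0, puncta_per_cell_range=(10, 30),
                    shot_noise=False, read_noise_sd=0.0)
    img, gt = simulate_field(cfg)
    labels = segment_cells(img, default_params)
    seg = detect_puncta(img, labels, default_params)
    _, puncta = quantify_field(img, seg)
    # match detections to truth by nearest centre
    from scipy.spatial import cKDTree

    tree = cKDTree(gt.puncta[["row", "col"]].to_numpy())
    d, idx = tree.query(puncta[["centroid_row", "centroid_col"]].to_numpy())
    rel = (puncta["dc"].to_numpy() - gt.puncta["dc"].to_numpy()[idx]) / gt.puncta[
        "dc"
    ].to_numpy()[idx]
    rel = rel[d <= 2.0]
    assert len(rel) >= 30
    assert abs(np.median(rel)) < 0.05
    assert np.quantile(np.abs(rel), 0.95) < 0.15


def test_puncta_size_distribution_summary():
    empty = puncta_size_distribution(pd.DataFrame({"area": []}))
    assert empty["areas"].size == 0 and np.isnan(empty["median"])
    d = puncta_size_distribution(pd.DataFrame({"area": [5, 9, 20]}))
    assert d["median"] == 9.0 and d["unit"] == "px^2"
    dm = puncta_size_distribution(pd.DataFrame({"area": [5, 9, 20]}), pixel_size=0.5)
    assert dm["median"] == pytest.approx(9 * 0.25) and dm["unit"] == "um^2"


def test_puncta_size_distribution_is_tight_for_fixed_spot_shape(segmented_noisy):
    _, _, seg = segmented_noisy
    areas = seg.puncta["area"].to_numpy(dtype=float)
    assert np.std(areas) / np.mean(areas) < 0.25


def test_percent_positive_invariant_to_intensity_rescaling(default_params):
    img, _ = simulate_field(SimConfig(seed=42, responder_fraction=0.6))
    scaled = FluorImage(pixels=np.clip(0.5 * img.pixels, 0, img.max_value),
                        bit_depth=img.bit_depth)
    out = []
    for im in (img, scaled):
        labels = segment_cells(im, default_params)
        seg = detect_puncta(im, labels, default_params)
        cells, _ = quantify_field(im, seg)
        out.append(percent_positive(cells))
    assert out[0] == pytest.approx(out[1])


def test_saturated_cells_carry_no_mfi_and_no_dc(default_params):
    cfg = SimConfig(seed=43, responder_fraction=1.0, puncta_per_cell_range=(12, 20))
    img, _ = simulate_field(cfg)
    px = img.pixels.copy()
    labels = segment_cells(img, default_params)
    sat_label = 1
    sel = labels == sat_label
    px[sel] = img.max_value  # saturate one whole cell
    img2 = FluorImage(pixels=px, bit_depth=img.bit_depth)
    labels2 = segment_cells(img2, default_params)
    seg = detect_puncta(img2, labels2, default_params)
    cells, puncta = quantify_field(img2, seg)
    sat = cells[cells["saturated"]]
    assert len(sat) >= 1
    assert sat["mfi"].isna().all()
    sat_puncta = puncta[puncta["parent_cell"].isin(sat["cell_id"])]
    assert sat_puncta["dc"].isna().all()
    unsat = cells[~cells["saturated"]]
    assert unsat["mfi"].notna().all()


def test_sample_summary_warns_on_small_samples(caplog):
    cells = pd.DataFrame(
        {"positive": [True, False], "saturated": [False, False], "mfi": [10.0, 12.0]}
    )
    puncta = pd.DataFrame({"area": [5, 6], "dc": [2.0, 3.0]})
    with caplog.at_level("WARNING"):
        summary = summarize_sample(cells, puncta, sample_id="s1")
    assert summary["n_cells"] == 2
    assert summary["percent_positive"] == pytest.approx(50.0)
    assert summary["mean_dc"] == pytest.approx(2.5)
    assert any("only 2 cells" in w for w in summary["warnings"])


def test_metrics_params_validation():
    with pytest.raises(ValueError):
        MetricsParams(positivity_threshold=-1).validate()
    with pytest.raises(ValueError):
        MetricsParams(annulus_width=0).validate()
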