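"""Detection contracts: segmentation quality, particle semantics, saturation."""

import numpy as np
import pandas as pd
import pytest

from punctascreen.detect import (
    DetectionParams,
    detect_puncta,
    flag_saturated_cells,
    segment_cells,
)
from punctascreen.images import FluorImage
from punctascreen.simulate import SimConfig, simulate_field

from conftest import match_cells, per_cell_counts


def _disk_image(shape=(160, 160), bg=20.0, disks=(), value=120.0):
    """Uniform background with uniform disks: (row, col, radius) triples."""
    img = np.full(shape, bg)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r0, c0, rad in disks:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = value
    return FluorImage(pixels=img, bit_depth=16)


def test_segmentation_recovers_cells_with_high_jaccard(default_params):
    n_found = 0
    for seed in (21, 22, 23, 24, 25):
        img, gt = simulate_field(SimConfig(seed=seed, responder_fraction=0.5))
        labels = segment_cells(img, default_params)
        assert labels.max() == len(gt.cells)
        mapping = match_cells(labels, gt)
        for det, true in mapping.items():
            assert true > 0
            a = labels == det
            b = gt.cell_label_map == true
            jaccard = (a & b).sum() / (a | b).sum()
            assert jaccard >= 0.8
            n_found += 1
    assert n_found >= 20


def test_blank_image_yields_empty_label_map(default_params):
    img = FluorImage(pixels=np.zeros((64, 64)), bit_depth=16)
    labels = segment_cells(img, default_params)
    assert labels.shape == (64, 64)
    assert labels.max() == 0


def test_border_cell_discarded_by_default():
    params = DetectionParams(min_cell_area=200, max_puncta_area=100)
    img = _disk_image(disks=[(80, 80, 18), (5, 40, 18)])  # second disk crosses border
    labels = segment_cells(img, params)
    assert labels.max() == 1
    labels_keep = segment_cells(
        img,
        DetectionParams(min_cell_area=200, max_puncta_area=100,
                        discard_border_cells=False),
    )
    assert labels_keep.max() == 2


def test_puncta_area_filter_excludes_out_of_window_particles():
    """Particles below min_puncta_area or above max_puncta_area are absent."""
    img = _disk_image(shape=(200, 200), disks=[(100, 100, 45)], value=100.0)
    px = img.pixels.copy()
    px[100 - 1 : 100 + 1, 70 - 1 : 70 + 1] += 300.0   # tiny spot
    px[95:105, 95:105] += 300.0                        # 10x10 plateau, large mask
    px[120 - 2 : 120 + 2, 120 - 2 : 120 + 2] += 300.0  # mid-size spot
    img = FluorImage(pixels=px, bit_depth=16)
    params = DetectionParams(min_cell_area=500, split_touching_puncta=False)
    labels = segment_cells(img, params)
    seg_all = detect_puncta(img, labels, params)
    areas = sorted(seg_all.puncta["area"])
    assert len(areas) == 3
    tight = DetectionParams(
        min_cell_area=500,
        split_touching_puncta=False,
        min_puncta_area=areas[0] + 1,
        max_puncta_area=areas[2] - 1,
    )
    seg = detect_puncta(img, labels, tight)
    assert list(seg.puncta["area"]) == [areas[1]]


def test_diffuse_cell_has_no_puncta(default_params):
    img = _disk_image(disks=[(80, 80, 30)])
    labels = segment_cells(img, default_params)
    assert labels.max() == 1
    seg = detect_puncta(img, labels, default_params)
    assert seg.n_puncta == 0


def test_noisefree_counts_exact(default_params):
    for seed in (31, 32):
        cfg = SimConfig(seed=seed, responder_fraction=1.0, shot_noise=False,
                        read_noise_sd=0.0)
        img, gt = simulate_field(cfg)
        labels = segment_cells(img, default_params)
        seg = detect_puncta(img, labels, default_params)
        counts = per_cell_counts(seg, gt)
        assert (counts["detected"] == counts["true"]).all()


def test_particle_measurements_equal_bruteforce_sums(segmented_noisy):
    """Areas and integrated intensities equal a naive per-label loop exactly."""
    image, _, seg = segmented_noisy
    lab = seg.puncta_label_map
    for row in seg.puncta.itertuples(index=False):
        sel = lab == row.label
        assert int(sel.sum()) == row.area
        assert image.pixels[sel].sum() == pytest.approx(row.integrated_intensity, rel=1e-12)
        assert image.pixels[sel].max() == row.max_intensity
    # every punctum has exactly one parent cell and lies inside it
    assert ((lab > 0) <= (seg.cell_label_map > 0)).all()
    for row in seg.puncta.itertuples(index=False):
        parents = np.unique(seg.cell_label_map[lab == row.label])
        assert list(parents) == [row.parent_cell]


def test_detection_invariant_to_constant_offset(default_params):
    img, gt = simulate_field(SimConfig(seed=33, responder_fraction=1.0))
    shifted = FluorImage(pixels=np.clip(img.pixels + 500.0, 0, img.max_value),
                         bit_depth=img.bit_depth)
    seg_a = detect_puncta(img, segment_cells(img, default_params), default_params)
    seg_b = detect_puncta(shifted, segment_cells(shifted, default_params), default_params)
    counts_a = seg_a.puncta.groupby("parent_cell").size().to_numpy()
    counts_b = seg_b.puncta.groupby("parent_cell").size().to_numpy()
    assert np.array_equal(counts_a, counts_b)


def test_saturation_flag_is_strict_at_the_boundary():
    params = DetectionParams(saturation_fraction_max=0.01)
    labels = np.zeros((50, 80), dtype=np.int32)
    labels[10:30, 10:30] = 1   # area 400 -> boundary at 4 saturated px
    labels[10:30, 50:70] = 2
    px = np.full((50, 80), 100.0)
    px[10:30, 10:30][0, :4] = 65535.0   # exactly the boundary fraction
    px[10:30, 50:70][0, :5] = 65535.0   # one above
    img = FluorImage(pixels=px, bit_depth=16)
    flags = flag_saturated_cells(img, labels, params).set_index("label")
    assert not flags.loc[1, "saturated"]
    assert flags.loc[2, "saturated"]
    all_sat = FluorImage(pixels=np.where(labels == 1, 65535.0, 0.0), bit_depth=16)
    f2 = flag_saturated_cells(all_sat, (labels == 1).astype(np.int32), params)
    assert f2.set_index("label").loc[1, "saturated"]


def test_param_invariants_enforced():
    with pytest.raises(ValueError):
        DetectionParams(min_puncta_area=0).validate()
    with pytest.raises(ValueError):
        DetectionParams(min_cell_area=100, max_puncta_area=400).validate()
    with pytest.raises(ValueError):
        DetectionParams(cell_threshold_method="fixed").validate()


def test_misaligned_label_map_rejected(default_params):
    img = FluorImage(pixels=np.zeros((32, 32)), bit_depth=16)
    with pytest.raises(ValueError, match="aligned"):
        detect_puncta(img, np.zeros((16, 16), dtype=np.int32), default_params)
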