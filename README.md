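# punctascreen

Quantification and high-content-screening statistics for live-cell
**puncta reporters** — fluorescent biosensors (such as the TORSEL mTORC1
sensor) that switch from a diffuse cytosolic pattern to discrete bright
puncta when their target pathway is inhibited. The package is for
image-analysis and screening scientists who need the full readout chain of
such an assay as tested, scriptable code rather than an ad-hoc ImageJ
workflow: detect puncta in single-channel fluorescence images, compute
per-cell and per-well statistics, grade a screen, call hits, and fit
dose/time responses.

## What it computes

Per cell and per sample:

- puncta count and **positivity** (a cell is positive iff it holds **> 10**
  puncta), percent-positive over ~50 cells;
- **MFI**, the mean background-subtracted fluorescence of the cell, with
  saturated cells excluded;
- **degree of clustering** Dc = punctum intensity / nearby cytosol
  intensity (an annulus around the punctum);
- puncta-size distributions (median, IQR).

Per well and per plate:

- the reporter signal
  `TORSEL signal = Σ puncta pixel intensity / Σ cell pixel intensity ∈ [0, 1]`;
- min–max normalized scores, percent-of-positive-control, and **hit calls**
  at ≥ 30% of the mean positive control;
- assay quality as the **Z′ factor**,
  `Z′ = 1 − 3(σp + σn)/|µp − µn|`,
  from positive (e.g. Torin1) and negative (DMSO) control wells.

Response analysis:

- **four-parameter logistic** fits,
  `y = bottom + (top − bottom)/(1 + (x/midpoint)^hill)`,
  reporting IC50 (dose) or t1/2 (time) with standard errors and
  diagnostics, in a model/results idiom (`FourParamLogistic(...).fit()` →
  `ResponseFit` with `.summary()`);
- **FRAP** recovery normalization to the mean pre-bleach intensity;
- **ΔΔCt** qPCR fold changes (`2^−ΔΔCt`).

Because assays of this kind rarely deposit raw microscopy, the package
ships a first-class synthetic-field generator (`punctascreen.simulate`)
with exact per-cell/per-punctum ground truth, emulating the assay's
regimes: 70–90% responder fractions, 10–100 puncta per responding cell,
Dc in 2–4×, three expression tiers, Poisson + read noise. Every stage is
validated against it; see `docs/methods.md` for the model and its limits.

## Worked example

```python
from punctascreen import (SimConfig, simulate_field, DetectionParams,
                          segment_cells, detect_puncta, quantify_field,
                          torsel_signal)

cfg = SimConfig(seed=7, responder_fraction=0.8)   # positive-control regime
image, truth = simulate_field(cfg)

params = DetectionParams()
labels = segment_cells(image, params)
seg = detect_puncta(image, labels, params)
cells, puncta = quantify_field(image, seg)
print(cells[["cell_id", "area", "mfi", "puncta_count", "positive"]])
print(f"signal {torsel_signal(seg, image):.4f}")
```

```
 cell_id   area       mfi  puncta_count  positive
       1  13552  50.52500            70      True
       2  15922  61.87766            91      True
       3  16523  92.26378            49      True
       4  15942  52.28716            48      True
signal 0.1384
```

All four simulated cells responded (48–91 puncta, well above the
10-puncta positivity threshold), their background-subtracted MFIs sit in
the "medium" expression tier, and ~14% of the total cell fluorescence is
concentrated in puncta — a strong positive-control field. In this field
the detected counts equal the generator's ground truth exactly, and the
mean measured Dc is 3.03 against a simulated range of 2–4.

A dose–response fit:

```python
from punctascreen import FourParamLogistic
res = FourParamLogistic(doses_nM, percent_positive_values).fit()
print(res.summary())        # bottom/top/midpoint/hill with std errors
res.midpoint                # IC50 in the dose units
```

The command line mirrors the library:
`punctascreen simulate|quantify|screen|fit|frap` (see `--help`); `screen`
takes a plate-map CSV (well, compound, dose, role, image paths) and writes
`wells.csv` plus a `qc.json` with Z′, control statistics and per-well
warnings.

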