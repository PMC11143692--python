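# Methods

`punctascreen` quantifies live-cell assays in which a fluorescent reporter
converts from a diffuse cytosolic pattern to discrete puncta when a kinase
(here, mTORC1) is inhibited. This note records the models the package
implements, the synthetic data it is validated on, and the numerical and
design choices a maintainer would want to know about.

## The assay model

A field contains cells expressing the reporter at some level (its mean
fluorescence intensity, MFI). Upon pathway inhibition a *responding* cell
develops tens of bright puncta; non-responding cells stay diffuse. The
package computes, per the assay's conventions:

- **Puncta count and positivity.** A cell is reporter-positive iff it holds
  strictly more than `positivity_threshold` puncta (default 10, the
  threshold that separates background speckles from genuine responses).
  Percent-positive per sample is computed over ~50 cells.
- **MFI.** Mean of (pixel − background) over the cell mask, background being
  the median of non-cell pixels of the field; cells whose saturated-pixel
  fraction exceeds `saturation_fraction_max` (default 0.1%) carry no MFI.
- **Degree of clustering (Dc).** Per punctum, the ratio of
  background-subtracted punctum intensity to the median background-subtracted
  intensity of the nearby cytosol — an annulus 3 px wide around the punctum,
  inside the parent cell, excluding all puncta pixels. Inhibited cells sit
  in the 2–4× range.
- **Well-level signal.** `torsel_signal` = Σ(puncta pixel intensity) /
  Σ(cell pixel intensity) per field; wells average their fields' ratios.
  Since puncta pixels are a subset of cell pixels the ratio lies in [0, 1].
- **Plate statistics.** Min–max normalization of well signals to [0, 1];
  percent-of-positive-control normalization; hit calling at ≥ 30% of the
  mean positive control (inclusive boundary); assay quality as the Z′
  factor, 1 − 3(σp + σn)/|µp − µn| with sample standard deviations.
- **Response curves.** Four-parameter logistic
  y = bottom + (top − bottom)/(1 + (x/midpoint)^hill), fitted by unweighted
  least squares; the midpoint is reported as IC50 for dose data (fitted on a
  log10 axis) or t1/2 for time data (linear axis).
- **FRAP.** Recovery traces are divided by their mean pre-bleach intensity,
  so the pre-bleach segment has mean exactly 1.
- **qPCR.** Relative expression by ΔΔCt: fold change = 2^(−ΔΔCt) against a
  reference gene and control condition, computed from replicate means.

## Synthetic fields and what they do (not) capture

No raw microscopy accompanies the assay, so every stage is validated on a
seeded generator (`punctascreen.simulate`) whose defaults encode the
positive-control regime: ~80% responder cells, 10–100 puncta per responding
cell, per-punctum contrast (Dc) uniform in [2, 4], and expression tiers with
MFI 19.6 ± 11.22 (low), 74.08 ± 18.5 (medium, default) or 148.24 ± 22.18
(high). Camera noise is the standard model — Poisson shot noise on the
expectation image plus Gaussian read noise (default sd 4) — on a 16-bit
range above a flat offset (default 100).

Rendering choices that matter:

- **Cells** are randomly oriented ellipses with a smoothstep edge
  (half-width 2 px), placed on a shuffled, jittered slot grid that
  guarantees non-overlap with a minimum gap. A field that cannot host the
  requested cells raises `GenerationError` rather than silently truncating.
  Cells default to radii 62–72 px so a single cell can host 100
  well-separated puncta; a 512×512 field then holds 4 cells, and ~50-cell
  samples pool several fields.
- **Puncta** are flat-core spots (core radius 1.8 px) with a Gaussian edge
  (σ 0.7 px), placed on a jittered grid inside the cell with ≥ ~7 px centre
  separation and a ~9 px margin from the cell edge. The plateau amplitude is
  set from the drawn target Dc and the cell's cytosol level,
  a = (Dc − 1)·c, which makes ground-truth Dc = (a + c)/c exact by
  construction *and* recoverable by an intensity-ratio estimator. A pure
  Gaussian profile was rejected: its mean over any detection mask is far
  below the peak, so no mean-based Dc estimator could be unbiased for it.
- **Ground truth** records every cell (label map, cytosol level, responder
  flag, puncta count, border flag) and every punctum (centre, amplitude,
  Dc).

What the generator does **not** emulate: optics-accurate PSFs, 3D structure,
touching or overlapping cells, intracellular cytosol texture, photobleaching,
uneven illumination, or dense puncta clustering beyond the grid spacing.
Passing tests therefore demonstrate correctness of the *quantification*
given imaging that matches these idealizations; they do not certify
segmentation performance on confluent or textured real-world fields. The
`low` expression tier is truncated at intensity 2, which biases its realized
mean upward by ~7%; the medium and high tiers are effectively untruncated.

## Detection operators

- **Cell segmentation**: Gaussian smooth (σ 2) → global threshold → fill
  holes → drop objects < `min_cell_area` → optional watershed split →
  border-touching cells discarded by default. The default threshold comes
  from background statistics (global median + max(k·MAD, 2% of the median)
  of the smoothed image), which assumes background is the majority class.
  Otsu is available but *not* the default: when expression varies ~10-fold
  between cells, Otsu's two-class split cuts dim cells out of the
  foreground.
- **Puncta detection**: difference-of-Gaussians band-pass (σ 1.2/2.4),
  thresholded per cell at `median + max(k·noise_sd, 0.2·cytosol)`, where
  `noise_sd` is the robust sd of the band-pass response over background
  pixels (in-cell spread estimates are corrupted by the spots themselves and
  their negative DoG lobes) and the cytosol level is the background-
  subtracted median over the eroded cell interior. Both terms scale with the
  image, so detection is invariant to intensity offsets and positive
  rescaling, up to clipping. Connected components (8-connectivity) within
  [`min_puncta_area`, `max_puncta_area`] = [4, 400] px become particles;
  components holding several band-pass maxima are watershed-split (the
  standard companion step to particle analysis on dense fields — without it,
  touching particles merge and counts saturate below ~100/cell). Particles
  whose response peak lies within 7 px of the cell boundary are rejected:
  the cell's own edge ramp has a band-pass response (~0.13× cytosol) that
  would otherwise seed spurious arcs of "puncta".
- **Dc estimator**: numerator = mean of the punctum's bright core, the
  pixels above baseline + 0.85·(peak − baseline) with peak the 95th
  percentile of punctum pixels and baseline the annulus median. The full
  detected mask includes the dim skirt of each spot; averaging over it
  understates the contrast by 10–20%, while the bright-core mean is nearly
  unbiased (held-out median bias −1.7%, 95% of puncta within 11% of truth
  at default noise). The (0.85, P95) pair was calibrated once on synthetic
  fields at the default noise level.

## Numerical choices

- 4PL fitting parameterizes the midpoint as log10(midpoint) (positivity by
  construction) and initializes bottom/top from the data extremes, midpoint
  from the x nearest mid-response, and the hill sign from the overall trend.
  Results are canonicalized to bottom ≤ top (flipping the hill sign, which
  leaves the curve unchanged). Non-convergence is flagged on the results
  object and propagates as a missing IC50/t1/2, never a silent number.
- Standard errors come from the Gauss–Newton approximation
  (JᵀJ)⁻¹·residual_variance; the midpoint's error is delta-method-scaled
  from the log axis.
- The simulated dose series used for validation follow the standard IC50
  plate design: 8-point 3-fold serial dilution centred on the true midpoint,
  triplicates, multiplicative Gaussian noise with 5% CV (replicate scatter
  in fluorescence-derived readouts scales with the signal), slope magnitude
  1.5. Midpoint recovery is sensitive to these conditions: with additive
  5%-of-range noise and slope 1, the all-free 4PL is information-limited to
  ~8–10% median midpoint error however the doses are placed.
- Min–max normalization refuses constant input (undefined) rather than
  dividing by zero; Z′ refuses equal control means and fewer than two wells
  per arm; percent-positive of an empty sample is NaN ("missing"), never 0.
- Hit calling uses the percent-of-positive-control convention with an
  inclusive ≥ 30% boundary; min–max scores are emitted alongside for audit,
  and the QC JSON records which convention called the hits.

## Problem sizes

The validation suite and `scripts/acceptance.py` run everything at desk
scale, chosen as the package's own study conditions: 512×512 fields with 4
large cells (count regimes) or 9 smaller cells (plate regimes, 12–22
puncta/cell), ~50 cells per positivity sample, a 96-well plate with 8
positive controls, 8 negative controls, 20 true responders and 60 nulls at
3 fields/well, and 200 replicate dose series. At ~27 cells per well the
plate's Z′ lands around 0.5–0.7 — the well-to-well spread is dominated by
binomial responder sampling, so Z′ improves with cells per well and the
original assay's larger per-well cell counts plausibly support its higher
reported quality. Hit sensitivity and specificity are 1.0 at these sizes.

## Known limitations

- Segmentation assumes non-touching cells; `split_touching` exists but is
  untuned for confluent layers.
- The saturation criterion (fraction of pixels at the bit-depth maximum)
  follows standard practice; the original workflow's exclusion criterion is
  unspecified.
- Whether puncta "size" should be area or diameter, px or µm, is left as
  area in px² (µm² when a pixel size is provided).
- ΔΔCt assumes perfect amplification efficiency (plain 2^−ΔΔCt), no
  efficiency correction.
- The automated pipeline replaces the original manual review of hits with a
  deterministic QC report (per-well cell counts, segmentation coverage,
  Z′, per-well warnings).
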