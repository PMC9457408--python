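# Methods

This note documents the models, estimators and numerical choices behind
`cycleprof`, what the synthetic generator does and does not emulate, and
the known limitations.

## Population model

An asynchronous steady-state culture is modelled by the stationary age
density of an exponentially growing population, `φ(a) = 2 ln2 · 2^(−a)`
for age `a ∈ [0, 1]` doubling times: newborn cells are twice as frequent
as cells about to divide. Cycle position is identified with age. Length
follows a piecewise-linear tip-growth map: birth length `L_b = 7 µm` to
mitotic-entry length `L_m = 12 µm` over the G2 window `[0, 0.75]`, then
`L_m` to division length `L_d = 14 µm = 2·L_b` over `[0.75, 1]`. With the
default anchors the post-entry segment is slightly *faster* than G2 growth
(8 vs 6.7 µm/cycle); a literal growth plateau after mitotic entry is
incompatible with division at `2·L_b` once the stage windows are fixed, so
the map trades the plateau for the printed length anchors. The closed-form
length CDF (age CDF pushed through the growth map) is exposed as
`length_cdf` and is the oracle for the sampling tests.

Stage windows are fractions of the cycle: mitosis from 0.75, binucleate
from 0.85, septated from 0.92. These are calibration choices (such
fractions are not printed anywhere authoritative); they put ~5% of an
asynchronous population in the binucleate state and give septated cells
lengths above `L_m`, consistent with the anchors "<8 µm early G2, 8–12 µm
mid-G2 to mitotic entry, >12 µm mitosis".

## Concentration models

`StrainProfileModel` encodes whole-cell concentration `c(p)` versus cycle
position and a nuclear enrichment function `e(p)` (nuclear = `e·c`):

* `CONSTANT` — `c = baseline`; the null used for artifact bounds.
* `LINEAR_ACCUMULATOR` — linear from `baseline` to `baseline·fold` over
  the full cycle (endpoint ratio exactly `fold`). The cdc13-like preset
  additionally sets `division_reset`: anaphase proteolysis holds the peak
  through the first half of the binucleate window, then decays to baseline
  by septation, so newly split halves re-enter the short bins at baseline.
  Degradation is fast relative to the window, hence hold-then-decay rather
  than a linear ramp across the whole window.
* `OSCILLATOR` — piecewise linear from `baseline·fold` at birth down to
  `baseline` at `trough_position` (default 1/3) and back to
  `baseline·fold` at mitosis. Starting at the peak keeps concentration
  continuous across division.
* `G1S_PULSE` — peak at position 0 decaying linearly to baseline by
  mid-G2, re-induced during the septated window (G1/S transcription occurs
  in septated cells), again continuous across division and monotone
  non-increasing through G2.
* `NUCLEAR_RAMP` — constant whole-cell level with rising `e(p)` (the
  cdc2-like preset ramps enrichment 1.3→2.2); during mitosis enrichment
  collapses to 1 (nuclear export at envelope remodelling), a deliberate
  simplification.

Per-cell expression variability is a lognormal factor with unit mean and
CV 0.15 applied to both concentrations. It represents extrinsic expression
noise (single-cell dot plots of real populations show scatter of this
order) and matters structurally: without it the within-bin intensity law
is uniform-with-sharp-edges — the least favourable unimodal null — and any
calibrated bimodality detector fires at its nominal rate on perfectly
well-behaved bins.

## Rendering and noise

Cells are rods (rectangle plus semicircular caps, width 4 µm) rendered at
0.1 µm/px; nuclei are disks totalling 15% of the projected cell area (one
disk in mononucleates, two half-area disks otherwise). The protein channel
conserves mass: the nucleus is drawn at `e·c` and the cytoplasm at
`(c·A − e·c·A_n)/(A − A_n)` with rasterised areas, so the noise-free
channel sums to `c · cell area` exactly and the whole-cell mean *is* the
whole-cell concentration. (Enrichment relocates protein; it does not
create it. This also reproduces the observation that a constant
whole-cell signal can coexist with a rising nuclear one.) Enrichment is
capped by `e · area fraction < 1`.

The bright-field proxy is a dark interior (40) on a bright background
(100) with a 1 px Gaussian edge; septa add a +20 transverse band, kept
below the Otsu threshold so the cell segments as one object while the
septum remains detectable as an on-axis intensity peak.

Noise, in order: uniform in-cell autofluorescence `b0 + b1·L` per pixel
(defaults 2 + 0.5·L — the linear-in-length mean background an untagged
control exhibits), scattered cell-to-cell by a unit-mean lognormal factor
(CV 0.1; real control distributions are never delta functions, and
without this spread the synthetic control's bin SEs shrink to ~0.05% of
the mean, far below anything an instrument achieves), Poisson shot noise
on the fluorescence channels,
additive Gaussian read noise (sd 2) on all channels, clipped at zero. An
optional Gaussian PSF (σ = 0.12 µm) blurs the fluorescence channels at
render time. All draws flow from one seeded generator; identical seeds
give byte-identical populations and tiles.

Not emulated: 3D/z-stacks, optical aberrations beyond the Gaussian PSF,
photobleaching, touching cells, segmentation-error modes of real
instruments (debris, doublets, focus drift). Consequently the gates pass
nearly everything here — their tests verify the gate logic and the
sequential-attrition bookkeeping, not rejection rates on real debris — and
passing batteries demonstrate correctness of the measurement chain, not
robustness to real-world image pathology.

## Measurement choices

* **Eroded mask**: intensity statistics (total/mean/max/top-p%) use the
  3 px-eroded mask, matching flow-cytometry practice; length and shape
  features use the uneroded mask. The top-15% statistic uses the eroded
  mask too (the choice is not documented anywhere authoritative; erosion
  keeps the two intensity paths consistent).
* **Length**: principal-axis extent of the mask in the bulk pipeline; the
  medial line (skeleton, pruned, ordered tip-to-tip, end-tangents extended
  to the boundary, sub-sampled polyline arc length) defines length in the
  nucleus-counting path and agrees with the extent within ~1 px for rods;
  rotation changes it by <2%.
* **Medial-line nucleus counting**: peaks of the (5 px-smoothed) marker
  profile above `median + 3·MAD`, separated by ≥1.5 µm, with an additional
  relative-prominence gate of 0.3× the profile's dynamic range. The
  prominence gate is required because a nuclear plateau (~28 px) is wider
  than the separation (15 px), so plateau shot noise would otherwise split
  one nucleus in two. More than two qualifying peaks flags the record
  ambiguous.
* **Septum splitting**: per-column mean bright-field profile inside the
  mask; a candidate column must exceed `median + max(3·1.4826·MAD, 5)`
  within the central 50% of the axis; the qualifying column nearest
  mid-length is the cut (±1 px). The absolute floor of 5 intensity units
  (a quarter of the septum contrast) keeps read noise from triggering
  splits. Children below a minimum area suppress the split. Splitting
  happens *before* background correction, so the length covariate of a
  split half is its own length — see the caveat under background.
* **Shape/focus gate features**: width = median transverse chord,
  thickness max = largest chord, thickness min = smallest chord over the
  central 60% of the axis (the raw minimum is one pixel at the cap tips),
  focus score = RMS bright-field gradient in a ±2 px boundary band times a
  fixed calibration constant chosen once so an in-focus synthetic cell
  scores ≈70, mid-range of the default 65–78 gate. These are emulations
  of instrument features, labelled as such; a mean-chord width definition
  was rejected because a capped 4 µm rod has mean chord 3.5–3.75 µm and
  would fail the default width gate by construction.
* **Background**: per-feature OLS of control bin means on bin centres
  (0.33 µm bins). Mean-like features (top-p%, nuclear means) are corrected
  with the mean-intensity model, since uniform autofluorescence shifts
  every pixel equally. Negative corrected values are floored at zero and
  flagged; `floor=False` keeps signed residuals for control validation
  (flooring biases a zero-mean residual upward by ~0.4σ, so a floored
  control can never average to zero). Caveat: split halves carry
  autofluorescence laid down at the parent's length, so a split-first
  control biases the fitted slope; the default pipeline accepts the
  resulting <1.05× residual artifact (well inside the 1.1–1.3× artifact
  bound for constant proteins), while the calibration battery fits the
  control unsplit.
* **R5 extremes**: trimming outside the [0.1%, 99.9%] intensity quantiles
  of the R1–R4 survivors, per strain (no authoritative numbers exist).
* **95% CIs**: normal approximation `mean ± 1.96·SE`; bins have ≥10 cells
  wherever CIs are drawn.
* **Bimodality stop**: Hartigan-style dip statistic per retained bin
  (≥30 cells), scanning upward in length; the first flagged bin truncates
  the means and the fold change. The statistic is computed by the
  iterative convex-minorant/concave-majorant construction and returns half
  the maximal hull deviation (floor `1/(2n)`); its null is calibrated by
  seeded Monte Carlo on the uniform law — the asymptotically least
  favourable unimodal null — simulated once at a reference size and
  rescaled by `n^(−1/2)`. On Gaussian-like bins the test is conservative
  (empirical rejection ≪ 5%). A 2-component GMM/BIC detector (with an
  Ashman-D separation check) is available behind config.

## Derivative analysis

The 2D density over (length, intensity) uses a Gaussian product kernel on
a 256×256 grid spanning the data padded by 3 bandwidths, computed by
binned convolution and renormalised to integrate to 1. Automatic
bandwidths are per-axis Scott/Silverman (`σ·n^(−1/6)`) by default; a
Botev-style diffusion fixed-point selector is available behind config
(falling back to Silverman if the fixed point has no root in the bracket).
The ridge takes each length column's argmax with quadratic sub-cell
refinement; columns below 1% of the global density maximum, or within 2
length-bandwidths of the data extremes (where kernel estimates are
boundary-biased and the ridge flattens), are masked. Smoothing is a
centred moving average (default window 7; NaN propagates); `dI/dL` uses
centred differences on the uniform grid, one-sided at the edges.

Because neighbouring grid columns share kernel support, grid-scale
`dI/dL` is noise-dominated at desk-scale n; `ridge_rate` therefore also
reports the rate from each 1 µm length station to the next (interpolated
from the smoothed ridge), which is the scale at which accumulation
regimes are classified: a linear nuclear accumulator gives station rates
with CV < 0.15, an exponential one strictly increasing rates over the
upper half-range. The regime batteries use n = 20,000 cells per model and
G2 mononucleates only — mitotic nuclear export would otherwise fold the
end-of-cycle collapse into the upper half-range, which is a different
biological signal than the accumulation regime under test. The "/cell
length (µm)" in rate-plot axis labels is read as the derivative's
denominator; a secondary `dIdL_over_L` column is emitted for the
alternative reading.

## Problem sizes

The batteries run at: 10 × 20,000 cells (+ one 20,000-cell control) for
the constant-strain artifact panel; 20,000 cells per preset for profile
recovery; 1,000 tiles per stage for nucleus counting; 20,000 cells per
model for the derivative regimes; 10,000 cells for background recovery;
1,000 noise-free tiles for geometry. These sizes give every retained
0.33 µm bin ≥500 cells while keeping a full run in the tens of minutes on
a single core.

## Known limitations

* The generator's stage windows, enrichment ramps and expression CV are
  calibration choices, not fits to data; absolute intensities are
  arbitrary units throughout.
* Septum detection assumes near-axis-aligned single-cell tiles (as the
  per-tile generator produces); chord-based shape features likewise.
* The dip statistic is this package's construction of Hartigan's
  statistic; it matches the canonical values on the anchor cases
  (equally spaced → `1/(2n)`; two point masses → 0.25) but is validated by
  its own Monte Carlo calibration rather than against published tables.
* `fold_change` on a finite population underestimates a model's endpoint
  fold whenever the extreme bins are dropped by the min-count rule or
  blurred by stage mixing; recovery is within ±15% at n = 20,000, not
  exact.
* Background correction assumes the control matches the tagged strain in
  geometry and stage structure; a mismatched control leaves a linear
  residual that the artifact panel would reveal.
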