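# Methods

## The problem

Perinatal hypoxia-ischemia (H-I) injures the cerebral white matter of the
preterm brain across a wide spectrum: most injury today is diffuse,
non-necrotic gliosis, with only scattered microscopic necrosis. The classical
readout — an ordinal 0–4 necrosis score assigned by a pathologist from H&E
sections — is blind to the diffuse end of this spectrum. `gliaquant`
implements a continuous alternative: the fraction of a white-matter region of
interest (ROI) whose pixels are labeled by GFAP (astrocytes) or Iba1
(microglia) immunofluorescence, estimated without any operator-chosen
threshold, and embeds it in a fully synthetic but quantitatively calibrated
fetal-sheep H-I study so every stage can be tested against known ground
truth.

## Stained-area-fraction estimation by histogram reflection

For each section, a pixel-intensity histogram is computed over the ROI with
one bin per integer intensity level (256 bins at 8-bit). The estimator then:

1. **Locates the background peak** from the three highest-frequency bins:
   the adjacent bin triplet with the greatest total count (the window
   `c[i-1] + c[i] + c[i+1]` maximized over centers `i`, ties toward lower
   intensity), summarized by the count-weighted centroid of those three
   bins. Requiring adjacency anchors the peak on the dense, narrow
   background mode; an isolated bright bin — however tall — cannot capture
   it.
2. **Integrates the background side** (low-intensity side, since
   fluorescence background is darker than specific staining) of the peak:
   counts strictly below the peak bin are summed. The fractional centroid is
   mapped to its peak bin by rounding half toward the background side.
3. **Doubles** that sum, exploiting the approximate symmetry of the
   background mode about its peak, and adds the peak bin once. Counting the
   peak bin once (rather than doubling it too) avoids double-counting the
   mode; for a perfectly symmetric background-only histogram the estimate
   equals the ROI pixel count exactly.
4. **Subtracts** the doubled background count from the ROI pixel count; the
   remainder is the labeled area. The background count is clamped to the ROI
   total and the fraction floored at zero (both events are flagged).

Per-animal outcomes average the triplicate section fractions. Degenerate
histograms (fewer than three nonzero bins) return fraction 0 with a warning
flag rather than a fabricated estimate.

The estimator assumes (a) a symmetric, unimodal background intensity
distribution and (b) that the background mode is locally denser than any
stained-intensity neighborhood. Assumption (b) bounds the estimable range:
a section with essentially no unstained pixels has no background mode to
find. This is why the cohort simulator caps stained fractions at 0.92 (see
below).

## Synthetic section images

Sections are rendered as single-channel 8-bit frames (default 512×512,
full-frame ROI; arbitrary ROI masks supported). Background pixels are drawn
from a truncated Gaussian N(30, 1.2²); labeled pixels from N(160, 30²),
clipped to the bit range. Distributions whose theoretical tail mass beyond
the bit range exceeds 0.1% are rejected rather than silently distorted. The
narrow background versus broad signal mirrors real epifluorescence montages,
where unstained tissue is nearly uniformly dark while staining intensity
varies widely — and it is exactly the regime in which the histogram
estimator is identifiable up to high stained fractions (the background
triplet outweighs signal bins up to fractions ≈ 0.94 at these defaults).

Labeled pixels are laid down as overlapping random disk stamps (radius 5)
so lesions are blob-like, but bookkeeping is per pixel: exactly
`round(true_fraction · |ROI|)` pixels are signal-drawn and recorded in a
ground-truth mask, with the final stamp trimmed to land on the exact count.
Per-section true fractions are the animal's fraction plus Gaussian jitter
(SD 0.02), representing section-to-section variability behind the
triplicate averaging. What the generator does **not** emulate: optics
(point-spread function), montage stitching seams, multichannel
counterstains, uneven illumination, or spatially correlated background.
Passing recovery tests therefore demonstrates correctness of the estimator
under its own assumptions, not robustness to acquisition artifacts.

## The simulated cohort

A cohort holds 17 H-I fetuses (10 euthanized at 1 week, 7 at 2 weeks) and
17 twin controls. Epoch physiology (baseline, hypoxia, hypoxia-ischemia,
recovery) is drawn around the published means and SDs. Design choices where
the published record is open:

- **Joint H-I block.** (BP, CaO2, glucose, lactate) at the H-I epoch are
  multivariate normal with correlations `sign·sqrt(r²)` from the published
  pairwise values (lactate–CaO2 −0.86, glucose–CaO2 +0.55,
  glucose–lactate −0.55). The BP pairs are not published; defaults
  (+0.35, +0.20, −0.25 against CaO2/glucose/lactate) encode that
  hypotension accompanies hypoxemia and metabolic stress. The matrix is
  positive definite as-is; were it not, it is projected to the nearest
  correlation matrix, failing loudly if the projection moves any target by
  more than 0.05.
- **Oxygen content.** CaO2 = 1.34·Hb·SatO2/100 + 0.003·PO2. The published
  H-I triplet (Hb 10.4, SatO2 45.4, PO2 19.3) is internally inconsistent
  with this identity by ~6% (analyzer-reported values). Because CaO2 enters
  the correlation targets, the simulator draws CaO2 directly and derives
  SatO2, so the identity holds exactly; simulated H-I SatO2 means ≈ 42.6
  rather than 45.4.
- **Latent severity.** Injury severity is the standardized decreasing
  composite `s = −(w·z)/‖w‖_R` of the H-I z-scores of (BP, CaO2, glucose),
  glucose-dominated. Each marker's fraction is `clip((a + b·s)·ε, 0, 0.92)`
  with unit-mean lognormal noise ε — multiplicative noise because the
  published H-I GFAP SD equals its mean (0.40 ± 0.40), implying strong
  right skew. Weights and link parameters were calibrated once (simulated
  annealing-free Nelder–Mead on common random numbers) so that the
  *replicate-mean, week-adjusted, n = 17 sample* r² profile — not the
  population ρ² — reproduces the published values (GFAP:
  0.499/0.21/0.15 for glucose/CaO2/BP; Iba1: 0.298/0.08/0.057). Frozen
  defaults: GFAP w = (0.284, −0.042, 1), a = 0.4254, b = 0.2369,
  σ = 0.5019; Iba1 w = (−0.081, −0.334, 1), a = 0.3325, b = 0.1021,
  σ = 0.4372. Two consequences are worth stating plainly. First, at n = 17
  with a survival-week covariate the *null* expectation of the sample r² is
  1/(n−2) ≈ 0.067, so the Iba1–BP target of 0.057 lies below the reachable
  floor; the calibrated value settles at ≈ 0.067, inside the ±0.05
  acceptance band. Second, Iba1's published CaO2 r² (0.08) is smaller than
  the value its glucose correlation alone would induce through the
  glucose–CaO2 correlation; matching it requires a negative direct CaO2
  weight in the Iba1 composite — the *net* CaO2–Iba1 association remains
  negative, as published.
- **Fraction ceiling 0.92.** The lognormal tail otherwise puts ~6% of
  animals above fraction 1.0, and near-total staining is outside the
  estimator's identifiable range (no background mode). With the ceiling,
  the post-clip H-I GFAP SD settles at ≈ 0.26 rather than the published
  0.40: a distribution on [0, 0.92] with mean 0.40 and SD 0.40 would need
  extreme two-point mass piling, which neither the images nor the biology
  support. Group means, not SDs, are the calibration targets.
- **Controls** draw baseline physiology and moment-matched lognormal
  fractions (GFAP 0.22 ± 0.07, Iba1 0.16 ± 0.05) from an independent child
  seed stream, so control distributions cannot depend on the H-I
  covariance block.
- **Recovery glucose/lactate** inherit each animal's within-cohort rank
  from the H-I draw (no cross-epoch correlations are published, but a
  severely stressed animal should not recover to the cohort's best values).
- Heart rate during the occlusion is emitted as missing, as in the study.

## Ordinal pathology simulation

Necrosis percent follows a rectified-linear link on perceived severity:
`percent = clamp(gain · max(0, s + ε − θ), 0, 100)` with gain 25 %/unit,
rater/biology noise ε ~ N(0, 0.3²), and threshold θ = Φ⁻¹(12/17)·√(1+0.3²)
≈ 0.565 — calibrated so the probability of score 0 is 12/17, reproducing
the zero-inflation of the published cohort (12 of 17 H-I animals scored 0
while spanning most of the GFAP fraction range). Noise perturbs the
severity *inside* the rectifier: additive post-rectifier noise would give
half of all sub-threshold animals a spurious positive necrosis percent and
cap the zero rate at 50%, making the observed zero-inflation unreachable.
The 0–4 scale maps percent necrosis through half-open bands
(0, 25], (25, 50], (50, 75], (75, 100], with 0 reserved for exactly no
necrosis; half-open bands are the minimal consistent completion of the
published integer bands.

## Association statistics

The published analyses used mixed-effects models adjusted for survival
time, with survival time reported as non-significant. With one measurement
per animal the identifiable reduction is OLS of `y ~ x + week`; slope, SE,
t and p come from that fit, and r² is reported as the squared Pearson
correlation of the week-residualized x and y (a semi-partial coefficient of
determination). The generator is calibrated under the same definition, so
recovery is self-consistent. Group comparisons are one-way two-group ANOVA
(F = pooled t²); epoch-versus-baseline contrasts are paired t tests with a
Bonferroni factor of 3 (the three non-baseline epochs) — simpler and more
conservative than the published Dunnett/Dunn machinery, and used only for
synthetic self-checks. Two-sided p-values, α = 0.05 throughout.

A caveat the implementation surfaces honestly: the published GFAP group
moments (0.40 ± 0.40 vs 0.22 ± 0.07 at n = 17 per group) imply an expected
two-sample t ≈ 1.8 — modest single-cohort power, irrespective of the
p < 0.0001 printed alongside them. The Iba1 moments (0.33 ± 0.18 vs
0.16 ± 0.05) do support reliable per-cohort detection, and the test suite
asserts exactly that split: per-cohort power for Iba1, pooled-replicate
rejection for GFAP.

## Pipeline, determinism, problem sizes

One top-level seed fans out to per-stage child streams
(`SeedSequence([seed, stage])`), so a rerun with the same configuration is
byte-identical; the run manifest records output checksums to prove it. The
pipeline's calibration self-check regenerates 100 default-size cohorts and
requires every replicate-mean calibration quantity within 20% of target
(absolute floor 0.05 on the r² scale); it always runs at the default study
size because it validates the generator, not the particular cohort
requested. Default pipeline geometry is 512×512 sections; the test suite
and the replicate-recovery script use 96–128 px sections, where the
estimator's per-section error (≲ 0.01) is already negligible against the
biological spread, and 200 replicate cohorts (500 for the pathology
pattern), sizes at which every replicate-mean check is several standard
errors inside its band.

## Known limitations

- The imaging model omits acquisition artifacts (stitching, illumination
  gradients, PSF blur); the estimator's field performance on real montages
  is not established by these tests.
- The severity model is a one-factor Gaussian completion of pairwise
  published correlations; the true physiology is surely richer.
- The published per-predictor r² values' exact flavor (simple, partial or
  semi-partial) is not stated; the semi-partial definition adopted here is
  one defensible reading, applied consistently to generator and analysis.
- Sample r² at n = 17 is upward-biased; calibrating to the *sample*
  statistic means population effect sizes in the generator are smaller than
  the printed r² values.
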