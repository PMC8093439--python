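# Methods

## Decay model and simulation

A pulsed two-photon source with repetition period T = 12.5 ns (80 MHz)
excites each pixel; photon arrival times are histogrammed into 256 TCSPC
bins (bin width ≈ 49 ps). Because fluorophores with lifetimes of a few ns
do not fully decay between pulses, the per-period arrival-time density of a
component with lifetime τ is the *wrapped* exponential
e^(−t/τ) / (1 − e^(−T/τ)). The expected histogram of a pixel is

    E[y_k] = N · [IRF ⊛ (α₁ p_{τ₁} + α₂ p_{τ₂})]_k + C,

a circular convolution with the instrument response function, scaled to an
expected photon count N, plus a flat offset C (dark counts); realized
counts are independent Poisson draws per bin. Weights α are *amplitude*
fractions (the convention of standard TCSPC fitting software), so mixtures
of unit-amplitude wrapped exponentials carry them directly. The default
IRF is Gaussian, 0.2 ns FWHM centered at 1.0 ns, truncated to the window
and renormalized — a conventional stand-in for a measured
second-harmonic-generation IRF; any measured histogram can be supplied
instead.

## Synthetic scenes

Each scene is one z-plane: disk-shaped mCherry+ macrophages on a dim
autofluorescent background, rendered in three channels. Key generator
parameters (all overridable on the preset):

| parameter | default | meaning |
|---|---|---|
| field_size | 512×512 px | detector raster (tests and study runs use 128×128) |
| cell_radius_range | 3–6 px | uniform per-cell disk radius |
| photons_per_pixel_cell | 5000 | expected FAD photons per cell pixel |
| photons_per_pixel_background | 300 | expected NADH/FAD background photons per pixel |
| photons_per_pixel_mcherry | 2000 | expected mCherry photons per cell pixel |
| rr_mean, rr_cv | preset | lognormal per-cell redox-ratio distribution |
| nadh/fad_taum_mean, lifetime_jitter_cv | preset | truncated-normal per-cell mean lifetimes |
| mcherry_lifetime | 1.4 ns | mono-exponential reporter decay |

Condition presets encode the populations the analysis must resolve. Tumor:
RR mean 2.567, CV 30.37%, random layout, phenotype probabilities CD206+
0.522 / CD86+ 0.085. Dermis: RR mean 2.984, CV 108.05%, cells clustered
around follicle-like Gaussian foci, CD206+ 0.359 / CD86+ 0.206. Per-cell
RR is drawn **lognormally** parameterized by (mean, CV): a CV above 100%
is impossible for a normal draw on a positive quantity, and the published
±-values accompanying the means are 95% confidence intervals, not usable
as SDs (they are numerically inconsistent with the printed %CVs under any
single SD convention), so (mean, %CV) is the generative parameterization
throughout.

Mean lifetimes have no printed population values, so preset means are set
to literature-typical NAD(P)H/FAD values (tumor 1.00/0.90 ns, dermis
1.25/1.10 ns) with per-cell truncated-normal jitter of 8% (tumor) and 20%
(dermis) CV, preserving the qualitative ordering that dermal macrophages
are the more heterogeneous population on every variable. Per-cell
lifetimes are realized by fixing the short/long components (NAD(P)H
0.4/2.5 ns, FAD 0.4/2.8 ns) and solving the amplitude fraction for the
drawn τ_m; RR is realized exactly in expectation by scaling the NADH
photon budget as RR × (FAD budget). Cell pixels carry cell signal only —
the cell is treated as occluding the background at the focal plane — which
keeps the intensity-ratio construction unbiased. Cells are placed without
overlap (2 px clearance, rejection sampling with a bounded retry budget)
so every pixel has one owner.

What the generator does **not** emulate: optical PSF blur, detector
afterpulsing and dead time, motion, depth-dependent scattering, non-disk
morphology, spectral bleed-through, and 3-D continuity between z-planes.
Passing tests therefore demonstrate correctness of the *analysis* under
shot-noise-limited imaging of well-separated cells, not robustness to
every artifact of real intravital data.

## Lifetime fitting

Decays are binned 3×3 (neighborhood sums, truncated at edges) before
fitting. The bi-exponential fit minimizes Neyman-weighted least squares —
residuals divided by √max(y, 1) — between the histogram and
A·[IRF ⊛ wrapped bi-exponential] + C. The amplitude A and offset C ≥ 0 are
profiled out by weighted linear least squares at every candidate
(τ₁, τ₂, α₁), leaving a 3-parameter bounded trust-region problem
(initialization NAD(P)H 0.4/2.5/0.7, FAD 0.4/2.8/0.7; bounds τ₁ ∈
[0.05, 1.5], τ₂ ∈ [0.8, 10] ns, α₁ ∈ [0, 1]). Components are sorted
τ₁ < τ₂ post hoc with weights permuted, making α₁ + α₂ = 1 and
τ₁ ≤ τ_m ≤ τ₂ structural invariants. Pixels below 500 binned photons are
flagged absent rather than fitted; no χ² or lifetime gates are applied
beyond that threshold. For a pure mono-exponential input the two-component
split is unidentifiable but τ_m remains well determined, which is the
quantity carried into population statistics.

The mCherry channel uses a mono-exponential model (the reporter has a
single published lifetime near 1.4 ns): per pixel, the lifetime maximizes
the Poisson likelihood of A·[IRF ⊛ wrapped mono-exponential] + C, with
(A, C) solved by safeguarded Newton iterations inside a bounded scalar
search over τ ∈ [0.1, 6] ns. At 10⁴ photons this estimator has ≈ 14 ps
standard error, so true-1.4 ns pixels fall inside the 1.3–1.5 ns gate
essentially always, while autofluorescence with shorter apparent lifetime
is rejected.

## Segmentation

Binary morphological reconstruction by dilation (8-connectivity, 3×3
structuring element, scikit-image's fast hybrid algorithm) of
(marker ∧ mask) under the mask; tests verify exact equivalence to the
naive iterate-dilate-intersect fixed point. The FAD mask threshold is not
prescribed by the workflow this package models, so parameter-free Otsu is
the default with a `fixed:<value>` override. Components under 20 px are
discarded as photon-noise specks. Because decay binning spreads cell
photons one pixel outward, the raw marker includes a 1-px halo around each
cell; intersecting with the FAD mask before reconstruction removes it, and
recovered footprints on synthetic scenes are pixel-exact (Dice 1.0) at
default budgets. Each z-plane is segmented independently.

## Single-cell features and statistics

Per-cell features are unweighted means over the cell's defined pixels;
undefined pixels (FAD = 0 for the ratio, unfitted pixels for lifetimes)
are excluded per feature. Per-cell redox ratio is the **mean of per-pixel
ratios** — matching pixel-wise averaging within cell masks — not the ratio
of summed intensities; the alternative convention is available as
`extract_cell_features_ratio_of_means` but is not the default. Intensities
for the ratio are raw (unbinned) time-summed images; binning is applied
only to decays. Whole-field bi-exponential fitting is available
(`fit_channel(..., mask=None)`), but the pipeline restricts per-pixel fits
to segmented footprints by default, since only in-cell pixels ever enter
the feature table.

Population summaries use the sample (n−1) SD, Student-t 95% CIs, and
%CV = σ/μ·100. Between-condition comparisons are two-sided Mann–Whitney U
tests: exact enumeration when the pooled sample is tie-free and ≤ 20
observations (so the nominal-level calibration check at n₁ = n₂ = 10
exercises the exact path), otherwise the normal approximation with
continuity and tie corrections. No multiple-testing correction is applied;
variables are reported per comparison. Phenotype proportions are computed
per field of view and averaged, with SEM across FOVs (not across cells);
with exclusive CD86+/CD206+/double-negative labels the three percentages
sum to 100 by construction. Cells are pooled across fields without
hierarchical (per-animal) modeling, replicating the pooling convention of
the study design this package emulates.

## Problem sizes and numerical choices

Study-scale runs use 50 cells per 128×128 field (10 fields for the
500-cell tumor population, 6 for the 300-cell dermis population) — the
population statistics are properties of the presets, not the field size.
Optimizer tolerances are 1e−7 (ftol/xtol/gtol) for the bi-exponential
trust-region fit and 1e−4 ns for the mono-exponential scalar search.
Degenerate inputs are defined rather than thrown: Dice of two empty masks
is 1.0, an all-zero histogram is a flagged non-fit, a constant image under
Otsu yields an empty mask with a warning, and a zero-cell scene produces
an empty cell table with downstream statistics skipped.

## Known limitations

- Sample-CV estimation from a CV ≈ 108% lognormal population is
  heavy-tailed: at n = 300 cells the estimator itself scatters by ~±10%
  and is biased slightly low, so dermis heterogeneity recovery is the
  least stable quantity at study scale.
- Exact numerical agreement with proprietary commercial fitting software
  is neither claimed nor tested; the Neyman weighting and periodic-decay
  convolution match its documented behavior in spirit only.
- Touching or overlapping cells are out of scope (the generator enforces
  separation; no watershed splitting is implemented).
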