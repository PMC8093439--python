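# flimcyte

Single-cell metabolic autofluorescence analysis for intravital FLIM of
macrophage populations.

Two-photon imaging of the metabolic co-enzymes NAD(P)H and FAD reports the
redox state of individual cells without labels: the **optical redox ratio**
RR = I(NAD(P)H) / I(FAD) tracks the balance of reduction and oxidation, and
time-correlated single photon counting (TCSPC) resolves each pixel's
fluorescence decay into free and protein-bound lifetime components via the
bi-exponential model

    I(t) = α₁·e^(−t/τ₁) + α₂·e^(−t/τ₂) + C,   α₁ + α₂ = 1,
    τ_m = τ₁α₁ + τ₂α₂.

`flimcyte` is for researchers who want to quantify *metabolic heterogeneity*
of reporter-labeled cell populations (here: mCherry+ macrophages in tumor
vs. dermal tissue) from such data. It provides, as a tested Python library:

- **`flimcyte.synthetic`** — a ground-truthed TCSPC scene generator:
  three-channel (NAD(P)H / FAD / mCherry) photon-arrival histograms with
  Poisson shot noise, IRF convolution, non-overlapping disk cells with
  condition presets (`tumor`: RR mean 2.567, CV 30.37%, random layout;
  `dermis`: RR mean 2.984, CV 108.05%, follicle-like clustered layout) and
  per-cell CD86+/CD206+/double-negative phenotype labels.
- **`flimcyte.fitting`** — 3×3 decay binning, Neyman-weighted bi-exponential
  fits of the IRF-convolved periodic decay (per pixel), and mono-exponential
  Poisson-MLE lifetime estimation for the mCherry reporter channel.
- **`flimcyte.segmentation`** — marker-controlled **geodesic reconstruction**:
  mCherry lifetime thresholded on the reporter window (1.3–1.5 ns) as the
  marker, Otsu-binarized FAD intensity as the mask, morphological
  reconstruction by dilation to idempotency, component labeling, Dice
  validation.
- **`flimcyte.features`** — per-cell averaging into a tidy feature table
  (redox ratio, τ_m/τ₁/τ₂/α₁ per channel, intensities, area).
- **`flimcyte.stats`** — mean ± 95% CI summaries, %CV (= σ/μ·100)
  heterogeneity matrices, two-sided Mann–Whitney U tests (exact for small
  tie-free samples), and phenotype proportions with across-FOV SEM.
- **`flimcyte.pipeline` / `flimcyte` CLI** — `simulate`, `analyze`,
  `compare`, `report` over HDF5/TIFF/CSV/YAML files.

## Worked example

```python
import flimcyte as fc

irf = fc.default_irf()
h = fc.synthesize_decay(0.4, 2.5, 0.7, offset_rate=0.5, irf=irf,
                        expected_photons=1e5, rng=7)
fit = fc.fit_biexponential(h, irf, period=12.5)
print(fit.tau1, fit.tau2, fit.alpha1, fit.tau_m)
```

prints `0.409 2.511 0.701 1.038` — the 0.4/2.5 ns components and the 70%
free fraction recovered from 10⁵ photons, with τ_m within 1% of the true
1.03 ns (`examples/02_fit_decays.py`). The segmentation example
(`examples/03_segment_cells.py`) reports

```
true cells: 10, segmented: 10
mean per-cell Dice vs ground truth: 1.000
per-cell redox-ratio recovery: median relative error 0.0016
```

i.e. geodesic reconstruction returns pixel-perfect footprints on the
synthetic scene and the per-cell redox ratio matches the generator's drawn
value to ~0.2%. The population example (`examples/04_population_comparison.py`)
runs 60 cells per condition end to end and prints the tumor-vs-dermis
Mann–Whitney test (p < 0.01: tumor macrophages are more oxidized), a %CV
heatmap in which every dermis variable is more heterogeneous than its tumor
counterpart, and phenotype proportions (tumor ≈ 52% CD206+ vs ≈ 10% CD86+).

One-liner from the shell:

```sh
flimcyte simulate --preset tumor --seed 7 --n-cells 20 --field-size 128 --out run/sim
flimcyte analyze  --stack run/sim/stack.h5 --out run/ana
```

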