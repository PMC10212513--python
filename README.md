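# retscope

Quantifying the direction of electron flow through mitochondrial
complex I from rotenone-challenge fluorescence data.

## The problem

Complex I of the electron transport chain can run forward (FET: NADH →
ubiquinone) or, driven by the protonmotive force, in reverse (RET:
ubiquinol → NAD⁺). Which direction it runs in a given mitochondrion
determines how superoxide/H₂O₂ production at its quinone site should be
interpreted. A simple functional assay decides the direction: block the
Q-site with rotenone and watch the endogenous NAD(P)H autofluorescence —
if it **rises**, flow was forward (electrons keep trickling into the NAD
pool); if it **falls**, flow was reverse (the pool loses its QH₂-driven
supply and oxidises).

`retscope` implements the quantitative machinery around this challenge
for three experimental arms, together with a ground-truthed synthetic
data generator so every stage is testable without raw recordings:

- **Single isolated mitochondria** (TMRM + NAD(P)H wide-field imaging):
  background subtraction, punctum segmentation, trace extraction, the
  Nernst readout of relative membrane potential
  `Δψ = 61 mV × log10(F₁/F₂)`, rectangular gating of response classes,
  and thresholded three-way direction calls (forward / stalled /
  reverse) from population-normalised log₂-fold changes.
- **Mitochondria inside cells** (two-photon NAD(P)H before/after
  frames): Wiener denoising, B-spline deformable registration with
  Pearson-r QC (pairs with r < 0.6 discarded), Otsu union masking,
  pixelwise log₂-fold histograms, a mock-calibrated single-Gaussian null
  fit, a constrained two-component Gaussian mixture (both σ fixed to the
  mock), and the **excess-pixel-count estimator** of the oxidising (RET)
  subpopulation: the excess of observed over model-expected pixels below
  `μ_nonresp − 2σ_mock`.
- **Bulk plate/cuvette assays**: H₂O₂ calibration by standard spikes,
  OLS rates over an inclusive cycle window (default cycles 5–18, 14
  points), percent-of-vehicle and percent-reduction scalings, and
  variable-slope four-parameter-logistic (4PL) dose-response fits with
  residual-rate subtraction for nominal IC₅₀ determination.

## Worked example

The package's flagship control mirrors the validation used for the
excess-count estimator: simulate a rotenone-responsive cell population
(74% responders, ~50% mean intensity increase), erase 6.4% of
mitochondria to background in the post-challenge frame, and ask the
estimator to find them:

```sh
retscope recover --experiment masked-ret --seed 1 --outdir out/
cat out/recover_masked-ret.json
```

```json
{
 "experiment": "masked-ret",
 "truth_masked_fraction": 0.064,
 "realized_masked_fraction": 0.064,
 "estimate": 0.06118658095361841,
 "se": 0.0005467554029275691,
 "n_cells": 100,
 "sigma0_mock": 0.15321759484326072,
 "mu0_mock": -0.0004746587404691973
}
```

Reading: the mock (vehicle-vehicle) pairs calibrate a null width of
σ₀ ≈ 0.153 log₂-fold units (`sigma0_mock`, all noise, no real redox
change, mode pinned at 0 by `mu0_mock` rescaling); pooled over 100
synthetic cells the estimator reports 6.12 ± 0.05% of mitochondrial
pixels as significantly oxidised against a ground truth of 6.4% —
near-complete recovery of the planted RET-like population, with the
shortfall coming from mask-edge pixels and the max(observed−expected, 0)
tail accounting. Other experiments: `null-calibration` (mock-vs-mock
false-positive floor, ≈0.2%), `monotonicity` (estimate vs masked-truth
ladder), `direction` (three-way call recovery on replicate fields) and
`plate` (IC₅₀/calibration recovery).

Library use mirrors the CLI:

```python
from retscope import relative_polarization, fit_two_normals, pixel_log2fold
relative_polarization(10.0, 1.0)   # -> 61.0 mV, one Nernst decade
```

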