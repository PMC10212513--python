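# Methods

## The measurement model

The rotenone challenge converts a thermodynamic question — is electron
flow through complex I forward or reverse? — into the sign of an
NAD(P)H autofluorescence change. `retscope` quantifies that sign at
three scales: single immobilised mitochondria, mitochondria inside
cells, and bulk well/cuvette traces. All intensities are arbitrary
fluorescence units (AFU); all potentials are relative (no absolute-mV
calibration is attempted, because a true 0 mV reference is not
obtainable in these preparations).

### Nernst readout (single mitochondria)

TMRM accumulates in the matrix Nernstian-ly, ~10-fold per 61 mV.
Relative polarization between two conditions is
`61 mV × log10(F₁/F₂)`; the decade slope is fixed at exactly 61 (the
conventionally printed value at ~37 °C, not the 61.5 first-principles
figure) so results line up with common practice. The readout is
additive over chained ratios, which the tests assert to 1e-9 mV.
Polarization by glutamate+malate is referenced to succinate
(`x = V_GM − V_succ ≤ 0`, smaller magnitude = stronger G+M
polarization); the G3P response is referenced to G+M
(`y = V_G3P − V_GM`).

Response classes are rectangular gates in the (x, y) plane. Published
gate boundaries do not exist (the original classes are declared
arbitrary), so the defaults are documented, not claimed: a G3P floor at
+5 mV below which a mitochondrion is `nonresponsive`; a G+M split at
−30 mV and a G3P split at +20 mV separating `strong_gm_weak_g3p`
(x > −30, y < 20), `ret_like` (x ≤ −30, y ≥ 20) and `medium_medium`
(the remainder). Two thresholds alone cannot separate "medium/medium"
from "no response", hence the third (floor) threshold; the three
thresholds partition the plane exhaustively and disjointly, which a
property test asserts.

### Direction calls

Per-object NAD(P)H changes are normalised to the **population** mean
baseline, `Δ = log2(1 + ΔF / ⟨F_pre⟩)`, because individual baselines can
be near zero (dim mitochondria) and would otherwise produce unbounded
log-ratios. Calls are three-way: forward if `Δ > +t`, reverse if
`Δ < −t`, else stalled. The threshold `t` is `c` times the average
per-object standard error of a single post-challenge determination,
estimated from the three repeated post-challenge frames as the c₄
bias-corrected sample SD (c₄(3) ≈ 0.886). `c` defaults to 1.5 and is
configurable in [1, 2]; the recovery experiment uses the stringent end
(c = 2) because specificity is what matters when calling a ~4% reverse
class against a ~30% stalled class — at looser thresholds the noise
leak from the stalled population exceeds the rare class itself.

### Cell-arm pixel statistics

For each cell, before/after frames are background-subtracted (below),
Wiener-filtered (3×3 local-statistics filter; mean-preserving to 0.1%),
optionally registered, masked by the union of the two frames' Otsu
masks (the union keeps mitochondria that vanish after challenge — the
very pixels the estimator must count), and reduced to a histogram of
`log2((after + ε)/(before + ε))` with ε = 1 AFU and bin width 0.05.
The after frame is rescaled by a single common factor `2^(−μ₀_mock)` so
the mock-pair mode sits at 0 (the normalisation constant of the
intensity-rescale step is otherwise unidentifiable).

Mock (vehicle-vehicle) pairs pooled over cells are fitted with a single
Gaussian by **binned maximum likelihood** (multinomial over bin
probabilities; Nelder-Mead on (μ, log σ)); treated cells are fitted
with a two-component Gaussian mixture in which **both components share
the mock σ₀** — the responder's width is dominated by the same
noise/motility process as the non-responder's, so giving it a free
width would let it absorb the oxidised tail the estimator is meant to
count. The mixture is optimised by L-BFGS-B over (logit weight, μ_non,
δ ≥ 0) from a deterministic 18-point start grid, with the
identifiability constraint μ_resp = μ_non + δ ≥ μ_non.

A numerical point worth stating: the binned likelihood includes a tiny
fixed uniform contamination term (η = 1e-3 spread over the bins).
Without it, any pixel far outside the two Gaussians — precisely the
strongly oxidised pixels — drives the log-likelihood to −∞ and drags
the component means into the tail. With it, outlier bins contribute a
bounded, parameter-independent term and the Gaussians fit the bulk.

The RET (oxidising) fraction is the **excess pixel count**: over bins
with centre below `μ_nonresp − k·σ₀` (k = 2), sum
`max(observed − expected-under-fit, 0)` and divide by the masked pixel
count. The threshold is measured from the non-responder centre, i.e.
oxidation is counted relative to the unresponsive population, and the
reference curve is the full fitted mixture. The result is a pixel
fraction of the mitochondrial mask, reported as such; equating it with
a mitochondrion fraction assumes equal mean mitochondrial area across
classes. Per-cell estimates are pooled unweighted (mean ± SE across
cells, then across experiments).

The `max(·, 0)` makes the estimator positively biased under the null by
roughly `Σ_bins √(λ_b/2π) / n_pixels`; at the default conditions
(~3000 masked pixels/cell) the measured false-positive floor is ≈0.2%,
under the 0.5% design bound. The floor shrinks as 1/√n_pixels.

### Deformable registration

Free-form deformation on a cubic-B-spline control grid (spacing ≥ 8 px,
default 16), mean-squared-difference metric on [0,1]-rescaled images,
translation pre-alignment by phase cross-correlation, three-level
Gaussian scale-space continuation, analytic gradient via the tensor
B-spline basis, L-BFGS-B with a small Laplacian penalty (1e-2) on the
control grid. If the optimised field does not improve the Pearson
correlation with the fixed frame, the identity field is returned —
registration never degrades r. QC keeps pairs with r ≥ 0.6 (a pair at
exactly 0.6 is kept). Registration quality is validated against the
generator's true displacement fields: a 2-px RMS smooth warp is
recovered to < 1 px RMS residual over the foreground (displacement is
unobservable over flat background, so the residual is measured where
there is signal).

### Bulk assays

Rates are OLS slopes of fluorescence vs time over an inclusive cycle
window (default [5, 18]: 14 points of a 25 × 80 s recording),
offset-invariant by construction. H₂O₂ calibration regresses AFU steps
on spiked pmol through the origin (steps are differences and hence
offset-free); matrix consumption of H₂O₂ is deliberately **not**
corrected (an optional multiplier exists but defaults off), so absolute
rates are underestimates, consistently. Dose-response uses the
variable-slope 4PL `r(c) = bottom + (top − bottom)/(1 + (c/IC₅₀)^h)`
fitted by multi-start nonlinear least squares (h ∈ {0.5, 1, 2};
IC₅₀ on a log scale; zero-dose points handled exactly since
`(0/IC₅₀)^h = 0` for h > 0). With residual subtraction, the fitted
high-dose plateau (the suppressor-resistant rate from other sites) is
removed and the curve refit with the bottom pinned at 0 before the IC₅₀
is read. IC₅₀s are labelled *nominal*: they reflect added, not
measured, concentrations. Fits with no identifiable transition (IC₅₀
far outside the dosed range, or amplitude within 3× the residual noise)
raise instead of returning a number.

## The synthetic generator

The generator emulates exactly the statistical structure the estimators
assume, and is itself first-class, tested code.

- **Spots**: isotropic 2-D Gaussians (σ = 1.5 px), centres
  rejection-sampled at ≥ 4σ separation, 0-based (row, col) pixel-centre
  coordinates. Elongated/3-D shapes, photobleaching and TMRM quench
  behaviour are not modelled.
- **Classes**: forward-responders (NAD(P)H increase on challenge, mean
  log₂ 0.585 = +50%, SD 0.1), stalled (exactly 0), RET (mean −1.0) and
  non-polarizing (increase, +1.0). Realized counts are the
  deterministic largest-remainder apportionment of the class fractions
  (so control counts are exact); a multinomial switch exists and is
  used where replicate fields should be independent population draws.
- **TMRM amplitude**: `∝ 10^(V/61)` so the Nernst readout inverts it
  exactly in the noiseless limit.
- **Noise**: additive Gaussian read noise (σ = 3 AFU) plus a
  scaled-Poisson shot term (gain 0.5 AFU/photon) on a background of
  100 AFU with spot peaks ~300 AFU. These defaults are calibrated so
  that a mock frame pair yields a pixelwise log₂-fold σ ≈ 0.15, inside
  the plausible 0.1–0.3 range for this kind of recording; no noise
  magnitudes are published for the source instruments. EMCCD excess
  noise is not modelled (the estimators only assume a symmetric null,
  which the mock fit calibrates empirically).
- **Motility**: smooth random displacement fields (Gaussian-filtered
  white noise, RMS-normalised, pull semantics), with the true field
  retained for registration-recovery tests. Motility is **not** applied
  in the mixture/excess experiments: at σ = 1.5 px spot scale, ~0.7 px
  registration residuals inflate the mock σ far beyond the plausible
  band and the mixture analysis degenerates — so in those experiments
  the mock pair calibrates pure pixel noise. Consequently the masking
  control recovers nearly the full planted fraction (≈6.1% of 6.4%),
  whereas on real motile recordings the same control under-detects
  (≈5% of 6.4%); passing tests therefore demonstrate estimator
  correctness under the stated noise model, not robustness to residual
  motion artifacts.
- **Cell fields**: 256 × 256 px (matching single-cell crops at
  0.2 µm/px), 125 mitochondria per cell, so the 6.4% masking control is
  realized exactly (8 of 125). Masked mitochondria have all pixels
  within 3σ replaced by background sampled from a local annulus that
  excludes every spot's 4σ disk.
- **Plates**: linear resorufin accumulation `baseline + slope·rate·t`
  per well (25 × 80 s cycles), calibration wells with step increments
  at spike cycles, and rates following a stored 4PL curve where a
  suppressor concentration is given.
- **Randomness**: one root seed; every sub-draw comes from a named
  child stream (`SeedSequence(seed, spawn_key=crc32(name))`), so adding
  a feature never perturbs existing draws and identical configurations
  are bit-identical.

## Background subtraction

Per stack: foreground = Otsu of the max projection, dilated 3 px
(radius unpublished; exposed in config); per frame the scalar
background is the mean of off-mask pixels whose max-projection value
lies below the 50th percentile of off-mask values (the percentile is
likewise unpublished; 50 is the package default). Selecting on the max
projection conditions each frame's noise downward — about −0.5 σ at two
frames — but the bias is common to all frames, so the intensity
*ratios* every downstream readout consumes are unaffected; the tests
pin both facts.

## Problem sizes and determinism

The recovery experiments run at desk scale: 100 cells (+20 mock) for
the masking control, 40 (+15) for the null calibration, 15 per level
(+10) for the five-level monotonicity ladder, four 250-mitochondrion
fields for direction calls. These sizes put the pooled SEs well below
the effects being measured while keeping a full run in tens of seconds.
Every experiment is deterministic given (config, seed); reruns are
bit-identical, which the tests assert.

## Known limitations

- The synthetic morphology is punctate-only; Fa2N-4 cell geometry,
  organelle crowding and out-of-focus light are not emulated.
- Pixel fractions stand in for mitochondrion fractions under an
  equal-mean-area assumption across classes.
- The segmentation stage (LoG enhancement → local maxima → marker
  watershed → area filter) is an openly declared stand-in for
  unpublished acquisition-software internals; its contract is
  recall/precision ≥ 0.95 at SNR ≥ 10 on synthetic scenes.
- NAD(P)H signal is not attributed to NADH vs NADPH, and no absolute
  redox calibration is attempted.
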