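# Methods

`fddcs` implements the signal-processing chain of a camera-based heterodyne
(Fourier-domain) diffuse correlation spectroscopy instrument, together with a
physics-level simulator of the raw holograms it records. This note describes
the models, the defaults and the numerical choices, and states what the
synthetic data do and do not establish about real measurements.

## Measurement model

A continuous-wave beam is split into a sample arm (multiply scattered by a
turbid medium, collected through an aperture) and a reference arm that is
frequency-shifted by a detuning `Δf`. The two arms recombine off-axis on a
camera. By the Wiener–Khinchin theorem the power spectral density (PSD) of
the scattered field, `s1(ω)`, is the Fourier transform of the field
autocorrelation `g1(τ)`; sampling the heterodyne energy at a set of detunings
therefore samples the PSD point by point, and a fit of a dynamical model to
`S̄1(Δω)` yields the flow parameter (a correlation time `τc`, conventionally
rescaled to an effective Brownian diffusion coefficient `Db`).

Processing steps, in pipeline order:

1. **Temporal filter.** `H_C[n] = I_n − I_{n+1}` (DC-pair, the default:
   high-passes away the static reference), `H_C[n] = I_{n+1} − I_1`
   (first-frame, a diagnostic mode), or `H_C[n] = I_n` (single-frame, used
   after SVD filtering which has already removed the static content).
2. **Reconstruction.** `H_R = |F₂D(H_C)|²` with the unnormalised forward DFT
   and the zero-frequency bin shifted to the grid centre, so Parseval reads
   `ΣH_R = N_pix ΣH_C²`. Off-axis recombination separates the twin
   heterodyne images (an exact conjugate pair for real `H_C`; the package
   reports both, their mean, and the per-pixel values of the plus mask).
3. **Masks.** Closed lattice discs (`x² + y² ≤ r²`). A radius-80 disc holds
   exactly 20081 pixels, the signal-mask size on a 512×512 sensor. The minus
   mask is the exact point reflection of the plus mask; the shot-noise mask
   sits in a quiet corner reached by neither the heterodyne bands nor the
   sample autocorrelation band. The default layout scales the 512-pixel
   reference geometry (carrier at 170/512 of the grid per axis, radius
   80/512) to any grid size.
4. **Normalisation.** `S1 = H_R/N̄ − 1` per pixel, where `N̄` is the mean of
   `H_R` over the shot-noise mask — the homodyne shot-noise floor, which
   pixel integration does not attenuate. `N̄` is estimated per frame by
   default; `nbar_mode="stack_mean"` pools it over frames, appropriate for
   stationary acquisitions because the per-frame estimate carries a
   common-mode relative noise of `1/√M_shot` that matters once the signal
   mask is comparable in size to the shot mask.
5. **MTF correction.** Integration over the active pixel area (linear fill
   fraction `α`) attenuates heterodyne spatial frequencies by
   `MTF(kx,ky) = |sinc(α Δx kx) sinc(α Δy ky)|²` with `Δx kx` running over
   [−0.5, 0.5) across the grid. The correction divides per pixel *before*
   mask averaging. The effective `α` is calibrated, not taken from the
   sensor datasheet, because microlens aberrations and off-design wavelength
   response change it.
6. **SVD decluttering.** Frames are reshaped to a space–time matrix `Q`
   (`n_x n_y × n_t`); the largest singular values carry spatiotemporally
   correlated clutter (laser power modulation, beat notes, mode hops), while
   dynamic speckle has weak spatiotemporal correlation. Zeroing the first
   `n_c` values and rebuilding declutters the stack; reconstruction then
   proceeds in single-frame mode. `suggest_nc` flags the run of leading
   values elevated ≥1.25× above a log-linear fit to the tail half of the
   spectrum; it is advisory, mirroring selection by inspection.
7. **Multispeckle denoising (sort–median–unsort).** Masked `S1` values of
   `n_t` reconstructed holograms form `R` (mask pixels × frames). Each
   column is sorted ascending (removing the random spatial arrangement of
   speckle), each row is median-filtered along time with a `[1 × n]` window,
   and each column's recorded permutation is inverted exactly. Detector
   noise — white in the camera plane, hence speckle-like in the
   reconstruction — is suppressed; the speckle distribution itself is
   preserved. `n = 3` is the default; even windows take the mean of the two
   central order statistics (configurable to the lower one). Edge policy is
   replicate padding (configurable); the window is time-only by design.
8. **Spectrum fit.** For exponential `g1(τ) = exp(−|τ|/τc)` the PSD is the
   Lorentzian `s1(ω) = 2τc/(1 + ω²τc²)`. A camera exposure of length `T`
   measures the triangularly windowed PSD
   `(2/T) Re ∫₀ᵀ (T−τ) g1(τ) e^{−iωτ} dτ` (closed form implemented), which
   converges to `s1(ω)` as `T/τc → ∞`; fitting the windowed model removes
   exposure bias. The fit profiles the amplitude analytically and searches
   `log τc` from five log-spaced starts (deterministic). Arbitrary `g1`
   models enter via quadrature (`model="plugin"`). The map from `τc` to `Db`
   is a plug-in proportionality labelled as a placeholder: the closed-form
   semi-infinite correlation-diffusion model of the measurement geometry is
   deliberately out of scope.
9. **SNR analysis.** `SNR = μ/σ` of the per-frame `S̄1` series, with the
   sample (N−1) standard deviation (fixed for reproducibility; immaterial at
   500 repeats). The speckle area on the sensor is `S = (λz)²/A_aperture`;
   with λ = 785 nm, z = 76.84 mm, a 5.0 mm circular aperture and 3.45 µm
   pixels, `S = 1.853·10⁻¹⁰ m² = 15.57 px`, so the 20081-px mask detects
   ~1290 speckles. Speckle counts are real-valued (`mask_px / S_px`).
   Concentric sub-masks sweep the speckle number; reduced masks are prefixes
   of the radially ordered full mask, so the sweep is a single cumulative
   sum.

### Single-speckle reference for SNR gain

The gain compares the multispeckle SNR with the SNR a single-speckle
measurement of the same data quality would achieve. Lattice discs cannot
contain exactly one speckle area (the smallest disc at or above 15.57 px has
21 px), so the reference SNR is rescaled to exactly one speckle with the
square-root speckle-statistics law, `SNR₁ = SNR_ref/√(N_ref)`, and by default
pooled over all masks of up to eight speckle areas to cut the Monte-Carlo
noise of the estimate (this reduced the seed-to-seed spread of the full-mask
gain from ~9% to ~6%). The plain ratio against the smallest reference mask is
available (`normalize_reference=False`), in which case the reference's own
gain is 1 by construction.

## Synthetic holograms

The simulator synthesises the sample field directly in the camera's
spatial-frequency domain: independent circular-complex-Gaussian modes on a
closed disc of radius `aperture_radius_freq` centred at `carrier_offset`.
This reproduces the reconstruction statistics of the lensless Fourier
geometry — where reconstruction is a plain 2-D DFT of the camera plane —
without modelling the light guide. Each mode evolves as an AR(1) process
whose autocorrelation equals the configured `g1` at the substep interval
(exact for exponential `g1`; plug-in models are mapped to per-step
coefficients `g1(Δt)/g1(0)`, a first-order surrogate). Gaps between
exposures are bridged with a single AR step (exact, since AR(1) is Markov).

Detection: per substep the intensity is `|R e^{iΔωt} + E|²` with a uniform
reference amplitude; substeps are summed over the exposure (at least enough
that the beat advances ≤ π/4 per substep, enforced), averaged over the
active α-fraction of each pixel, scaled to photoelectrons, Poisson sampled,
Gaussian read noise added, divided by the quantisation gain, floored and
clipped to the bit depth. Two pixel-integration paths exist:

- **oversample** — explicit sub-pixel sampling with area-weighted fractional
  boundary sub-samples (so non-integer `α·oversample` is exact to first
  order); used for fill-factor studies so that the attenuation being fitted
  enters through actual spatial integration rather than through the same
  analytic formula.
- **fourier** — because the synthesised intensity is band-limited within the
  camera Nyquist range (enforced by the band-placement validation), the
  area average is applied exactly as a `sinc(αu)sinc(αv)` transfer in the
  frequency domain. This is the continuum limit of the oversampled path (the
  two differ only by a fixed (os−1)/(2·os)-pixel registration offset, which
  no intensity statistic sees) and makes 512×512×501 acquisitions tractable.

Validation requires the twin bands to fit inside the Nyquist quadrant and to
clear the origin/autocorrelation band, the beat to be resolved within an
exposure, and `τc ≥ 2·substep`. All randomness derives from `rng_seed`
(per-purpose child streams), and identical configurations reproduce stacks
bit for bit.

**Clutter injection.** `inject_global_clutter` multiplies each frame by
`1 + w[t]` (beat notes, drifts) — a rank-one perturbation of the space-time
matrix, so a beat elevates exactly one singular value of the DC-pair matrix,
while a slow drift falls inside the DC-pair stopband. `inject_mode_hops`
models a laser mode hop before frame `f`: the speckle state is redrawn with
an independent global phase, reference–sample coherence is destroyed for the
remainder of that frame's exposure (random phase per substep), and the
reference power steps by a small persistent factor (default 1%), as a new
longitudinal mode has slightly different output power. Under DC-pair
filtering the two pairs spanning the hop lose roughly half their heterodyne
energy — the negative-going `S̄1` outliers seen on real data — and under
first-frame filtering the unmatched reference level appears as a step in the
mean hologram intensity.

An optional coherence-area extension (`speckle_area_px > 1`) multiplies the
camera field by a Gaussian envelope whose width is solved (by bisection on
the discrete effective-cells formula `N²Σh⁴/(Σh²)²`) so the
reconstruction-plane field has a chosen coherence area. It is exercised by
tests but not used in the headline studies: with correlated modes, lattice
masks near one speckle area hold disproportionately many partial coherence
cells, which distorts the small-mask end of the gain curve.

## Study conditions

`scenarios.py` freezes the named conditions. The SNR-gain study uses one
1 kHz detuning with `τc = 1/(2π·1 kHz)` (sampling the Lorentzian at
`ωτc = 1`), a 200 Hz frame rate with 0.2 ms exposures, 5000 reference
photoelectrons per pixel per frame, a 0.2% sensor-mean sample beam (placing
per-pixel `S1` in the tens-to-low-hundreds), read noise 2.45 e⁻,
quantisation interval 5.73 e⁻, 12-bit ADC, 501 frames of 512×512. Under
these conditions the control (DC-pair + MTF) gain saturates near 25 at the
full mask — the per-frame `N̄` estimate contributes a common-mode noise
comparable to speckle sampling noise at 20081 mask pixels — and `n = 3`
denoising, which suppresses the temporally white part of the noise more than
the shared-frame-correlated sampling noise, restores the square-root law
(gain ≈ 36 at ~1290 speckles, log–log slope ≈ 0.5); `n = 4` exceeds it.
Seed-to-seed spread of the full-mask denoised gain is about 6%.

The fill-factor study records 500 flat-field frames on a 128-pixel grid with
5×5 sub-pixel integration at α = 0.72 and recovers α by the variance
minimisation (101-point grid on [0, 1], golden-section refinement between
the best grid neighbours to 10⁻³; objective evaluated on the union of both
twin masks, where the mean image carries signal). The recovered value runs
≈ 0.02 high, the residual of fitting the continuous sinc window to data
generated with a 5-sample discrete window. The correlation-time study uses
six detunings (0–800 Hz) × 500 frames at 64×64 with 5 ms exposures
(`T = 5τc`) and fits the windowed model; recovery is within a few tenths of
a percent, and control and denoised fits agree to ~10⁻⁴ relative.

Problem sizes are desk-scale choices: grids below 512 scale the mask layout
proportionally, and the studies above complete in about a minute in total.

## What the synthetic data do not show

The simulator draws ideal, spatially uniform reference beams, perfectly
stationary phantom statistics, exponential `g1`, and pixel-independent
read/quantisation noise. It does not model fixed-pattern nonuniformity, dust
diffraction, light-guide transfer-matrix motion artefacts, laser cavity
dynamics (mode hops are injected phenomenologically, not emitted by a cavity
model), absolute photon budgets of a specific tissue geometry, or the
analytic semi-infinite FD-DCS model needed for absolute `Db`. Passing tests
therefore establish the correctness and statistical behaviour of the
*processing chain* under controlled conditions, not instrument-level
performance on tissue.

## Numerical and degenerate-input choices

- Masks validate disjointness, grid bounds and DC exclusion at construction;
  the minus mask is generated by reflection, never re-derived.
- An exactly static, noiseless acquisition cancels to zero under DC-pair
  filtering; normalisation then raises a degenerate-input error (no
  shot-noise energy), rather than returning 0/0.
- `singular_spectrum` uses the time-side Gram matrix for tall inputs
  (matching a full decomposition to ~10⁻⁸ relative on well-conditioned
  problems) and a direct SVD otherwise. Decluttering removes exactly the
  head of the singular spectrum; reapplying it removes the *next* head, so
  repeated application is not the identity — the projection property that
  does hold (and is tested) is the Pythagorean split of energies and the
  truncation of the spectrum.
- Sorting ties break by stable original order; the recorded permutation
  guarantees exact unsorting regardless.
- SNR of a constant series is an explicit error; sweeps record such radii as
  gaps (NaN).
- Fits are deterministic multi-start bounded scalar minimisations; quadrature
  convergence is checked and failure raises rather than returning garbage.
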