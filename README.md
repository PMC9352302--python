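# fddcs

Simulation and signal processing for **holographic Fourier-domain diffuse
correlation spectroscopy (FD-DCS)** — a camera-based, heterodyne variant of
DCS that measures flow (e.g. cerebral blood flow surrogates) from the
temporal decorrelation of multiply scattered coherent light.

In FD-DCS a frequency-shifted reference beam interferes off-axis with the
scattered sample field on an inexpensive camera. By the Wiener–Khinchin
theorem the power spectral density of the field fluctuations,
`s1(ω) = ∫ g1(τ) e^{−iωτ} dτ`, is sampled point by point by scanning the
reference detuning `Δf`; a Lorentzian (exponential-`g1`) fit to `S̄1(Δω)`
yields the correlation time `τc` and hence a flow parameter. Each camera
frame detects thousands of speckles in parallel, and the SNR of the
speckle-averaged measurement should grow as `√N_speckles` — provided
detector and instrument noise are dealt with. This package implements the
full chain that makes that scaling reachable:

- a physics-level **simulator** of off-axis heterodyne dynamic-speckle
  holograms (AR(1) mode dynamics for any `g1`, finite exposure, sub-pixel
  fill-factor integration, Poisson/read/ADC noise, injectable mode hops and
  global clutter);
- **reconstruction**: `H_R = |F₂D(H_C)|²` with DC-pair / first-frame /
  single-frame temporal filtering, twin-image and shot-noise masking, and
  shot-noise-normalised `S1 = H_R/N̄ − 1`;
- **MTF correction and fill-factor calibration**:
  `MTF = |sinc(αΔx kx) sinc(αΔy ky)|²`, with the effective `α` estimated by
  minimising the variance of the mean corrected `S1` image;
- **SVD decluttering** of the space–time matrix `Q` (zero the `n_c` largest
  singular values, then single-frame reconstruction);
- the **sort–median–unsort multispeckle denoiser**: per-column rank sort of
  the `S1` space–time matrix `R`, `[1 × n]` time-axis median, exact unsort;
- **spectrum fitting** (Lorentzian and exposure-windowed Lorentzian, plug-in
  `g1` models) and **SNR / speckle-count analysis** with
  `S = (λz)²/A_aperture` and concentric mask-radius sweeps.

The fit/transform-shaped stages are scikit-learn estimators
(`FillFactorCalibrator`, `SVDClutterFilter`, `MultispeckleDenoiser`,
`SpectrumModel`) that compose with sklearn pipelines; plain functions wrap
them for script use, and a `fddcs` CLI drives the chain on TIFF stacks.

## Worked example

```python
from fddcs import REFERENCE_GEOMETRY, speckle_area
from fddcs.pipeline import tauc_recovery_study

px = speckle_area(REFERENCE_GEOMETRY)
print(f"speckle area: {px:.2f} px -> {20081 / px:.0f} speckles in the 20081-px mask")

study = tauc_recovery_study(seed=7, n_frames=200)
print(f"true tau_c : {study.true_tauc_s * 1e3:.3f} ms")
print(f"fitted     : {study.fit_control.tauc_s * 1e3:.3f} ms (control)")
print(f"fitted     : {study.fit_denoised.tauc_s * 1e3:.3f} ms (denoised, n = 3)")
ratio = study.spectrum_denoised.stds / study.spectrum_control.stds
print("per-detuning spread ratio (denoised/control):",
      " ".join(f"{r:.2f}" for r in ratio))
```

prints

```
speckle area: 15.57 px -> 1290 speckles in the 20081-px mask
true tau_c : 1.000 ms
fitted     : 0.993 ms (control)
fitted     : 0.992 ms (denoised, n = 3)
per-detuning spread ratio (denoised/control): 0.66 0.68 0.70 0.69 0.74 0.75
```

The first line is the closed-form geometry: with λ = 785 nm, an observation
distance of 76.84 mm, a 5.0 mm circular collection aperture and 3.45 µm
pixels, one speckle covers 15.57 camera pixels, so the radius-80 signal mask
(20081 pixels) detects ~1290 speckles in parallel. The remaining lines come
from an end-to-end synthetic run (six detunings, 200 frames each): the
correlation time is recovered to better than 1%, denoising leaves the fitted
value essentially unchanged (the signal is not corrupted), and the spread of
the PSD samples shrinks at every detuning.

The same machinery at full scale (`fddcs.pipeline.snr_gain_study`, 501
frames of 512×512 with shot, read and quantisation noise) shows the control
SNR gain saturating near 25 at the full mask while `n = 3` denoising
restores the square-root scaling law, reaching a gain of ≈ 36 over a
single-speckle measurement at ~1290 speckles.

## Command line

```sh
fddcs simulate --config sim.cfg --out data/          # stacks per detuning
fddcs reconstruct --in data/det_1000/frames.tif --filter dc_pair \
      --alpha 0.72 --out scalars_det1000.csv
fddcs calibrate-mtf --in flat/frames.tif --grid 101 --out fit.csv
fddcs svd-filter --in data/det_0/frames.tif --nc 10 --out filtered
fddcs denoise --in s1_stack.tif --n 3 --edge replicate --out s1_denoised
fddcs fit --in scalars/ --out fit.csv --exposure 0.005
fddcs snr --in s1_stack.tif --radii 5:80:5 --speckle-px 15.57 --out curve.csv
fddcs pipeline --config sim.cfg --denoise-n 3 --out run/
```

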