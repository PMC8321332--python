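# prfthermo

MR thermometry toolkit for focused-ultrasound treatment monitoring:
classical proton-resonance-frequency (PRF) shift temperature mapping,
**referenceless** thermometry by radial-basis-function (RBF) and polynomial
extrapolation of the background phase, Rician-corrected SNR estimation, and
a fully synthetic phantom/sonication simulator so that every method is
testable without scanner data.

It is written for medical physicists and imaging scientists who study
whether MRI-based temperature monitoring can detect unwanted heating — for
example at skin/gel interfaces during MR-guided focused ultrasound (MRgFUS)
— and who need a reproducible, ground-truthed bench for the reconstruction
and statistics chain.

## The science in brief

The water proton resonance frequency shifts with temperature
(α ≈ −0.01 ppm/°C), so in a gradient-echo acquisition

ΔT = Δφ / (2π · γ · α·10⁻⁶ · B₀ · TE).

Classical PRF thermometry takes Δφ against a pre-heating baseline frame.
Referenceless thermometry avoids the baseline: it fits an interpolant

s(X) = p_m(X) + Σᵢ λᵢ φ(‖X − Xᵢ‖₂)

to the phase of an unheated annulus around the treated region (solving the
saddle-point system that enforces the interpolation conditions s(Xⱼ) = fⱼ
and side conditions Σᵢ λᵢ q(Xᵢ) = 0, q ∈ π_m^d), extrapolates it under the
heated region as the background-phase estimate, and converts the residual
phase to ΔT. Kernels: linear, thin-plate spline, Gaussian, multiquadric.

SNR of magnitude images is estimated as SNR = 0.655 · μ(object) /
σ(background): the 0.655 = √(2 − π/2) factor corrects for the Rayleigh
distribution of a signal-free Rician background. Methods are compared
against a PRF reference with two-sided paired Wilcoxon signed-rank tests
(exact null distribution for n ≤ 12 pairs).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a 16 °C focal hot spot in the 105 mm quality-assurance phantom and
recover it without a baseline frame:

```python
import prfthermo as pt
from prfthermo.phantom import PhantomConfig, HotspotSpec, gen_phantom_series

cfg = PhantomConfig()                      # 96×96 @ 1.5 mm, SNR≈20 phantom
series, rois, truth = gen_phantom_series(
    cfg, hotspot=HotspotSpec(peak_deltaT=16.0), n_frames=2, seed=0
)

tmap = pt.referenceless_map(series, 1, rois, interpolator="thin_plate_spline")
inner = rois.mask("inner_roi")
print(f"peak dT = {tmap.delta_T[inner].max():.2f} C (truth {truth.delta_T[1].max():.1f} C)")

snr, mu, sigma = pt.compute_snr(
    series.magnitude[1], rois.mask("phantom"), rois.mask("background")
)
print(f"phantom SNR = {snr:.1f} (mu={mu:.1f}, sigma={sigma:.2f})")
print(f"rayleigh factor = {pt.rayleigh_noise_factor(10**6, seed=1):.4f}")
```

Output:

```
peak dT = 15.52 C (truth 16.0 C)
phantom SNR = 20.0 (mu=20.0, sigma=0.66)
rayleigh factor = 0.6552
```

The recovered peak sits within the noise of the injected 16 °C spot (the
acquisition carries complex Gaussian noise at σ_g = 1); the phantom SNR of
20 is the configured amplitude-to-noise ratio, with the background scatter
(0.66) showing the Rayleigh factor at work; and the Monte-Carlo estimate of
that factor reproduces √(2 − π/2) ≈ 0.655.

## Command line

```sh
prfthermo simulate   --seed 1 --peak 16 --out data/        # synthetic series
prfthermo snr        --data data/ --out snr.csv
prfthermo reconstruct --data data/ --kernel tps --out maps/
prfthermo compare    --data data/ --out compare.json
prfthermo run-study  --seed 1 --out study/                 # full pipeline
```

`run-study` chains simulate → SNR → reconstruction (classical PRF,
referenceless RBF kernels, polynomial) → paired comparison, and writes CSV
tables, PNG figures and a deterministic `summary.json`.

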