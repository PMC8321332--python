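# Methods

## The measurement model

`prfthermo` monitors focal heating in MR-guided focused-ultrasound (MRgFUS)
procedures from gradient-echo phase images. The water proton resonance
frequency shifts approximately linearly with temperature, with coefficient
α ≈ −0.01 ppm/°C in aqueous tissue, so a temperature change ΔT between two
acquisitions appears as a phase difference

    Δφ = 2π · γ · α·10⁻⁶ · B₀ · TE · ΔT

with γ = 42.576 × 10⁶ Hz/T the proton gyromagnetic ratio, B₀ the field
strength and TE the echo time. The inverse of this relation is the whole of
PRF thermometry; everything else in the package is about how Δφ is obtained.

Two routes are implemented:

* **Classical PRF** (`thermometry.classical_prf_map`): subtract the phase of
  a pre-heating baseline frame pixel-by-pixel. Subtraction is wrap-safe (the
  angle of the complex ratio), so both operands may be arbitrarily wrapped;
  only the principal value of the difference is available, which aliases
  |ΔT| beyond π/|2π γ α·10⁻⁶ B₀ TE| (≈ 78 °C at TE = 10 ms, B₀ = 1.5 T).
  No spatial or temporal unwrapping is attempted; pixels at the wrap
  boundary are counted in `extras["saturated_pixels"]` and passed through.

* **Referenceless PRF** (`thermometry.referenceless_map`): assume the
  background phase varies smoothly across the image, fit an interpolant to
  an unheated annulus (*outer* ROI) around the treated region, extrapolate
  it under the heated region (*inner* ROI) as the baseline estimate, and
  convert actual-minus-estimated phase as above. This avoids the baseline
  frame and hence inter-frame motion and drift artifacts, at the price of a
  background-smoothness assumption.

## RBF interpolation

The background interpolant is a radial basis function network

    s(X) = p_m(X) + Σᵢ λᵢ φ(‖X − Xᵢ‖₂)

fitted by solving the symmetric saddle-point system [[A, P], [Pᵀ, 0]]·[λ; c]
= [f; 0], which enforces interpolation at the nodes and the side conditions
Σᵢ λᵢ q(Xᵢ) = 0 for all polynomials q of degree ≤ m. Kernels: linear φ(r) =
r and thin-plate spline φ(r) = r² log r (both conditionally positive
definite, requiring a degree-1 tail and nodes not all on one line), Gaussian
exp(−(r/ρ)²) and multiquadric √(r² + ρ²) (positive definite, no tail
required). Node coordinates are physical millimetres (pixel index ×
spacing), so the shape parameter ρ is resolution-independent; its `"auto"`
default is the mean nearest-neighbour distance among centers.

Numerical choices:

* The system is solved with a pivoted least-squares factorisation (LAPACK
  `gelsy`). Condition numbers above 10¹² raise a warning; fits whose node
  residual exceeds 10⁻⁶ of the data range raise a `ConditioningError`
  carrying the condition estimate. Dense annuli of pixels produce notoriously
  ill-conditioned kernel matrices, which motivates both the pivoted solver
  and the cap on node count.
* Annulus pixels typically number in the hundreds to thousands; `fit_rbf`
  retains at most `max_nodes = 500` seeded-uniformly subsampled centers
  (identical seed → bit-identical model). Centers are fixed at data sites
  and output weights are solved linearly; no iterative optimisation of
  center positions is performed.
* Unisolvency is decided from the numerical rank of the monomial-basis
  matrix at the nodes; collinear nodes with a degree-1 kernel are rejected
  before assembly.

**Tail policy.** In `fit_rbf` the Gaussian and multiquadric kernels carry no
polynomial tail by default, matching their classical interpolation theory.
`estimate_background_phase`, however, enables the degree-1 tail for *all*
kernels by default: background estimation is extrapolation into a hole
roughly 15 mm across, and the tail is what carries planar phase trends (shim
gradients) across it. Without the tail, a pure multiquadric extrapolating an
exactly affine phase field into the inner ROI errs by ≈ 0.004 rad (≈ 0.1 °C
at the default conversion), an avoidable systematic; with the tail, affine
backgrounds are reproduced to machine precision. Callers wanting the
tail-free behaviour pass `include_tail=False`.

The polynomial alternative (`fit_polynomial_wls`) minimises
Σ wⱼ (p(Xⱼ) − fⱼ)² over the monomial basis, with a rank check on the
weighted design; it reproduces the classical "low-order polynomial fit to
the surrounding phase" approach against which the RBF network is compared.

## SNR estimation

With independent zero-mean Gaussian noise of standard deviation σ_g in each
complex channel, a signal-free magnitude region is Rayleigh distributed with
standard deviation σ_g √(2 − π/2) ≈ 0.655 σ_g. The estimator

    SNR = 0.655 · μ(object ROI) / σ(background ROI)

therefore rescales the measured background scatter back onto the Gaussian
component scale. Standard deviations use the population convention (divide
by N); the convention is recorded in every `SNRReport`. For 3D slabs each
slice is one depth row; per-slab figures average across slices.
`rayleigh_noise_factor` verifies the constant by direct simulation.
No Rician bias correction is applied to object-region means: at the SNR
levels where the estimator is trusted (≥ ~3) the bias is second-order, and
the correction addresses the background term only.

## The synthetic bench

Since no scanner data ship with the package, `phantom` generates the full
study bench: a 105 mm cylindrical tissue-mimicking phantom over a 3 mm skin
layer over a 10 mm gel pad, imaged as 3 s frames (96×96 at 1.5 mm default)
over a 16 mm slab, with a treatment schedule of 56 sonications of
20.0 ± 2.9 s and 2353 ± 611 J separated by 85 s cooling. Region amplitudes
default to phantom 20, skin 3, gel 2.5 signal units against complex noise
σ_g = 1, i.e. SNR ≈ 20 for the water-rich phantom and 2–4 for the fat-like
interface layers — low enough that referenceless thermometry on the
interface is noise-dominated by construction, which is the regime the
package is designed to study. Probe traces are sampled at 1 Hz with 0.05 °C
measurement noise (interferometric probes resolve 0.01 °C and respond in
under 1 s).

Heating is deliberately phenomenological: an isotropic Gaussian focal spot
(σ = 4 mm default) whose amplitude saturates as 1 − e^(−t/τ_rise)
(τ_rise = 8 s) during a sonication and decays as e^(−t/τ_decay)
(τ_decay = 20 s) afterwards, superposed across sonications. There is no
acoustic propagation, absorption, perfusion or heat-diffusion physics; the
generator reproduces the *shape* of heating/cooling curves and the spatial
confinement of the focus, not tissue thermodynamics. Consequently, passing
tests demonstrate correctness of the reconstruction and statistics chain —
not that the methods would succeed on in vivo data, where motion,
susceptibility drift and non-Gaussian artifacts dominate.

The inner ROI is the heated disc — taken out to the 1%-of-peak contour of
the Gaussian spot (≈ 3.03σ) — dilated by 2 pixels; the outer ROI is the
surrounding 8-pixel annulus clipped to the phantom. Extending the disc to
the 1% contour keeps residual heating under the baseline annulus below
0.02 °C for a 16 °C spot; with a tighter disc the spot's tail leaks into the
annulus and biases the background fit by ~0.2 °C. The background phase is
affine by default (0.3 + 0.01·y − 0.008·x rad with mm coordinates centred on
the image), with optional quadratic terms and linear temporal drift.

Every generator is deterministic per seed, and `gen_phantom_series` returns
a `TruthRecord` (background phase, per-frame ΔT field, noise σ) sufficient
to score any downstream reconstruction without regeneration.

## Statistics

Paired method comparisons use the two-sided Wilcoxon signed-rank test at
α = 0.05. Zero differences are dropped before ranking and ties receive
mid-ranks. For n ≤ 12 remaining pairs the null distribution is computed
exactly by convolution over the rank multiset (mid-ranks are doubled to
integers first); beyond that a tie-corrected normal approximation with
continuity correction is used, and the method is recorded in the result.
The tests are reported raw — no multiple-testing correction — with the
number of tests recorded alongside.

The comparison pairing axis is frames: each method contributes one inner-ROI
mean ΔT per frame, paired with the reference's value at the same frame.
Bias is the mean of the per-frame errors and RMSE their quadratic mean, so
RMSE ≥ |bias| always.

## Default study problem sizes

`run_study` images two sonications of the 56-sonication schedule — one weak
(0.5 °C peak) and one strong (16 °C peak) — as 10 frames of 96×96 pixels,
reconstructs with classical PRF, linear/thin-plate-spline/multiquadric
referenceless RBF and a degree-2 polynomial, and compares per-frame inner-ROI
means against the classical reference. These sizes keep a full study at a
few seconds on one core while leaving every fit at its default `max_nodes`;
the geometry and acquisition parameters are unchanged from the defaults
above.

## Known limitations

* Phase is fitted directly in radians; if the background phase wraps within
  the outer annulus the fit is invalid. The generators keep backgrounds
  inside (−π, π] across the ROI, but real data may need rewrapping first.
* No unwrapping means |ΔT| beyond ≈ 78 °C (at the default TE/B₀) aliases.
* The Gaussian/exponential heating model has no physical units of power;
  sonication energy only scales probe asymptotes, it does not drive the
  imaged hot spot.
* Referenceless accuracy degrades when heating leaks under the outer
  annulus; the ROI constructor controls this for the generator's Gaussian
  spots, but irregular real heating patterns require user-drawn ROIs.
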