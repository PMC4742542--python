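# Methods

## The forward model

`dwiphantom` simulates diffusion-weighted MRI from a voxel-wise
hindered/restricted/free multi-compartment model. Per voxel, volume
fractions of up to five isotropic tissue compartments (cGM, dGM, WM, CSF,
abnormal) and up to three fiber compartments form a convex-combination
weight vector: non-negative, summing to 1 inside the brain and 0 in the
background. The noise-free signal is

S(g, b) = S0 · [ Σᵢ Fᵢ exp(−b(λ⊥ + (λ∥−λ⊥)(g·vᵢ)²)) + Σⱼ Tⱼ exp(−b Dⱼ) ]

Assumptions worth stating explicitly:

* **Gaussian, axially symmetric fiber response.** Each fiber compartment is
  a cylinder-symmetric diffusion tensor; no cylinder-radius, exchange or
  time-dependence effects.
* **Mono-exponential isotropic compartments.** Hindered (tissue) and free
  (CSF) compartments decay as exp(−bD); no kurtosis or multi-exponential
  behavior.
* **Flat S0.** The non-weighted intensity is constant (default 1000 a.u.)
  across tissues: the phantom's contrast is purely diffusion-driven, with no
  T2 weighting per compartment.
* **No imaging chain.** No eddy currents, motion, ghosting or partial
  Fourier; the only artifacts modeled are Rician noise and an optional
  susceptibility-like warp.

## Default parameters

| parameter | default | units | notes |
|---|---|---|---|
| λ∥, λ⊥ (fiber kernel) | 2.2e-3, 0.2e-3 | mm²/s | axially symmetric tensor |
| D_WM, D_cGM, D_dGM | 2.0e-4, 7.0e-4, 9.0e-4 | mm²/s | hindered, isotropic |
| D_CSF | 3.0e-3 | mm²/s | free water |
| D_abnormal | none | mm²/s | must be set by the user if used |
| scheme | 100 dirs, 1 shell b=1000, 1 b=0 | s/mm² | uniform coverage |
| SNR | 30.0 | — | on mean in-brain b=0 |
| S0 | 1000.0 | a.u. | flat |
| voxel size | 2.0 | mm | isotropic, RAS+ |

All diffusivities, the kernel, the scheme and the SNR are user-configurable
through `RunConfig` / YAML.

## Model assembly from raw ingredients

`assemble_model` turns crude per-fiber fraction estimates, an FA map and a
tissue segmentation into a final model. The combination rule implemented
here is a documented stand-in (the original derivation is not fully
specified by the sources this design follows): the dominant fiber fraction
is inferred from FA rather than from its noisy direct estimate,

* F₁ = FA · T′_WM (clipped to [0, 1]),
* Fᵢ = F′ᵢ · T′_WM for i = 2, 3 (preserving their ratio),
* Σᵢ Fᵢ is capped at T′_WM by proportional rescaling — restricted
  compartments live inside white matter only,
* T_WM = T′_WM − Σᵢ Fᵢ; the other tissue fractions pass through,
* fractions are then normalized to sum to exactly 1 per brain voxel.

This is the simplest rule consistent with the constraints it must satisfy
(FA drives F₁; fibers confined to WM; convex weights). Normalizing to
exactly 1 (rather than leaving a signal-free residual compartment) was a
deliberate choice: it makes the b=0 signal equal S0 everywhere in the brain,
which the self-validation layer exploits. Non-local-means denoising of raw
maps is out of scope: the synthetic fixtures are generated already smooth.

## Gradient scheme design

Per shell, directions minimize the antipodally symmetric electrostatic
energy Σ 1/|vᵢ−vⱼ| + 1/|vᵢ+vⱼ|, the standard uniformity criterion for
diffusion sampling. The optimizer is L-BFGS on unconstrained coordinates
with analytic gradients projected through the normalization map (points are
renormalized to the sphere inside the objective), run from 20 seeded random
starts; the lowest-energy solution wins, making generation deterministic
given the seed. For n = 6 this reproduces the known optimum (icosahedral
antipodal pairs, minimal angle 63.43°); for n = 100 the minimal antipodal
angle exceeds 14°.

bvec convention: directions are stored and written in the world/scanner
frame, the same frame as the model's fiber direction fields — there is no
image-axis flip anywhere. This is the single largest source of silent sign
errors in dMRI tooling, so it is fixed and documented here.

## FOD representation

Fiber compartments can be projected onto a fiber orientation distribution:
a sum of antipodally symmetrized delta functions weighted by Fᵢ, truncated
to even degree L (default 8) in the orthonormal real spherical-harmonic
basis. The signal is then the spherical convolution of the FOD with the
kernel's rotational harmonics (computed by 64-point Gauss–Legendre
quadrature). The discrete tensor sum is exact, so it is the default
simulation path; the FOD path exists as the continuous-representation
equivalent and agrees with the discrete path to < 2% RMS at L = 8 for up to
three crossing fibers (measured ~0.02% for the default kernel at b = 1000 —
the kernel is smooth enough that order 8 is nearly converged).

## Noise

Rician: each sample becomes √((S+n₁)² + n₂²) with n₁, n₂ i.i.d. N(0, σ).
σ = (mean noise-free b=0 over voxels with fraction sum > 0.5) / SNR; the
in-brain mean b=0 is the conventional SNR reference when no region is
specified. Background magnitude is then Rayleigh(σ) with mean σ√(π/2),
which the SNR estimator inverts. Noise is seeded and reproducible;
SNR = ∞ returns the input unchanged.

## Distortion

Susceptibility-like warping is applied post-simulation (not to the
microstructural model): this keeps the ground truth identical between the
reference and distorted outputs of one run, which is what a
correction-method evaluation needs. The displacement field is a synthetic
Gaussian bump (default peak 6 mm, decaying below 1% of peak at 20 mm; both
configurable — real distortion fields are not Gaussian, this is a smooth,
controllable stand-in). Each volume is resampled along the phase-encode
axis by linear interpolation at the displaced coordinates and modulated by
the 1D Jacobian 1 + ∂d/∂x_pe (clipped at 0), giving first-order pile-up and
stretch while conserving total intensity away from the boundary. Edge
handling is clamping.

## Self-validation estimators

* Tensor fit: unweighted log-linear OLS on −ln(S/S0) = b gᵀDg. Unweighted
  (not WLS/iterated) because it is exact for noise-free tensor-generated
  signals, which is what the acceptance checks need. Negative eigenvalues
  from noisy fits are clamped to zero inside the FA computation only.
* ADC: least-squares slope of −ln(S/S_b0) vs b through the origin.
* SNR: σ̂ = mean(background b=0)/√(π/2); SNR̂ = mean(foreground b=0)/σ̂.
  Asymptotically unbiased; at ≥10⁴ background voxels the estimate is within
  a few percent of the configured value (the small Rician bias of the
  foreground mean, ≈ σ/(2·SNR), is negligible at SNR ≥ 10).

## Synthetic fixtures

The fixtures replace subject-derived microstructure so the whole pipeline
is testable without any external data:

* **single_voxel** — exact requested composition; all closed-form checks.
* **crossing_slab** — two straight bundles through the grid center at a
  configurable angle (peak fiber fraction 0.45 each) with cosine-tapered
  cross-sections; WM fills the remainder.
* **mini_brain** — crisp spherical head (radius 0.45·min(shape)), ~2.5-voxel
  cGM shell, central CSF sphere (0.15 R), two dGM nuclei (0.18 R), WM
  elsewhere; a straight bundle and an arc bundle (tangent direction field)
  carved out of the WM fraction. At 32³ this leaves ≈ 2·10⁴ background
  voxels for noise estimation.

What the fixtures do **not** emulate: real cortical folding, anatomically
plausible tract geometry, partial-volume statistics of real segmentations,
spatially varying S0/T2, or the noise correlations of accelerated
acquisitions. Tests passing on these fixtures therefore validate the signal
model, the noise model and the code paths — not performance on real brains.

## Numerical choices

* All attenuations computed in double precision; outputs stored as float64
  NIfTI, never quantized.
* Normalization zeroes voxels whose fraction sum is below 1e-6 instead of
  amplifying them.
* Direction-field invariants are enforced at 1e-6 (unit norms, fraction
  sums).
* Scheme optimizer: ftol 1e-14, gtol 1e-10, ≤2000 iterations, 20 restarts.
* Problem sizes in tests and the acceptance script: 32³ grids and 30–101
  volume schemes, chosen so the full validation runs on a laptop-class
  single core in well under a minute per check.

## Known limitations

* The FA→F₁ combination rule is a documented stand-in, not a validated
  biophysical mapping.
* The distortion model is a generic smooth warp, not a B0 field simulation;
  its default magnitude/extent are arbitrary and should be set per use case.
* Hindered compartments are purely mono-exponential and isotropic; no
  restricted-geometry (cylinder radius) effects.
* The abnormal-tissue compartment has no default diffusivity by design;
  simulating pathology requires an explicit user choice.
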