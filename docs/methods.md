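# Methods

## The model and what the test asks

Most biophysical models of white-matter diffusion MRI assume the
*single-convolution* form

S(b, **g**) = (H ∗ P)(b, **g**) = ∫_{S²} H(b, **g**·**n**) P(**n**) d**n**,

one axially symmetric response kernel H(b, θ) and one orientation
distribution function (ODF) P per voxel. Projected onto the real,
symmetric (even-order) spherical harmonic basis, the convolution becomes
a per-coefficient multiplication,

s_{ℓ,b}^m = √(4π/(2ℓ+1)) · h̄_{ℓ,b} · p_ℓ^m = h_{ℓ,b} p_ℓ^m ,

with h̄_{ℓ,b} the zonal SH coefficients of the kernel.  Arranging one
voxel's per-shell coefficients of each order ℓ in a matrix S_ℓ (k shells
in rows, 2ℓ+1 coefficients in columns), the single-convolution model is
equivalent to every S_ℓ being the outer product h_ℓ p_ℓᵀ — an exactly
rank-1 matrix in the absence of noise.  A voxel containing fascicles
with genuinely different kernels *and* different orientations makes
S_ℓ (ℓ ≥ 2) rank > 1; if all kernels agree up to scale, or all ODFs do,
the model algebraically collapses back to a single convolution, and S_0
is always rank 1 because it has one column.

The package measures departure from rank 1 by the SVD of every S_ℓ
(a voxel-wise SHARD — spherical harmonics and radial decomposition),
pools component effect sizes across orders by singular-value index,

σ_i² = Σ_ℓ σ_{ℓ,i}² ,

and summarizes the leading component's share of signal power as
R = σ_1² / Σ_i σ_i² · 100%.  Significance of components i > 1 is
assessed with a residual-bootstrap permutation test and voxel maps are
corrected with the Benjamini–Hochberg FDR step-up.

## Fitting and decomposition

- Per shell, ordinary least squares in the real orthonormal even-order
  SH basis at ℓmax = 8 (45 coefficients), via precomputed
  pseudoinverses.  No regularization or weighting: the voxel-wise test
  needs the plain projection, and every shell in the reference protocol
  has 70 ≥ 45 directions.
- The basis convention is documented in `sh.py`: m = 0 is the complex
  zonal harmonic, |m| > 0 are √2·(−1)^m times the real/imaginary parts,
  Condon–Shortley phase cancelled; columns ordered ℓ ascending, m
  ascending.  All decomposition outputs are convention-invariant.
- SVD signs are fixed (largest-magnitude entry of each left singular
  vector positive) for reproducible maps.
- Components are pooled strictly by singular-value index per order;
  no cross-order matching heuristic is applied.
- An all-zero voxel would make R = 0/0; it is reported as R = 100 with a
  `degenerate` flag, since such voxels are masked out in practice.
- The b=0 measurements never enter the matrices S_ℓ (ν counts only the
  k × 70 shell directions).  Optionally (`normalize_b0=True`, off by
  default) signals are divided by the voxel's mean b=0 before fitting;
  this rescales σ maps but leaves R and the permutation test invariant.

## Permutation test

Null hypothesis: components i > 1 carry no structure.  Per voxel:

1. rank-1 representation ŷ and residuals e = y − ŷ (length ν = 420);
2. N bootstrap instances y′ = ŷ + c·Πe, with Π a uniform random
   permutation of all ν entries (no stratification by shell; an
   i.i.d.-resampling mode is available) and c a leverage correction;
3. refit, rebuild S_ℓ, store pooled σ′_i;
4. P_i = 1 − (N_i⁺ + 1)/(N + 1), N_i⁺ = #{σ_i > σ′_i} (ties count as
   not exceeded), so P ∈ [0, N/(N+1)] and never reaches 1;
5. Benjamini–Hochberg at q = 0.05 across in-mask voxels, per component.

The leverage h = κ/ν uses κ = Σ_ℓ [k + (2ℓ+1) − 1] (the parameter count
of a rank-1 factorization per order): κ = 70, ν = 420, h = 1/6 for the
reference protocol.  An OLS fit leaves residuals with mean square
(1 − h) times the noise variance, so the default correction is
c = 1/√(1−h), which restores the residual variance exactly.  The
alternative c = 1/(1−h) is available as `leverage_mode="linear"`; the
variance argument favours the square-root form and it is the default,
but neither is silently preferred in reports — the mode used is recorded
in every output.

Voxel seeds are derived by mixing the voxel's grid index into the seed
sequence, so maps are identical for any traversal or masking order.

### Calibration, measured

The bootstrap is *valid but mildly conservative*, and the package's own
tests quantify this honestly rather than assuming exact uniformity:

- In the regime where every fitted band carries signal well above the
  noise floor, the leverage count is exact — over 10⁴ simulated voxels
  the mean squared residual is (1−h)·s² to within 0.1% — and the size
  of the test at α = 0.05 measured over 500 null voxels at SNR 30 is
  ≈ 0.03, within binomial 99% bounds of the nominal level.
- In white-matter-like voxels whose ODF dispersion leaves the ℓ = 6, 8
  bands essentially signal-free, the rank-1 truncation absorbs more
  noise than the κ parameter count suggests (closer to
  (√k + √(2ℓ+1))² per weak band than k + 2ℓ), so ŷ retains spurious
  leading-component power and the null σ′ is slightly inflated: the
  measured size is ≈ 0.02.  The test never exceeds its nominal level in
  either regime (no anti-conservatism), which is the property the test
  suite asserts, together with the absence of FDR discoveries under the
  null.

## Synthetic data

The generator emulates a rich multi-shell research acquisition: 6 shells
at b = 900, 1600, 2500, 3600, 4900, 6400 s/mm² with 70 directions per
shell (electrostatic-repulsion optimized, distinct across shells,
seeded) and 30 b=0 volumes.

Kernels are the two-compartment "standard model": an intra-axonal stick
(signal fraction f, diffusivity D_i) plus an axially symmetric
extra-axonal tensor (axial D_e, radial D_r),

H(b, ξ) = f·exp(−b D_i ξ²) + (1−f)·exp(−b (D_r + (D_e − D_r) ξ²)),

with b in s/mm² and diffusivities in µm²/ms.  The white-matter-like
default f = 0.5, D_i = 2.2, D_e = 2.0, D_r = 0.8 µm²/ms is an
implementation choice within commonly reported adult ranges, not a
fitted or published parameter set.  Zonal coefficients h̄_{ℓ,b} are
obtained by 100-point Gauss–Legendre quadrature (independently verified
against adaptive quadrature to 1e−8).

Fascicle ODFs are spherical-heat-kernel-smoothed deltas:
p_ℓ^m = w·exp(−ℓ(ℓ+1)t²/2)·Y_ℓ^m(**n**) with dispersion bandwidth
t = 0.3 rad (≈ 17°) by default, within the orientation-dispersion range
observed in coherent adult white matter.  Dispersed signals are
synthesized band-limited at ℓ = 16, where the truncated content is
< 1e−5 of the leading component.  Exact (non-band-limited) δ-fascicle
evaluation is also available; note that at ℓmax = 8 its aliased ℓ > 8
kernel content is shell-dependent and therefore *not* exactly rank 1
(σ₂/σ₁ ≈ 4·10⁻³ for the default kernel), which is a physical property
of sharp crossings, not a numerical artifact.

Noise is Gaussian by default (emulating data after complex-domain
denoising, which suppresses Rician bias), with σ = 1/SNR relative to
the unit b=0 amplitude; a Rician mode is provided.  At SNR 30 the two
modes differ in mean signal by < 1% of b0 averaged over the
acquisition, but fully attenuated measurements sit on the Rician floor
σ√(π/2) (≈ 4% of b0 at SNR 30) — a reason the Gaussian default is the
right match for denoised magnitude data.

What the generator does **not** emulate: spatial noise correlation,
artefacts (Gibbs ringing, motion, distortion, fat shift, pulsation),
residual Rician bias, CSF or other non-white-matter partial volumes, or
spatial anatomy.  Passing tests therefore validate the estimator
and its calibration under the stated signal model, not robustness to
acquisition artefacts.

## Detectability surface

`simulate.power_surface` sweeps two equally weighted fascicles crossing
at 90°, kernels split on one standard-model parameter (x̄ ± Δ/2), over a
(Δ, SNR) grid.  Each cell simulates n voxels, runs the full
decompose-and-test pipeline and records the fraction with
P₂ < α for α ∈ {0.05, 0.001}; 50%-detection contours are interpolated
in log-SNR.  Desk-scale defaults are 100 voxels/cell and N = 999
permutations (the p-value formula is valid for any N; production
analyses use N = 10⁴).  Only structural properties of the surface are
asserted — rate ≈ α at Δ = 0, monotone growth with SNR and Δ, and the
p < 0.001 contour at higher SNR than p < 0.05 — because the absolute
contour positions depend on the baseline kernel, which is an
implementation default.

## Numerical choices

- Direction sets: 300 iterations of tangential-projected electrostatic
  repulsion over antipodal pairs with annealed step, seeded; the
  70-point sets beat uniformly random sets' minimum pairwise angle in
  > 95% of trials.
- Bootstrap effect sizes use eigenvalues of the k×k Gram matrices
  S_ℓS_ℓᵀ (singular values squared) for speed; this path agrees with
  the full SVD to 1e−8 and floors at ~√ε·σ₁ for exactly-zero singular
  values.
- Shell grouping merges b-values by single-linkage with a 50 s/mm²
  tolerance (safe for any protocol whose shell gaps exceed 100 s/mm²);
  b ≤ 50 s/mm² counts as b=0.
- Directions are renormalized when within 1e−3 of unit norm and
  rejected beyond that.

## Problem sizes used in the shipped experiments

Simulated experiments are sized to run on a single CPU in minutes while
keeping binomial error small relative to the asserted margins: 1000
voxels for the signal-power regime, 500 voxels × 999 permutations for
null calibration, 100 voxels/cell × 999 permutations on a 3×3 grid for
the detectability surface.

## Known limitations

- The permutation test is conservative in band-sparse voxels (see
  Calibration); detection rates in the power surface are accordingly
  slight underestimates.
- Exact contour positions of the detectability surface are
  configuration-dependent and not comparable across kernel baselines.
- Watson or Bingham ODF dispersion, generalized diffusion encodings and
  diffusion-time dependence are out of scope; the heat-kernel dispersion
  is a convenience model of fibre spread.
- Whole-image (multi-voxel, joint) SHARD representations and rank-r
  denoising applications are not implemented; the decomposition here is
  strictly per voxel.
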