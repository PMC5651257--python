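# Methods

## The model

`morphocode` treats an anatomical surface as a deformation of a common
template. A deformation is parameterized by an *initial momentum* field
p0 — one 3-vector per template vertex — which generates a diffeomorphic
flow by geodesic shooting under a Gaussian reproducing kernel
K(dx) = exp(−|dx|²/2σ²), σ = 6.5 mm by default. The template vertices xᵢ
and momenta pᵢ evolve as the Hamiltonian particle system

    dxᵢ/dt = v(xᵢ) = Σⱼ K(xᵢ − xⱼ) pⱼ,
    dpᵢ/dt = −Dv(xᵢ)ᵀ pᵢ,            t ∈ [0, 1],

with Dv evaluated analytically (∇K(dx) = −(dx/σ²) K(dx)). Because momenta
live in a vector space, population statistics are Gaussian-friendly even
though diffeomorphisms are not.

A population of momenta is summarized by tangent-space PCA under the
kernel (dual-space) inner product ⟨p, q⟩_K = Σ_ab pₐᵀ K(xₐ − x_b) q_b:
mean b0, a kernel-orthonormal basis {bᵢ}, and a variance spectrum {σᵢ²},
retaining the smallest number of modes whose cumulative variance reaches
95% of the covariance trace. A shape is then p0 = b0 + Σ βᵢ bᵢ with
independent βᵢ ~ N(0, σᵢ²).

The coefficients β are *discretized* with a random codebook. For
independent Gaussians under squared error, the optimal rate-distortion
trade-off is the reverse water-filling solution: per-dimension distortion
Dᵢ = min(λ, σᵢ²) with λ chosen so Σ Dᵢ = D, giving
R(D) = Σᵢ ½ log₂(σᵢ²/Dᵢ) bits. A codebook of 2^(NR) codewords for blocks
of N shapes draws component i from N(0, σᵢ² − λ) above the water level
and sets it to exactly zero below; encoding maps β to the nearest
codeword in squared Euclidean distance, which equals the squared
kernel-metric error of the momentum restricted to the basis span (the
basis is orthonormal in that metric).

Finally, geometric accuracy is tied to code rate: both the sampled and
the decoded momenta are shot to surfaces, compared with the symmetric
vertex-set Hausdorff distance (max over both surfaces of each vertex's
distance to the closest vertex of the other; correspondence-free), and
the mean error per rate is inverted to report the code rate required at a
target accuracy in mm.

## Numerical choices

- **Integrator.** Fixed-step RK4 with 10 steps over t ∈ [0, 1]. The
  Hamiltonian H = ½ Σᵢⱼ pᵢᵀ K(xᵢ − xⱼ) pⱼ is recorded at every step; at
  momenta producing ~5 mm displacements the relative drift is ~1e-9 and
  shrinks ~16× per step-halving, confirming 4th-order behaviour. Zero
  momentum short-circuits to the exact identity.
- **Metric PCA.** Cholesky whitening of the vertex Gram matrix
  (G = LLᵀ; p ↦ Lᵀp is an isometry onto Euclidean coordinates), ordinary
  SVD of the whitened centered data, and back-substitution. This yields
  kernel-orthonormality by construction and avoids a generalized
  eigenproblem. Covariance divisor M − 1; modes below 1e-12 of the
  leading eigenvalue are treated as rank noise; a 1e-10 jitter is added
  (once, logged) if G is numerically singular. PCA uses the kernel
  metric because the basis's stated orthonormality is with respect to the
  dual-space inner product.
- **Water-filling.** Bisection on λ (monotone in both directions:
  distortion at fixed λ, rate at fixed λ), bracket [0, max σᵢ²], 200
  iterations, final rescale so Σ Dᵢ = D to 1e-9 relative. Requested
  distortion above the total variance clamps to the zero-rate solution.
  Rates are inverted with the bracket lower bound λ = max σᵢ² · 4^(−R),
  which guarantees the target rate is enclosed.
- **Codebooks.** One documented RNG seed per codebook; encoding is
  deterministic with ties broken toward the lowest index. The default
  size cap is 2²⁰ codewords (20 bits at N=1); larger codes are supported
  by raising the cap. Batch encoding uses the |s|² − 2s·c + |c|²
  expansion in chunks of 2¹⁴ codewords.
- **Rate-at-scale fit.** err(R) = a·2^(−bR) + c with a, b, c ≥ 0 by
  bounded least squares; a descriptive fit through the data, not a model.
  Targets at or above the fitted rate-0 error clamp to 0 bits; targets
  below the asymptote c raise an error rather than extrapolate; if the
  fit does not converge the pipeline falls back to monotone linear
  interpolation, flagged in the fit record.

## The synthetic generator

Real subcortical-surface populations (template estimation, segmentation,
registration) are out of scope; the `synthetic` module generates study
populations with known ground truth instead:

- **Template:** an icosphere (10·4ⁿ + 2 vertices) scaled to semi-axes
  20 × 12 × 10 mm — the extent of a hippocampus-sized structure. Default
  2 subdivisions (162 vertices).
- **Basis:** kernel-smoothed white-noise momentum fields,
  Gram-Schmidt-orthonormalized under ⟨·,·⟩_K (double pass; near-dependent
  draws are redrawn).
- **Spectrum:** σᵢ² = s·i^(−γ), default γ = 1 and s = 9. The scale was
  calibrated once so that shooting typical prior draws displaces the
  template by 1–5 mm (measured mean Hausdorff displacement 1.9 mm, range
  0.8–4.0 mm), matching the millimeter accuracy scales under study.
- **Population:** i.i.d. coefficients βᵢ ~ N(0, σᵢ²); b0 = 0 by default
  so the template is the mean shape (a nonzero mean is supported).

What the generator does **not** emulate: real segmentation noise,
registration error in estimated momenta, non-Gaussian or multimodal
population structure, inter-structure covariance, and meshes with
anatomical vertex densities (~1000 vertices). Passing tests therefore
validate the coding machinery and its statistical behaviour under the
model's own assumptions, not the fidelity of the Gaussian momentum model
to real anatomy.

## Problem sizes

Default experiments use the 162-vertex template, 5 modes, rates 0–10
bits in steps of 2, 25 observations per rate, and 500-subject populations
for prior recovery; Monte Carlo distortion checks use 2000–20000 draws.
These sizes keep every experiment deterministic, oracle-checked and fast
while exercising the same machinery as a full-scale study; rates up to
32 bits are supported by raising the codebook size cap.

## Known limitations

- Random Gaussian codebooks attain the R(D) bound only asymptotically in
  the block size N. At very low rates (≈2 bits per structure) the N=2
  block code is measurably *worse* per structure than N=1 (≈10% in mean
  distortion at 2000-sample precision) — a finite-blocklength penalty
  invisible at coarse error bars; from ~4 bits upward N=2 is strictly
  better, and both straddle the theoretical curve from above.
- Individual PCA eigenvectors are identifiable only where eigengaps are
  large relative to sampling noise (≈√(λᵢλⱼ)/|λᵢ−λⱼ|·√(2/M)); recovery
  checks for closely spaced modes must compare subspaces, not vectors.
- The error floor of the rate-error curve depends on the retained-mode
  truncation and the random-code overhead; targets below that floor are
  reported as unreachable rather than extrapolated.
- The ambient flow is integrated only at template vertices; decoded
  shapes are compared by vertex clouds, so the metric ignores surface
  interpolation between vertices.
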