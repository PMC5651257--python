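# morphocode

**How many bits does it take to describe the shape of a brain structure at
millimeter accuracy?**

`morphocode` answers this question for populations of anatomical surfaces
described by a Bayesian shape prior. It is aimed at computational-anatomy /
diffeomorphometry researchers who already have a template surface and
per-subject LDDMM initial momenta (or want to simulate them) and wish to
quantify the *complexity* of a shape population: the code rate R, in bits,
required to reproduce a random shape from the population to within a given
geometric error in mm.

## The method

1. **Shape model.** Each subject is a deformation of a template surface,
   parameterized by an initial momentum field p0 (one 3-vector per template
   vertex) and generated by geodesic shooting under a Gaussian kernel
   (σ = 6.5 mm): ẋᵢ = Σⱼ K(xᵢ−xⱼ)pⱼ, ṗᵢ = −Dvᵀ(xᵢ)pᵢ.
2. **Empirical prior.** Tangent-space PCA of the momenta under the kernel
   inner product ⟨p,q⟩_K = Σ_ab pₐᵀK(xₐ−x_b)q_b gives
   p0 = b0 + Σᵢ βᵢbᵢ with independent βᵢ ~ N(0, σᵢ²), keeping the modes
   that capture 95% of the covariance trace.
3. **Discrete coding.** For independent Gaussians the optimal rate at
   distortion D is R(D) = Σᵢ ½log₂(σᵢ²/Dᵢ) with Dᵢ = min(λ, σᵢ²) by reverse
   water-filling. A random codebook with 2^(NR) codewords (component i ~
   N(0, σᵢ²−λ) above the water level, 0 below) approaches this bound;
   encoding maps β to its nearest codeword.
4. **Complexity at scale.** Shooting both the sampled and the decoded
   momenta and measuring the vertex Hausdorff distance yields geometric
   error as a function of rate; inverting a fitted err(R) = a·2^(−bR) + c
   curve reports the bits required at 1.0 and 1.5 mm.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

No input data are required — the `synthetic` module generates a template
(an ellipsoidal icosphere, 20 × 12 × 10 mm) and a population with a known
5-mode prior:

```sh
morphocode demo --seed 7 --out demo --subjects 100 --n-obs 10
```

prints (abridged):

```
prior: 5 modes retained, total variance 19.719
 rate_bits  mean_error_mm  stderr_mm
         0       1.969424   0.238542
         2       1.468841   0.200350
         4       1.421815   0.200799
         6       1.026057   0.118413
         8       0.808957   0.065373
        10       0.472388   0.052362
5.90 bits required at 1 mm
2.40 bits required at 1.5 mm
```

Reading this: a 0-bit code (every subject replaced by the mean shape) errs
by ~2 mm on average; 10-bit codes (1024 candidate anatomies) reduce the
mean Hausdorff error to ~0.5 mm; the fitted curve says ~6 bits suffice for
1 mm accuracy and ~2.4 bits for 1.5 mm on this synthetic population. For
perspective, a 100³ binary voxel mask costs ~10⁶ bits and the mesh itself
~192,000 bits, so a handful of bits is a drastic compression.

The same pipeline runs on real data via the library or the subcommands
`fit-prior` (template + per-subject momentum files → prior directory),
`make-codebook`, `encode`/`decode`, `rd-curve`, `rate-error` and
`rate-at-scale`; every run writes a `manifest.json` from which its outputs
are reproducible bit-for-bit.

```python
import morphocode as mc

prior = mc.make_ground_truth_prior(mc.SyntheticSpec(seed=7))
curve = mc.rate_error_experiment(prior, rates=[0, 2, 4, 6, 8, 10],
                                 n_obs=10, seed=7)
print(mc.fit_rate_at_error(curve, target_mm=1.0).rate_bits)
```

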