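# Methods

## Model

A parallel-beam acquisition of a square slice x (N×N pixels) produces a
sinogram d with one row per projection angle θ ∈ [0, π) and one column per
detector bin s. Detector-borne artifacts add an offset to fixed columns of
d that is constant (or slowly varying) in angle and becomes a ring after
reconstruction. We model the data as d = P x + R u + noise, where P is the
projector, u is a length-n_bins vector of per-bin offsets and R u
broadcasts u to every angle row. Reconstruction solves

    min_{x,u}  ½‖C (P x + R u − d)‖²  +  β·TV(x)  +  β_r·‖u‖₁        (TV prior)

or, with a patch-dictionary prior,

    min_{W,u}  ½‖C (P S(W) + R u − d)‖²  +  ρ·h(W)  +  β·‖W‖₁  +  β_r·‖u‖₁

where S(W) synthesizes the slice from overlapping patches and h penalizes
disagreement between overlapping patch reconstructions. The L1 penalty on u
encodes the prior that only a few detector bins are defective; β_r → ∞
recovers the ordinary solver with no ring correction.

Assumptions: the artifact is additive and angle-constant per bin (bands are
handled as several adjacent bins); the rotation center used by P matches
the acquisition; noise is homoscedastic Gaussian (L2 fidelity).

## Optimization

Both problems are solved with FISTA on the stacked variable v = (x, u) (or
(W, u)): a gradient step of length 1/L on the smooth part, a proximal step
on the non-smooth part, and momentum t_{k+1} = (1 + √(1+4t_k²))/2. Because
the fidelity couples the blocks only through the residual, the prox is
separable: TV denoising (or soft thresholding of W) on the first block and
soft thresholding with threshold β_r/L on u. An optional restart on energy
increase exists but is off by default; the iteration count is fixed
(`n_iter`) rather than tolerance-controlled, so runs are exactly
reproducible.

The fidelity carries a ½ factor so that the gradient is exactly
A^T C^T C (A v − d) with A = [P, R]; this is a pure rescaling of β and β_r
relative to writing the squared norm without ½.

**Step size.** L is the largest eigenvalue of the augmented normal operator
[C·P, C·R]^T [C·P, C·R], computed by a power method on the actual operator
stack (100 iterations or relative change < 1e−9, fixed-seed start vector).
The ring block contributes R^T R = n_angles·I, which the operator product
reflects automatically. Unit tests check the estimate against a dense
eigendecomposition on a toy geometry.

**Preconditioning.** Back-projected residuals over-represent low spatial
frequencies; the preconditioner reweights them with the band-limited ramp
filter (spatial kernel ¼ at lag 0, −1/(π²n²) at odd lags, 0 at even lags;
applied by FFT with zero-padding to ≥ 2·n_bins so there is no circular
wrap). The kernel is even, so the per-row filter matrix is symmetric, and
its frequency response is strictly positive — in particular the DC gain is
small but nonzero, so the constant component of the residual is damped, not
discarded. We define the preconditioned fidelity as the quadratic form
½⟨r, F r⟩ with F this one-pass ramp (i.e. C = F^{1/2} conceptually): the
gradient then back-projects a ramp-filtered residual — a filtered
back-projection — and one preconditioned gradient step from zero
initialization equals FBP(d) up to the scalar π/(n_angles·L). The ring
gradient uses the same filtered residual, summed over angles per bin.

**Initialization** is x = 0, u = 0 (an FBP warm start is available via
`warm_start_fbp`). With the `rings=False` switch the u-update is skipped
while every other floating-point operation is unchanged, so a run with an
effectively infinite β_r matches the frozen-u run bit for bit — a useful
regression property and the cleanest definition of "correction off".

## Projector

P is a Joseph-style discretization: for each angle the ray steps along its
dominant axis with unit steps, linearly interpolating the transverse
coordinate between the two neighbouring pixels, weighted by the path length
1/max(|cosθ|, |sinθ|); rays leaving the support contribute zero. The pair
(geometry, N) is assembled once into a scipy.sparse CSR matrix and cached;
the backprojector is the literal transpose, so the adjoint dot-test holds
to rounding error — a requirement for the convergence theory of FISTA, and
the reason an independently discretized pixel-driven backprojector was not
used. Image center is pixel ((N−1)/2, (N−1)/2); the rotation center
defaults to bin (n_bins−1)/2 and may be any real bin coordinate.

## TV prox and power method

Isotropic TV uses forward differences with Neumann boundary (zero
difference at the last row/column). Its prox is solved on the dual by
accelerated projected gradient (Chambolle/FGP form) with dual step 1/8, the
2-D gradient operator's squared-norm bound. The default inner budget is 20
iterations per outer FISTA step — enough because the prox input changes
little between consecutive outer iterations; the inner count and an
optional relative-change tolerance are exposed in `TVParams`. At 100 inner
iterations the denoising objective is within 1e−4 of a 10×-longer reference
run on random 8×8 inputs, which the suite verifies.

The power method returns the largest eigenvalue of a symmetric PSD
operator via the Rayleigh quotient of the iterates; estimates are
non-decreasing across iterations and deterministic given the seed.

## Patch model

Patches of size w (default 8) are laid on a regular grid with stride w/2
(50% overlap); the grid must tile the image exactly. Synthesis
overlap-averages the per-patch reconstructions W·D; analysis is its exact
adjoint (cover-normalized extraction correlated with the atoms). The
overlap-coherence term is the pairwise squared disagreement
h = Σ_pixels Σ_{i<j} (v_i − v_j)² between the patch reconstructions
covering each pixel — two patches sharing one pixel with values a, b
contribute (a−b)² — with analytic gradient 2(k·v_i − Σ_j v_j). h is a
homogeneous quadratic, so its Hessian action equals its gradient map,
which the Lipschitz power method exploits.

The dictionary is trained offline by standard K-SVD: OMP sparse coding
(scikit-learn's `orthogonal_mp`) at a fixed per-patch sparsity alternated
with rank-1 SVD atom updates; unused atoms are re-seeded with the
worst-approximated patch; atom signs are canonicalized for determinism.
The training corpus is generated in-repo (piecewise-constant and textured
disk phantoms). On patches drawn exactly from a planted 8-atom dictionary
at sparsity 1, training recovers all atoms to mean |cosine| > 0.99.

## Synthetic data

Phantoms are random disk compositions inside a 0.45·N support circle
(values 0.3–1.0 on a zero background), optionally with smooth random
texture, or with genuine ring-shaped features (a filled black disk and a
one-pixel-wide bright annulus at radius 0.33·N) that a correct method must
preserve. Three corruption presets mirror increasing difficulty: (1)
constant stripes, (2) stripes whose intensity varies smoothly with angle
(low-order random cosine series, bounded in [0, amplitude]), (3) stripes —
one of them two bins wide — on the ring-featured phantom. Defaults are
128×128 pixels, 180 angles, six stripes of amplitude 5% of max(d) placed
at well-separated bins in the central 70% of the detector; everything is
deterministic given the seed. These sizes make a full 500-iteration study
run in tens of seconds on one CPU while leaving the stripe-to-feature
scale comparable to practice.

What the generator does *not* emulate: photon (Poisson) noise, detector
gain drift, partial rings (arcs), beam hardening, or miscalibrated rotation
centers. Passing tests therefore demonstrate correct recovery of additive,
angle-constant (or smoothly varying) stripe corruption under ideal
counting statistics — not robustness to every experimental failure mode.

Quality metrics: PSNR = 10·log10(peak²/MSE) with peak = max(ref) − min(ref)
(+inf for identical images), and a stripe-energy statistic — the per-bin
column mean minus its 9-bin median trend, summed in magnitude over the
corrupted bins — which isolates sharp detector lines from smooth genuine
structure. The median detrending matters when judging the wavelet–Fourier
baseline: the approximation band retains a low-frequency smear of a
removed stripe that is invisible as a ring but would dominate a naive
column-mean difference.

## Wavelet–Fourier destriper (comparator)

`munch_destripe` decomposes the sinogram with a 2-D DWT (symmetric
extension), filters each vertical-detail band along the angle axis with the
high-pass Gaussian gain 1 − exp(−k²/(2σ²)) — the DC gain is 0, removing the
angle-constant component of each band — and reconstructs. Defaults σ = 3.5,
two levels, Daubechies-15. It is linear in the data and approximately
idempotent. This is a pre-processing technique: it alters d itself, which
is exactly what the joint formulation avoids.

## Parameter guidance

- β (TV weight): 1e−3 for the packaged 128×128 scenarios; scales with the
  fidelity term, so halving the preconditioner response or the data scale
  requires rescaling β.
- β_r (ring L1 weight): 1e−1 default. Larger values shrink |u| and can
  leave residual rings; values ≳ the sup-norm of the ring gradient freeze
  u at zero entirely.
- ρ (overlap coherence, DL solver): 0.05 with 50% overlap; 0 disables the
  term (patch seams may appear).
- n_iter: 300–500 for the packaged scenarios. Ring-corrected runs need
  more iterations than correction-off runs to reach the same relative
  energy tolerance — the augmented problem is larger and its spectrum
  flatter — which the suite checks as an ordering property.

## Numerical choices and degenerate inputs

Float64 throughout. Non-finite sinograms, shape mismatches, out-of-range
stripe bins, empty dictionaries and non-tiling patch grids raise
`ValueError` at construction. A zero sinogram yields zero reconstructions
exactly (0 is the unique minimizer when the data are zero). The power
method returns 0 for the zero operator; a zero Lipschitz constant aborts
reconstruction with a degenerate-geometry error. Soft thresholding of
±0.0 is treated as exact zero. The prox-TV dual variable starts at zero,
so a single inner iteration already guarantees the denoising objective
does not exceed the objective at the input.

## Known limitations

- Angle-constant model only: stripes whose intensity varies strongly with
  angle are captured approximately (their angle-mean component); a
  per-angle stripe model is out of scope.
- Fixed iteration budget rather than a convergence criterion; energy
  traces are returned so callers can implement their own stopping rule.
- The sparse projector matrix costs O(n_angles·n_bins·N) memory; fine to
  ~512², not intended for 3-D or GPU-scale problems.
- The K-SVD trainer is the standard algorithm, not an enhanced variant;
  dictionary quality was not the sensitive ingredient in our studies (a
  single dictionary serves all scenarios).
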