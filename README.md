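# ringtomo

Compressed-sensing tomographic reconstruction with **ring-artifact
correction built into the optimization**.

Ring artifacts are concentric circles in a reconstructed CT slice caused by
detector flaws (dead pixels, scintillator dust, monochromator vibration).
Because they are tied to fixed detector bins, they appear in the sinogram as
lines that are (nearly) constant along the projection angle. Classical
remedies either filter the sinogram before reconstruction or scrub circles
from the slice afterwards — both can damage genuine structure. `ringtomo`
instead decomposes the data *inside* the reconstruction: the acquired
sinogram `d` is modelled as

    d ≈ P x + R u

where `P` is the parallel-beam projector, `x` the slice, `u` a per-detector-
bin offset vector, and `R` replicates `u` across all angles. Both unknowns
are estimated jointly by minimizing

    E(x, u) = ½ ‖C (P x + R u − d)‖² + β · TV(x) + β_r · ‖u‖₁

with FISTA. The L1 penalty keeps `u` sparse — only genuinely corrupted bins
are claimed by the ring vector — while the Total Variation prior (or,
alternatively, an L1-sparse patch/dictionary model) regularizes the slice.
Because the quadratic fidelity is separable across the two blocks, each
FISTA iteration applies TV denoising to the image block and plain soft
thresholding to the ring block. `C` is an optional ramp-filter
preconditioner: `C^T C` equals one application of the band-limited ramp
filter (with nonzero DC gain), so the preconditioned gradient is a filtered
back-projection of the residual and a single iteration from a zero start
reproduces classical FBP.

The package is a tool for people doing iterative reconstruction of
parallel-beam (synchrotron-style) tomography who need ring suppression
without modifying their raw data: the corrupted bins and their amplitudes
come out explicitly in `u`.

## What is inside

| module | contents |
| --- | --- |
| `ringtomo.geometry` | Joseph-interpolation projector `P`, exact-transpose backprojector, discrete ramp filter, FBP |
| `ringtomo.prox` | isotropic TV, dual-accelerated TV prox, soft thresholding, power method |
| `ringtomo.solvers` | joint (x, u) FISTA solvers with TV and dictionary priors, preconditioning, Lipschitz estimation |
| `ringtomo.dictionary` | overlapping patch synthesis/analysis, overlap-coherence penalty, K-SVD trainer |
| `ringtomo.synthetic` | phantoms, the three stripe-corruption scenarios, PSNR / stripe-energy metrics |
| `ringtomo.baselines` | wavelet–Fourier (Münch-style) sinogram destriper used as comparator |
| `ringtomo.io`, `ringtomo.cli` | TIFF/.npy/YAML I/O and the `ringtomo` command line |

## Worked example

Generate the packaged "constant stripes" scenario (128×128 phantom, 180
projections, six spurious lines at 5% of the sinogram maximum), reconstruct
with the TV + rings solver, and compare with the destriping baseline:

```bash
ringtomo make-fixtures --case 1 --size 128 --angles 180 --seed 0 --outdir demo
ringtomo reconstruct --sino demo/sino_corrupted.tif --algo tv \
    --beta 1e-3 --beta-rings 0.1 --n-iter 500 \
    --angles demo/geometry.yaml --output demo/rec_tv.tif \
    --save-rings demo/u.txt --log demo/trace.csv
ringtomo destripe --sino demo/sino_corrupted.tif --sigma 3.5 --levels 2 \
    --output demo/destriped.tif
```

prints

```
Case-1 fixtures written to demo
TV reconstruction written to demo/rec_tv.tif (final energy 2.08239, 7 nonzero ring bins)
Destriped sinogram written to demo/destriped.tif
```

The stripes were injected at bins 21, 32, 57, 63, 84, 102 (see
`demo/stripes.txt`), each with amplitude 3.12. Inspecting the result:

```python
import numpy as np
from ringtomo import io as rio
from ringtomo.synthetic import psnr

rec = rio.read_raster("demo/rec_tv.tif")
phantom = rio.read_raster("demo/phantom.tif")
u = rio.read_ring_vector("demo/u.txt")
print("PSNR vs phantom: %.2f dB" % psnr(phantom, rec))
print("largest |u| bins:", np.argsort(np.abs(u))[-6:][::-1])
```

```
PSNR vs phantom: 39.86 dB
largest |u| bins: [ 21 102  32  84  57  63]
```

The six largest ring-vector entries sit exactly at the six corrupted bins:
the solver attributed the stripes to `u` instead of painting rings into the
slice. Running the same solver with the ring vector frozen at zero
(`--no-rings`) drops the PSNR by well over 3 dB, and the energy trace in
`demo/trace.csv` (per-iteration fidelity, TV, ring-L1 and total) shows the
monotone decrease of the objective.

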