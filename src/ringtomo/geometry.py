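"""Parallel-beam projection geometry and operators.

The forward projector ``P`` is a Joseph-style (linear-interpolation,
ray-driven) discretization of the 2-D Radon transform, assembled once per
(geometry, image size) pair as a sparse matrix; the back-projector is its
exact transpose, so the pair passes an adjoint dot-test to rounding error.
A band-limited discrete ramp filter (nonzero DC gain) provides the
high-pass preconditioner and, combined with back-projection, standard
filtered back-projection (FBP).

Conventions: the image is N×N with rotation axis at pixel
((N−1)/2, (N−1)/2); detector bins are 0-based with real-valued
``rotation_center`` (default (n_bins−1)/2); angles lie in [0, π). A pixel
(row i, col j) has Cartesian coordinates x = j − cx, y = i − cy, and the
ray of bin s at angle θ is the line x·cosθ + y·sinθ = s − rotation_center.
Rays that leave the image support contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ProjectionGeometry",
    "Image2D",
    "Sinogram",
    "project",
    "projection_matrix",
    "backproject",
    "ramp_filter",
    "ramp_kernel",
    "fbp",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Acquisition geometry: projection angles and detector layout.

    Parameters
    ----------
    angles_rad : tuple of float
        Strictly increasing projection angles θ in radians, in [0, π).
    n_bins : int
        Number of detector bins (≥ 2).
    rotation_center : float
        Real-valued center bin, 0-based; defaults to (n_bins − 1)/2.
    """

    angles_rad: tuple[float, ...]
    n_bins: int
    rotation_center: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_rad)
        object.__setattr__(self, "angles_rad", angles)
        if len(angles) == 0:
            raise ValueError("need at least one projection angle")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("angles must be strictly increasing")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.rotation_center is None:
            object.__setattr__(self, "rotation_center", (self.n_bins - 1) / 2.0)
        if not 0.0 <= self.rotation_center <= self.n_bins - 1:
            raise ValueError("rotation_center outside the detector")

    @property
    def n_angles(self) -> int:
        return len(self.angles_rad)

    @classmethod
    def uniform(cls, n_angles: int, n_bins: int,
                rotation_center: float | None = None) -> "ProjectionGeometry":
        """Evenly spaced angles covering [0, π)."""
        angles = tuple(np.pi * k / n_angles for k in range(n_angles))
        return cls(angles, n_bins, rotation_center)


@dataclass
class Image2D:
    """A square reconstruction slice."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("image must be a square 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class Sinogram:
    """Projection data: one row per angle, one column per detector bin."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram must be 2-D")
        if self.values.shape != (self.geometry.n_angles, self.geometry.n_bins):
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_angles} angles × {self.geometry.n_bins} bins)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")


@lru_cache(maxsize=16)
def projection_matrix(geom: ProjectionGeometry, n: int) -> sp.csr_matrix:
    """Sparse Joseph projector mapping flat N² images to flat sinograms.

    For each angle the ray is stepped along its dominant axis with unit
    steps; the transverse coordinate is linearly interpolated between the
    two neighbouring pixels and the path-length factor 1/max(|cosθ|,|sinθ|)
    weights every sample.
    """
    cx = cy = (n - 1) / 2.0
    t = np.arange(geom.n_bins) - geom.rotation_center  # detector coordinate
    rows, cols, vals = [], [], []
    for a, theta in enumerate(geom.angles_rad):
        c, s = np.cos(theta), np.sin(theta)
        if abs(c) >= abs(s):
            # step along image rows (y); interpolate along columns (x)
            i = np.arange(n)
            y = i - cy
            jj = (t[:, None] - y[None, :] * s) / c + cx  # (n_bins, n)
            w = 1.0 / abs(c)
            j0 = np.floor(jj).astype(np.int64)
            frac = jj - j0
            row_idx = a * geom.n_bins + np.broadcast_to(
                np.arange(geom.n_bins)[:, None], jj.shape)
            pix_row = np.broadcast_to(i[None, :], jj.shape)
            for jn, wgt in ((j0, (1.0 - frac) * w), (j0 + 1, frac * w)):
                ok = (jn >= 0) & (jn < n) & (wgt != 0)
                rows.append(row_idx[ok])
                cols.append(pix_row[ok] * n + jn[ok])
                vals.append(wgt[ok])
        else:
            # step along image columns (x); interpolate along rows (y)
            j = np.arange(n)
            x = j - cx
            ii = (t[:, None] - x[None, :] * c) / s + cy  # (n_bins, n)
            w = 1.0 / abs(s)
            i0 = np.floor(ii).astype(np.int64)
            frac = ii - i0
            row_idx = a * geom.n_bins + np.broadcast_to(
                np.arange(geom.n_bins)[:, None], ii.shape)
            pix_col = np.broadcast_to(j[None, :], ii.shape)
            for inn, wgt in ((i0, (1.0 - frac) * w), (i0 + 1, frac * w)):
                ok = (inn >= 0) & (inn < n) & (wgt != 0)
                rows.append(row_idx[ok])
                cols.append(inn[ok] * n + pix_col[ok])
                vals.append(wgt[ok])
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_angles * geom.n_bins, n * n),
    )
    return mat.tocsr()


def project(img: Image2D, geom: ProjectionGeometry) -> Sinogram:
    """Forward-project a slice: row θ holds line integrals along direction θ."""
    if not isinstance(img, Image2D):
        img = Image2D(np.asarray(img))
    mat = projection_matrix(geom, img.size)
    values = (mat @ img.pixels.ravel()).reshape(geom.n_angles, geom.n_bins)
    return Sinogram(values, geom)


def backproject(sino: Sinogram, n: int | None = None) -> Image2D:
    """Apply the exact adjoint P^T of :func:`project`.

    ``n`` is the output image side; defaults to ``n_bins`` of the geometry.
    """
    if n is None:
        n = sino.geometry.n_bins
    mat = projection_matrix(sino.geometry, n)
    pixels = (mat.T @ sino.values.ravel()).reshape(n, n)
    return Image2D(pixels)


@lru_cache(maxsize=32)
def ramp_kernel(n_bins: int) -> np.ndarray:
    """Band-limited spatial-domain ramp kernel over lags −(n_bins−1)…(n_bins−1).

    h(0) = 1/4, h(n) = −1/(π²n²) for odd n, 0 for even n ≠ 0. Its DC gain
    (the lag-sum) is positive for any finite support, which is the property
    the preconditioner relies on.
    """
    lags = np.arange(-(n_bins - 1), n_bins)
    h = np.zeros(lags.shape, dtype=np.float64)
    h[lags == 0] = 0.25
    odd = (lags % 2) != 0
    h[odd] = -1.0 / (np.pi ** 2 * lags[odd].astype(np.float64) ** 2)
    return h


@lru_cache(maxsize=32)
def _ramp_response(n_bins: int) -> np.ndarray:
    """Real FFT response of the ramp kernel on a wrap-free padded grid."""
    m = int(2 ** np.ceil(np.log2(max(2 * n_bins, 4))))
    h = ramp_kernel(n_bins)
    padded = np.zeros(m)
    # kernel centered at 0 with negative lags wrapped to the end
    padded[: n_bins] = h[n_bins - 1 :]
    padded[m - (n_bins - 1) :] = h[: n_bins - 1]
    return np.fft.rfft(padded)


def _ramp_rows(values: np.ndarray, preserve_dc: bool) -> np.ndarray:
    n_bins = values.shape[-1]
    resp = _ramp_response(n_bins).copy()
    m = 2 * (resp.size - 1)
    if not preserve_dc:
        resp[0] = 0.0
    spec = np.fft.rfft(values, n=m, axis=-1)
    out = np.fft.irfft(spec * resp, n=m, axis=-1)
    return out[..., :n_bins]


def ramp_filter(sino: Sinogram, preserve_dc: bool = True) -> Sinogram:
    """Convolve every sinogram row with the discrete ramp kernel.

    Linear convolution via FFT with zero-padding to ≥ 2·n_bins (no circular
    wrap). With ``preserve_dc`` (the default) the zero-frequency gain is the
    kernel's own small positive value; setting it False forces DC to zero.
    The resulting per-row operator is a symmetric Toeplitz matrix, so the
    filter is self-adjoint.
    """
    return Sinogram(_ramp_rows(sino.values, preserve_dc), sino.geometry)


def fbp(sino: Sinogram, n: int | None = None) -> Image2D:
    """Filtered back-projection: backproject(ramp_filter(sino)) · π/n_angles."""
    filtered = ramp_filter(sino)
    img = backproject(filtered, n=n)
    img.pixels *= np.pi / sino.geometry.n_angles
    return img
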