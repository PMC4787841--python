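"""Phantoms, stripe-corruption regimes, and image-quality metrics.

Everything the test-suite and the demo pipelines consume is generated
here, deterministically from a seed: piecewise-constant disk phantoms,
textured variants, phantoms carrying genuine ring-shaped features (a
filled disk and a thin annulus that a correct reconstruction must keep),
and three sinogram-corruption scenarios of increasing difficulty —
constant detector lines, lines with angle-varying intensity, and stripes
on top of a ring-featured phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import Image2D, ProjectionGeometry, Sinogram, project

__all__ = [
    "StripeSpec",
    "PhantomSpec",
    "Scenario",
    "make_phantom",
    "inject_stripes",
    "variable_profile",
    "psnr",
    "stripe_energy",
    "annulus_mask",
    "make_scenario",
]

PHANTOM_KINDS = ("piecewise_disks", "textured", "with_ring_features")


@dataclass
class StripeSpec:
    """One spurious detector line (or band, for width > 1).

    ``amplitude`` is either a scalar (constant along angle) or a per-angle
    profile array (variable-intensity case).
    """

    bin: int
    amplitude: float | np.ndarray
    width: int = 1

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("stripe width must be >= 1")


@dataclass
class PhantomSpec:
    kind: str = "piecewise_disks"
    size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.size < 16:
            raise ValueError("phantom size must be >= 16")


def _radius_grid(n: int) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(xx - c, yy - c)


def annulus_mask(n: int, radius: float, width: float = 1.5) -> np.ndarray:
    """Boolean mask of pixels within ``width`` of the given center radius."""
    return np.abs(_radius_grid(n) - radius) <= width


def make_phantom(spec: PhantomSpec) -> Image2D:
    """Deterministic synthetic slice.

    piecewise_disks    — uniform support disk plus random constant disks
    textured           — the same plus smooth random texture inside the support
    with_ring_features — adds a filled black disk and a thin bright annulus
                         that belong to the object (must survive correction)
    """
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    r = _radius_grid(n)
    support_r = 0.45 * n
    img = np.zeros((n, n))
    img[r <= support_r] = 0.3

    c = (n - 1) / 2.0
    for _ in range(6):
        rr = rng.uniform(0.05, 0.18) * n
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, support_r - rr - 1)
        cx, cy = c + rad * np.cos(ang), c + rad * np.sin(ang)
        yy, xx = np.mgrid[0:n, 0:n]
        mask = np.hypot(xx - cx, yy - cy) <= rr
        img[mask] = rng.uniform(0.4, 1.0)

    if spec.kind == "textured":
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.standard_normal((n, n)), sigma=1.2)
        img[r <= support_r] += 0.12 * tex[r <= support_r] / np.abs(tex).max()
        img = np.clip(img, 0.0, None)
    elif spec.kind == "with_ring_features":
        ang = rng.uniform(0, 2 * np.pi)
        rr = 0.08 * n
        rad = rng.uniform(0.1, 0.3) * n
        cx, cy = c + rad * np.cos(ang), c + rad * np.sin(ang)
        yy, xx = np.mgrid[0:n, 0:n]
        img[np.hypot(xx - cx, yy - cy) <= rr] = 0.0  # genuine black disk
        img[annulus_mask(n, 0.33 * n, width=1.5)] = 1.0  # genuine thin ring
    return Image2D(img)


def variable_profile(
    n_angles: int, amplitude: float, seed: int, n_modes: int = 3
) -> np.ndarray:
    """Smooth per-angle stripe intensity: a low-order random cosine series.

    The profile is bounded by ±amplitude and has mean amplitude/2, so a
    variable stripe never changes sign relative to its constant analogue.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, np.pi, n_angles, endpoint=False)
    prof = np.zeros(n_angles)
    for m in range(1, n_modes + 1):
        prof += rng.uniform(-1, 1) * np.cos(m * t + rng.uniform(0, 2 * np.pi))
    prof /= max(np.abs(prof).max(), 1e-12)
    return amplitude * (0.5 + 0.5 * prof)


def inject_stripes(
    sino: Sinogram, stripes: Sequence[StripeSpec], seed: int = 0
) -> tuple[Sinogram, np.ndarray]:
    """Additively corrupt a sinogram with spurious detector lines.

    Returns the corrupted sinogram together with the injected corruption
    field, so the original is exactly ``corrupted − field``. Scalar
    amplitudes are replicated over all angles; array amplitudes give the
    per-angle profile. ``seed`` is unused for fully specified stripes but
    kept for symmetry with the other generators.
    """
    n_angles, n_bins = sino.values.shape
    field_arr = np.zeros_like(sino.values)
    for sp in stripes:
        if not 0 <= sp.bin < n_bins:
            raise ValueError(f"stripe bin {sp.bin} outside detector [0, {n_bins})")
        if sp.bin + sp.width > n_bins:
            raise ValueError("stripe band extends past the detector edge")
        amp = np.asarray(sp.amplitude, dtype=np.float64)
        if amp.ndim == 0:
            col = np.full(n_angles, float(amp))
        elif amp.shape == (n_angles,):
            col = amp
        else:
            raise ValueError("amplitude must be scalar or one value per angle")
        field_arr[:, sp.bin : sp.bin + sp.width] += col[:, None]
    return Sinogram(sino.values + field_arr, sino.geometry), field_arr


def psnr(ref: Image2D | np.ndarray, test: Image2D | np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak = max(ref) − min(ref).

    Identical images return +inf.
    """
    a = ref.pixels if isinstance(ref, Image2D) else np.asarray(ref, float)
    b = test.pixels if isinstance(test, Image2D) else np.asarray(test, float)
    if a.shape != b.shape:
        raise ValueError("psnr requires same-shape images")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    peak = float(a.max() - a.min())
    return 10.0 * np.log10(peak ** 2 / mse)


def stripe_energy(values: np.ndarray, bins: Sequence[int],
                  detrend_width: int = 9) -> float:
    """Residual stripe strength at the given detector bins.

    A spurious line shows up as a sharp excursion of the per-bin column
    mean from its local trend; the trend is estimated by a median filter
    of ``detrend_width`` bins, and the absolute detrended deviations are
    summed over ``bins``. Smooth (genuine) sinogram structure contributes
    almost nothing, so the statistic isolates the stripes.
    """
    from scipy.signal import medfilt

    col_mean = np.asarray(values, dtype=np.float64).mean(axis=0)
    dev = col_mean - medfilt(col_mean, detrend_width)
    return float(np.abs(dev[np.asarray(bins, dtype=int)]).sum())


@dataclass
class Scenario:
    """A packaged corruption study: phantom, clean and corrupted data."""

    case: int
    phantom: Image2D
    geometry: ProjectionGeometry
    clean: Sinogram
    corrupted: Sinogram
    corruption_field: np.ndarray
    stripes: list[StripeSpec] = field(default_factory=list)

    @property
    def stripe_bins(self) -> np.ndarray:
        bins = []
        for sp in self.stripes:
            bins.extend(range(sp.bin, sp.bin + sp.width))
        return np.array(sorted(bins))


def _pick_stripe_bins(rng: np.random.Generator, n_bins: int, n_stripes: int,
                      min_gap: int = 4) -> np.ndarray:
    """Well-separated bins inside the central 70% of the detector.

    Sampling is gap-shifted (draw sorted distinct values from a contracted
    range, then spread them by the minimum gap), so it terminates for any
    feasible (n_bins, n_stripes) combination.
    """
    lo, hi = int(0.15 * n_bins), int(0.85 * n_bins)
    span = hi - (n_stripes - 1) * (min_gap - 1)
    if span - lo < n_stripes:
        raise ValueError(
            f"cannot place {n_stripes} stripes with gap {min_gap} in "
            f"{n_bins} detector bins"
        )
    base = np.sort(rng.choice(np.arange(lo, span), size=n_stripes, replace=False))
    return base + np.arange(n_stripes) * (min_gap - 1)


def make_scenario(
    case: int,
    size: int = 128,
    n_angles: int = 180,
    seed: int = 0,
    n_stripes: int = 6,
    amplitude_frac: float = 0.05,
) -> Scenario:
    """The three corruption regimes, deterministic given the seed.

    case 1 — piecewise-constant phantom, constant stripes of amplitude
             ``amplitude_frac``·max(d)
    case 2 — same phantom, stripes with smooth angle-varying intensity
    case 3 — phantom carrying genuine ring-shaped features, plus variable
             stripes (one of width 2)
    """
    if case not in (1, 2, 3):
        raise ValueError("case must be 1, 2 or 3")
    kind = "with_ring_features" if case == 3 else "piecewise_disks"
    phantom = make_phantom(PhantomSpec(kind=kind, size=size, seed=seed))
    geom = ProjectionGeometry.uniform(n_angles, size)
    clean = project(phantom, geom)
    amp = amplitude_frac * float(clean.values.max())
    rng = np.random.default_rng(seed + 1)
    bins = _pick_stripe_bins(rng, size, n_stripes)
    stripes = []
    for i, b in enumerate(bins):
        width = 2 if (case == 3 and i == 0) else 1
        if case == 1:
            amplitude: float | np.ndarray = amp
        else:
            amplitude = variable_profile(n_angles, amp, seed=seed + 10 + i)
        stripes.append(StripeSpec(bin=int(b), amplitude=amplitude, width=width))
    corrupted, field_arr = inject_stripes(clean, stripes, seed=seed)
    return Scenario(case, phantom, geom, clean, corrupted, field_arr, stripes)
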