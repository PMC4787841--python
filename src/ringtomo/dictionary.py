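"""Patch-based sparse model of the slice.

The image is covered by overlapping square patches; each patch is a
linear combination of learned unit-norm atoms and the slice is
synthesized by overlap-averaging the per-patch reconstructions. A
quadratic coherence penalty discourages disagreement between overlapping
patches. The dictionary itself is trained offline with K-SVD
(orthogonal-matching-pursuit sparse coding alternated with rank-1 SVD
atom updates).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from sklearn.linear_model import orthogonal_mp

from .geometry import Image2D

__all__ = [
    "Dictionary",
    "PatchGrid",
    "PatchCoefficients",
    "patch_synthesize",
    "patch_analyze",
    "overlap_coherence",
    "sparse_code",
    "learn_dictionary",
    "save_dictionary",
    "load_dictionary",
]


@dataclass
class Dictionary:
    """Atoms φ_k, one per row, each a flattened w×w patch of unit L2 norm."""

    atoms: np.ndarray  # (n_atoms, w*w)
    patch_size: int

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2 or self.atoms.shape[0] < 1:
            raise ValueError("need a 2-D atom matrix with at least one atom")
        if self.atoms.shape[1] != self.patch_size ** 2:
            raise ValueError("atom length does not match patch_size²")
        norms = np.linalg.norm(self.atoms, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero atom in dictionary")
        self.atoms = self.atoms / norms[:, None]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]


@dataclass(frozen=True)
class PatchGrid:
    """Regular patch lattice covering an N×N image exactly."""

    image_size: int
    patch_size: int
    stride: int

    def __post_init__(self) -> None:
        n, w, s = self.image_size, self.patch_size, self.stride
        if w > n:
            raise ValueError("patch larger than image")
        if s < 1:
            raise ValueError("stride must be >= 1")
        if (n - w) % s != 0:
            raise ValueError(
                f"stride {s} does not tile an image of size {n} with patches of {w}"
            )

    @classmethod
    def cover(cls, image_size: int, patch_size: int, stride: int) -> "PatchGrid":
        return cls(image_size, patch_size, stride)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(0, self.image_size - self.patch_size + 1, self.stride)

    @property
    def n_patches(self) -> int:
        return len(self.positions) ** 2


@dataclass
class PatchCoefficients:
    """Per-patch atom weights W, rows ordered row-major over the grid."""

    W: np.ndarray  # (n_patches, n_atoms)
    grid: PatchGrid

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[0] != self.grid.n_patches:
            raise ValueError("coefficient rows do not match the patch grid")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite patch coefficients")


@lru_cache(maxsize=16)
def _grid_indices(grid: PatchGrid) -> tuple[np.ndarray, np.ndarray]:
    """Flat pixel indices per patch (n_patches, w²) and the cover count map."""
    n, w = grid.image_size, grid.patch_size
    pos = grid.positions
    local = (np.arange(w)[:, None] * n + np.arange(w)[None, :]).ravel()
    origins = (pos[:, None] * n + pos[None, :]).ravel()
    idx = origins[:, None] + local[None, :]
    cover = np.bincount(idx.ravel(), minlength=n * n).astype(np.float64)
    return idx, cover


def patch_synthesize(W: PatchCoefficients, D: Dictionary) -> Image2D:
    """Overlap-averaged slice: each pixel is the mean of the per-patch values."""
    grid = W.grid
    if D.patch_size != grid.patch_size:
        raise ValueError("dictionary patch size does not match the grid")
    idx, cover = _grid_indices(grid)
    V = W.W @ D.atoms  # (n_patches, w²) per-patch reconstructions
    acc = np.bincount(idx.ravel(), weights=V.ravel(),
                      minlength=grid.image_size ** 2)
    return Image2D((acc / cover).reshape(grid.image_size, grid.image_size))


def patch_analyze(img: Image2D, D: Dictionary, grid: PatchGrid) -> PatchCoefficients:
    """Exact adjoint of :func:`patch_synthesize`.

    Extracts the cover-normalized image over every patch and correlates it
    with the atoms, so ⟨S(W), g⟩ = ⟨W, analyze(g)⟩ holds to rounding.
    """
    if img.size != grid.image_size:
        raise ValueError("image size does not match the grid")
    idx, cover = _grid_indices(grid)
    g = (img.pixels.ravel() / cover)[idx]  # (n_patches, w²)
    return PatchCoefficients(g @ D.atoms.T, grid)


def overlap_coherence(
    W: PatchCoefficients, D: Dictionary
) -> tuple[float, PatchCoefficients]:
    """Pairwise squared disagreement between overlapping patch reconstructions.

    h = Σ_pixels Σ_{i<j} (v_i − v_j)² over the patches covering each pixel
    (two patches sharing one pixel with values a, b contribute (a−b)²).
    Returns (h, ∂h/∂W); both are zero for a non-overlapping grid.
    """
    grid = W.grid
    if D.patch_size != grid.patch_size:
        raise ValueError("dictionary patch size does not match the grid")
    idx, cover = _grid_indices(grid)
    if grid.stride >= grid.patch_size:
        return 0.0, PatchCoefficients(np.zeros_like(W.W), grid)
    V = W.W @ D.atoms
    n2 = grid.image_size ** 2
    sum_v = np.bincount(idx.ravel(), weights=V.ravel(), minlength=n2)
    sum_v2 = np.bincount(idx.ravel(), weights=(V ** 2).ravel(), minlength=n2)
    # Σ_{i<j}(v_i−v_j)² = k·Σv² − (Σv)² per pixel
    h = float((cover * sum_v2 - sum_v ** 2).sum())
    field = 2.0 * (cover[idx] * V - sum_v[idx])  # ∂h/∂v per patch pixel
    grad = PatchCoefficients(field @ D.atoms.T, grid)
    return h, grad


def sparse_code(patches: np.ndarray, D: Dictionary, sparsity: int) -> np.ndarray:
    """OMP coefficients (n_patches, n_atoms) with ≤ sparsity nonzeros per row."""
    coef = orthogonal_mp(D.atoms.T, patches.T, n_nonzero_coefs=sparsity)
    coef = np.atleast_2d(coef)
    if coef.shape[0] != D.n_atoms:
        coef = coef.T
    return coef.T.astype(np.float64)


def _extract_training_patches(images, w: int) -> np.ndarray:
    out = []
    for img in images:
        a = img.pixels if isinstance(img, Image2D) else np.asarray(img, float)
        win = np.lib.stride_tricks.sliding_window_view(a, (w, w))
        out.append(win.reshape(-1, w * w))
    return np.concatenate(out, axis=0)


def learn_dictionary(
    training_images,
    n_atoms: int,
    w: int = 8,
    sparsity_target: int = 4,
    n_epochs: int = 10,
    seed: int = 0,
) -> Dictionary:
    """Train a unit-norm dictionary by K-SVD.

    Alternates OMP sparse coding at ``sparsity_target`` with sequential
    rank-1 SVD updates of every atom (jointly re-fitting the coefficients
    of the patches that use it). Atoms never used in an epoch are replaced
    by the currently worst-approximated training patch. Deterministic
    given ``seed``.
    """
    patches = _extract_training_patches(training_images, w).astype(np.float64)
    if patches.shape[0] < 10 * n_atoms:
        raise ValueError("need at least 10 training patches per atom")
    if float(patches.std()) == 0.0:
        raise ValueError("degenerate (constant) training data")
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(patches, axis=1)
    candidates = np.flatnonzero(norms > 1e-12 * norms.max())
    init = rng.choice(candidates, size=n_atoms, replace=False)
    atoms = patches[init] / norms[init][:, None]
    D = Dictionary(atoms.copy(), w)

    Y = patches.T  # (w², n_patches)
    for _ in range(n_epochs):
        X = sparse_code(patches, D, sparsity_target).T  # (n_atoms, n_patches)
        A = D.atoms.T  # (w², n_atoms), column atoms
        for k in range(D.n_atoms):
            users = np.flatnonzero(X[k] != 0)
            if users.size == 0:
                resid_norm = np.linalg.norm(Y - A @ X, axis=0)
                j = int(np.argmax(resid_norm))
                a = Y[:, j]
                na = np.linalg.norm(a)
                if na > 0:
                    A[:, k] = a / na
                continue
            Ek = Y[:, users] - A @ X[:, users] + np.outer(A[:, k], X[k, users])
            U, s, Vt = np.linalg.svd(Ek, full_matrices=False)
            a = U[:, 0]
            if a[np.argmax(np.abs(a))] < 0:  # deterministic sign
                a = -a
                Vt = -Vt
            A[:, k] = a
            X[k, users] = s[0] * Vt[0]
        D = Dictionary(A.T.copy(), w)
    return D


def save_dictionary(D: Dictionary, path: str | Path) -> None:
    """Flat whitespace text array plus a small sidecar header (.meta)."""
    path = Path(path)
    np.savetxt(path, D.atoms)
    path.with_suffix(path.suffix + ".meta").write_text(
        f"n_atoms {D.n_atoms}\npatch_size {D.patch_size}\n"
    )


def load_dictionary(path: str | Path) -> Dictionary:
    path = Path(path)
    meta = dict(
        line.split() for line in
        path.with_suffix(path.suffix + ".meta").read_text().splitlines() if line
    )
    atoms = np.loadtxt(path).reshape(int(meta["n_atoms"]), -1)
    return Dictionary(atoms, int(meta["patch_size"]))
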