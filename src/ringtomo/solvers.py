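"""Joint slice + ring-vector reconstruction by preconditioned FISTA.

The acquired sinogram ``d`` is modelled as ``d ≈ P x + R u`` where ``P``
is the parallel-beam projector, ``x`` the slice, ``u`` a per-detector-bin
offset vector and ``R`` the operator replicating ``u`` across all angles
(its adjoint is the column-wise sum over angles). Spurious detector lines
— constant along the projection angle — are absorbed into ``u`` instead of
being filtered out of the data, so the ring correction is part of the
reconstruction itself. The energy minimized under the TV prior is

    E(x, u) = ½‖C(P x + R u − d)‖² + β·TV(x) + β_r·‖u‖₁

with ``C`` an optional ramp-filter preconditioner (``C^T C`` equals one
application of the symmetric band-limited ramp, so the preconditioned
gradient backprojects a ramp-filtered residual — a filtered
back-projection — and one preconditioned step from zero reproduces FBP).
Because the quadratic coupling is only through the fidelity, the proximal
step is separable: TV denoising on the image block and soft thresholding
on the ring block. A dictionary-learning variant replaces the TV prior by
an L1 penalty on patch coefficients plus a smooth overlap-coherence term,
requiring a single FISTA loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dictionary import (
    Dictionary,
    PatchCoefficients,
    PatchGrid,
    overlap_coherence,
    patch_analyze,
    patch_synthesize,
)
from .geometry import (
    Image2D,
    ProjectionGeometry,
    Sinogram,
    backproject,
    fbp,
    project,
    projection_matrix,
    ramp_filter,
)
from .prox import LinearOperatorSpec, TVParams, power_method, prox_tv, soft_threshold

__all__ = [
    "RingVector",
    "SolverConfig",
    "ReconResult",
    "replicate_rings",
    "rings_adjoint",
    "fidelity_grad",
    "estimate_lipschitz",
    "energy_tv",
    "energy_dl",
    "reconstruct_tv_rings",
    "reconstruct_dl_rings",
]


@dataclass
class RingVector:
    """Per-detector-bin additive offsets, constant along the angle axis."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 1:
            raise ValueError("ring vector must be 1-D")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("ring vector contains non-finite values")


@dataclass
class SolverConfig:
    """Reconstruction settings.

    beta            — weight of the spatial prior (TV seminorm, or L1 on
                      patch coefficients for the DL solver)
    beta_rings      — L1 weight β_r on the ring vector u
    n_iter          — outer FISTA iterations (fixed count; no default
                      tolerance-based stop)
    precondition    — ramp-filter the residual inside gradient and energy
    inner_tv        — settings of the nested TV-denoising subproblem
    lipschitz_iters — power-method iterations for the step size 1/L
    seed            — seed of the power-method start vector
    rings           — False freezes u at zero (correction off) while
                      keeping the identical arithmetic path, so runs with
                      an effectively infinite β_r match it bitwise
    overlap_weight  — weight ρ of the smooth patch-overlap coherence term
                      (DL solver only)
    restart         — restart FISTA momentum when the energy increases
    """

    beta: float = 1e-3
    beta_rings: float = 1e-2
    n_iter: int = 300
    precondition: bool = True
    inner_tv: TVParams = field(default_factory=lambda: TVParams(weight=1.0, n_inner=20))
    lipschitz_iters: int = 100
    seed: int = 0
    rings: bool = True
    overlap_weight: float = 1.0
    restart: bool = False
    warm_start_fbp: bool = False

    def __post_init__(self) -> None:
        if self.beta < 0 or self.beta_rings < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class ReconResult:
    """Joint reconstruction output: slice, ring vector, diagnostics."""

    x: Image2D
    u: RingVector
    energy_trace: np.ndarray
    corrected_sinogram: Sinogram
    energy_terms: np.ndarray | None = None  # columns: fidelity, prior, ring_l1
    coefficients: "PatchCoefficients | None" = None


def replicate_rings(u: np.ndarray, n_angles: int) -> np.ndarray:
    """R u: add the same per-bin offset row to every angle."""
    return np.broadcast_to(u, (n_angles, u.shape[0])).copy()


def rings_adjoint(residual: np.ndarray) -> np.ndarray:
    """R^T r: column-wise sum over angles (so R^T R = n_angles · I)."""
    return residual.sum(axis=0)


def _filter_residual(r: np.ndarray, geom: ProjectionGeometry,
                     precondition: bool) -> np.ndarray:
    if not precondition:
        return r
    return ramp_filter(Sinogram(r, geom)).values


def fidelity_grad(
    x: Image2D,
    u: RingVector,
    d: Sinogram,
    precondition: bool = True,
) -> tuple[Image2D, RingVector]:
    """Gradient of the (optionally preconditioned) fidelity at (x, u).

    Residual r = P x + R u − d. Without preconditioning the result is
    (P^T r, R^T r); with it the residual is first passed through the
    symmetric ramp filter (C^T C r), so the image gradient is a filtered
    back-projection of the residual and the ring gradient is the per-bin
    sum of the filtered residual over angles.
    """
    geom = d.geometry
    if u.u.shape[0] != geom.n_bins:
        raise ValueError("ring vector length does not match detector bins")
    r = project(x, geom).values + replicate_rings(u.u, geom.n_angles) - d.values
    fr = _filter_residual(r, geom, precondition)
    gx = backproject(Sinogram(fr, geom), n=x.size)
    gu = rings_adjoint(fr)
    return gx, RingVector(gu)


def _normal_op(geom: ProjectionGeometry, n: int, precondition: bool,
               with_rings: bool = True):
    """(x,u) ↦ A^T C^T C A (x,u) with A = [P, R] on the stacked vector."""
    mat = projection_matrix(geom, n)
    n_img = n * n

    def apply(v: np.ndarray) -> np.ndarray:
        x = v[:n_img]
        s = (mat @ x).reshape(geom.n_angles, geom.n_bins)
        if with_rings:
            s = s + replicate_rings(v[n_img:], geom.n_angles)
        fs = _filter_residual(s, geom, precondition)
        out_x = mat.T @ fs.ravel()
        if not with_rings:
            return out_x
        return np.concatenate([out_x, rings_adjoint(fs)])

    size = n_img + (geom.n_bins if with_rings else 0)
    return LinearOperatorSpec(apply, (size,))


def estimate_lipschitz(
    geom: ProjectionGeometry,
    n: int,
    precondition: bool = True,
    cfg: SolverConfig | None = None,
    with_rings: bool = True,
) -> float:
    """Largest eigenvalue of the augmented normal operator [CP, CR]^T[CP, CR].

    Depends only on the geometry, the image side ``n`` and the
    preconditioning flag — never on the sinogram content. Deterministic
    given the configured seed.
    """
    cfg = cfg or SolverConfig()
    op = _normal_op(geom, n, precondition, with_rings)
    return power_method(op, n_iter=cfg.lipschitz_iters, tol=1e-9, seed=cfg.seed)


def _fidelity_value(r: np.ndarray, geom: ProjectionGeometry,
                    precondition: bool) -> float:
    # ½⟨r, C^T C r⟩; the ramp response is nonnegative so this is ≥ 0
    fr = _filter_residual(r, geom, precondition)
    return 0.5 * float(np.vdot(r.ravel(), fr.ravel()).real)


def energy_tv(x: Image2D, u: RingVector, d: Sinogram, cfg: SolverConfig) -> float:
    """E = ½‖C(Px+Ru−d)‖² + β·TV(x) + β_r·‖u‖₁ (C = identity if unpreconditioned)."""
    from .prox import tv_norm

    geom = d.geometry
    r = project(x, geom).values + replicate_rings(u.u, geom.n_angles) - d.values
    return (
        _fidelity_value(r, geom, cfg.precondition)
        + cfg.beta * tv_norm(x.pixels)
        + cfg.beta_rings * float(np.abs(u.u).sum())
    )


def _energy_terms_tv(r, x_pix, u, geom, cfg):
    from .prox import tv_norm

    fid = _fidelity_value(r, geom, cfg.precondition)
    prior = cfg.beta * tv_norm(x_pix)
    ring = cfg.beta_rings * float(np.abs(u).sum())
    return fid, prior, ring


def reconstruct_tv_rings(d: Sinogram, cfg: SolverConfig, n: int | None = None) -> ReconResult:
    """TV-regularized reconstruction with joint ring estimation.

    FISTA on the stacked variable v = (x, u): a gradient step on the
    fidelity with step 1/L, then the separable proximal step —
    ``prox_tv(·, β/L)`` on the image block and ``soft_threshold(·, β_r/L)``
    on the ring block — with standard momentum
    t_{k+1} = (1 + sqrt(1 + 4 t_k²))/2. Initialization is x = 0, u = 0
    (or the FBP reconstruction for x if ``warm_start_fbp``).
    """
    geom = d.geometry
    if n is None:
        n = geom.n_bins
    mat = projection_matrix(geom, n)
    L = estimate_lipschitz(geom, n, cfg.precondition, cfg)
    if L <= 0:
        raise ValueError("degenerate geometry: zero Lipschitz constant")

    x = np.zeros((n, n))
    if cfg.warm_start_fbp:
        x = fbp(d, n=n).pixels
    u = np.zeros(geom.n_bins)
    yx, yu = x.copy(), u.copy()
    t_mom = 1.0
    trace = np.empty(cfg.n_iter)
    terms = np.empty((cfg.n_iter, 3))
    tv_params = replace(cfg.inner_tv, weight=cfg.beta / L)
    best = np.inf
    for k in range(cfg.n_iter):
        r = (mat @ yx.ravel()).reshape(geom.n_angles, geom.n_bins)
        r += replicate_rings(yu, geom.n_angles)
        r -= d.values
        fr = _filter_residual(r, geom, cfg.precondition)
        gx = (mat.T @ fr.ravel()).reshape(n, n)
        gu = rings_adjoint(fr)

        x_new = prox_tv(yx - gx / L, tv_params)
        if cfg.rings:
            u_new = soft_threshold(yu - gu / L, cfg.beta_rings / L)
        else:
            u_new = np.zeros_like(u)

        r_new = (mat @ x_new.ravel()).reshape(geom.n_angles, geom.n_bins)
        r_new += replicate_rings(u_new, geom.n_angles)
        r_new -= d.values
        fid, prior, ring = _energy_terms_tv(r_new, x_new, u_new, geom, cfg)
        trace[k] = fid + prior + ring
        terms[k] = (fid, prior, ring)

        if cfg.restart and trace[k] > best:
            t_mom = 1.0
        best = min(best, trace[k])

        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2)) / 2.0
        mom = (t_mom - 1.0) / t_new
        yx = x_new + mom * (x_new - x)
        yu = u_new + mom * (u_new - u)
        x, u, t_mom = x_new, u_new, t_new

    corrected = Sinogram(d.values - replicate_rings(u, geom.n_angles), geom)
    return ReconResult(
        x=Image2D(x),
        u=RingVector(u),
        energy_trace=trace,
        corrected_sinogram=corrected,
        energy_terms=terms,
    )


def _dl_normal_op(geom, grid: PatchGrid, D: Dictionary, precondition: bool,
                  overlap_weight: float):
    """Hessian action of the smooth DL term on the stacked (W, u) vector."""
    mat = projection_matrix(geom, grid.image_size)
    n_w = grid.n_patches * D.n_atoms

    def apply(v: np.ndarray) -> np.ndarray:
        W = v[:n_w].reshape(grid.n_patches, D.n_atoms)
        u = v[n_w:]
        x = patch_synthesize(PatchCoefficients(W, grid), D).pixels
        s = (mat @ x.ravel()).reshape(geom.n_angles, geom.n_bins)
        s += replicate_rings(u, geom.n_angles)
        fs = _filter_residual(s, geom, precondition)
        bp = (mat.T @ fs.ravel()).reshape(grid.image_size, grid.image_size)
        gW = patch_analyze(Image2D(bp), D, grid).W
        if overlap_weight > 0:
            # h is a homogeneous quadratic, so its Hessian action on a
            # direction W equals the gradient evaluated at W
            _, hgrad = overlap_coherence(PatchCoefficients(W, grid), D)
            gW = gW + overlap_weight * hgrad.W
        gu = rings_adjoint(fs)
        return np.concatenate([gW.ravel(), gu])

    return LinearOperatorSpec(apply, (n_w + geom.n_bins,))


def energy_dl(W: PatchCoefficients, u: RingVector, d: Sinogram,
              D: Dictionary, cfg: SolverConfig) -> float:
    """½‖C(P S(W)+Ru−d)‖² + ρ·h(W) + β‖W‖₁ + β_r‖u‖₁ (S = patch synthesis)."""
    geom = d.geometry
    x = patch_synthesize(W, D)
    r = project(x, geom).values + replicate_rings(u.u, geom.n_angles) - d.values
    h, _ = overlap_coherence(W, D)
    return (
        _fidelity_value(r, geom, cfg.precondition)
        + cfg.overlap_weight * h
        + cfg.beta * float(np.abs(W.W).sum())
        + cfg.beta_rings * float(np.abs(u.u).sum())
    )


def reconstruct_dl_rings(
    d: Sinogram,
    D: Dictionary,
    cfg: SolverConfig,
    n: int | None = None,
    stride: int | None = None,
) -> ReconResult:
    """Dictionary-learning reconstruction with joint ring estimation.

    A single FISTA loop over the stacked (W, u): the smooth part is the
    preconditioned fidelity of the synthesized slice plus the quadratic
    overlap-coherence term; the non-smooth part is L1 on both blocks,
    handled by soft thresholding each block.
    """
    geom = d.geometry
    if n is None:
        n = geom.n_bins
    if stride is None:
        stride = max(1, D.patch_size // 2)
    grid = PatchGrid.cover(n, D.patch_size, stride)
    mat = projection_matrix(geom, n)

    op = _dl_normal_op(geom, grid, D, cfg.precondition, cfg.overlap_weight)
    L = power_method(op, n_iter=cfg.lipschitz_iters, tol=1e-9, seed=cfg.seed)
    if L <= 0:
        raise ValueError("degenerate geometry: zero Lipschitz constant")

    W = np.zeros((grid.n_patches, D.n_atoms))
    u = np.zeros(geom.n_bins)
    yW, yu = W.copy(), u.copy()
    t_mom = 1.0
    trace = np.empty(cfg.n_iter)
    terms = np.empty((cfg.n_iter, 3))
    best = np.inf
    for k in range(cfg.n_iter):
        xs = patch_synthesize(PatchCoefficients(yW, grid), D).pixels
        r = (mat @ xs.ravel()).reshape(geom.n_angles, geom.n_bins)
        r += replicate_rings(yu, geom.n_angles)
        r -= d.values
        fr = _filter_residual(r, geom, cfg.precondition)
        bp = (mat.T @ fr.ravel()).reshape(n, n)
        gW = patch_analyze(Image2D(bp), D, grid).W
        if cfg.overlap_weight > 0:
            _, hgrad = overlap_coherence(PatchCoefficients(yW, grid), D)
            gW = gW + cfg.overlap_weight * hgrad.W
        gu = rings_adjoint(fr)

        W_new = soft_threshold(yW - gW / L, cfg.beta / L)
        if cfg.rings:
            u_new = soft_threshold(yu - gu / L, cfg.beta_rings / L)
        else:
            u_new = np.zeros_like(u)

        Wc = PatchCoefficients(W_new, grid)
        e = energy_dl(Wc, RingVector(u_new), d, D, cfg)
        fidterm = e - cfg.beta * float(np.abs(W_new).sum()) \
            - cfg.beta_rings * float(np.abs(u_new).sum())
        trace[k] = e
        terms[k] = (
            fidterm,
            cfg.beta * float(np.abs(W_new).sum()),
            cfg.beta_rings * float(np.abs(u_new).sum()),
        )

        if cfg.restart and trace[k] > best:
            t_mom = 1.0
        best = min(best, trace[k])

        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2)) / 2.0
        mom = (t_mom - 1.0) / t_new
        yW = W_new + mom * (W_new - W)
        yu = u_new + mom * (u_new - u)
        W, u, t_mom = W_new, u_new, t_new

    Wc = PatchCoefficients(W, grid)
    corrected = Sinogram(d.values - replicate_rings(u, geom.n_angles), geom)
    return ReconResult(
        x=patch_synthesize(Wc, D),
        u=RingVector(u),
        energy_trace=trace,
        corrected_sinogram=corrected,
        energy_terms=terms,
        coefficients=Wc,
    )
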