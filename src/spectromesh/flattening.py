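"""Locally injective planar flattening of disk-topology triangle meshes.

The parametrization problem is

    f* = argmin_f E(f)   subject to   det df_t > 0 for every triangle t,

where f is piecewise affine (determined by the planar vertex images) and
df_t its 2x2 Jacobian on triangle t, expressed between an orthonormal frame
in the source triangle's plane and the target plane.  The orientation
constraint keeps the map locally injective (no inverted triangles).

The solver is a two-stage contract-equivalent of block-coordinate distortion
minimizers: a convex-combination (Tutte) embedding onto the unit disk, which
is bijective on disk meshes, followed by monotone descent of a barrier
energy (symmetric Dirichlet by default) with a line search whose maximum
step stays strictly below the smallest positive root of det(df_t) = 0 along
the descent direction — so no accepted iterate can flip a triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .meshing import TriMesh, boundary_loop

__all__ = [
    "PlanarEmbedding",
    "FlattenConfig",
    "tutte_embed",
    "minimize_distortion",
    "flatten",
    "triangle_jacobians",
    "source_frames",
]

# Energies usable as minimization objectives: both diverge as a singular
# value approaches zero, so monotone descent cannot cross a collapse.
_BARRIER_OBJECTIVES = ("symmetric_dirichlet", "mips")


@dataclass(frozen=True)
class FlattenConfig:
    """Solver settings for :func:`minimize_distortion`.

    ``method='newton'`` (default, symmetric Dirichlet only) takes descent
    directions from a per-triangle PSD-projected analytic Hessian;
    ``method='lbfgs'`` uses a limited-memory quasi-Newton direction and works
    for any supported objective.  ``rel_tolerance`` stops the descent when
    the relative energy decrease of an accepted step falls below it;
    ``grad_tolerance`` stops on the infinity-norm of the energy gradient.
    ``boundary='free'`` lets the boundary leave the initial disk (a fixed
    convex boundary forces large length distortion on non-developable
    surfaces), which requires a barrier objective.
    """

    optimized_energy: str = "symmetric_dirichlet"
    method: str = "newton"
    max_iters: int = 2000
    grad_tolerance: float = 1e-8
    rel_tolerance: float = 1e-8
    line_search_shrink: float = 0.5
    flip_step_fraction: float = 0.9
    boundary: str = "free"
    lbfgs_memory: int = 8
    tutte_weights: str = "mean_value"
    record_iterates: bool = False

    def __post_init__(self) -> None:
        if self.boundary not in ("free", "fixed"):
            raise ValueError("boundary must be 'free' or 'fixed'")
        if self.optimized_energy not in _BARRIER_OBJECTIVES:
            raise ValueError(
                f"unsupported objective {self.optimized_energy!r} "
                f"(supported: {_BARRIER_OBJECTIVES})"
            )
        if self.method not in ("newton", "lbfgs"):
            raise ValueError("method must be 'newton' or 'lbfgs'")
        if self.method == "newton" and self.optimized_energy != "symmetric_dirichlet":
            raise ValueError(
                "the Newton solver implements the symmetric Dirichlet "
                "eigensystem only; use method='lbfgs' for other objectives"
            )
        if not 0 < self.line_search_shrink < 1:
            raise ValueError("line_search_shrink must be in (0, 1)")
        if not 0 < self.flip_step_fraction < 1:
            raise ValueError("flip_step_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PlanarEmbedding:
    """A simplicial map into the plane with its per-triangle differentials.

    ``sigma1 >= |sigma2|`` are the signed singular values of each Jacobian;
    ``sigma2 < 0`` marks an inverted triangle.  ``energy_trace`` holds
    (iteration, objective energy) pairs of the accepted iterates and is
    non-increasing.
    """

    uv: np.ndarray  # (V, 2)
    jacobians: np.ndarray  # (T, 2, 2)
    sigma1: np.ndarray  # (T,)
    sigma2: np.ndarray  # (T,) signed
    energy_trace: tuple[tuple[int, float], ...] = field(default_factory=tuple)
    iterates: tuple[np.ndarray, ...] = ()  # accepted uv iterates, if recorded

    @property
    def n_inverted(self) -> int:
        return int(np.count_nonzero(self.sigma2 <= 0))

    @property
    def is_injective(self) -> bool:
        return self.n_inverted == 0

    @classmethod
    def from_uv(
        cls,
        mesh: TriMesh,
        uv: np.ndarray,
        energy_trace: tuple[tuple[int, float], ...] = (),
        iterates: tuple[np.ndarray, ...] = (),
    ) -> "PlanarEmbedding":
        jac, s1, s2 = triangle_jacobians(mesh, uv)
        return cls(
            uv=np.asarray(uv, dtype=np.float64),
            jacobians=jac,
            sigma1=s1,
            sigma2=s2,
            energy_trace=energy_trace,
            iterates=iterates,
        )


# ---------------------------------------------------------------------------
# Source frames and Jacobians
# ---------------------------------------------------------------------------

def source_frames(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle source edge matrices in a local orthonormal frame.

    For triangle (p0, p1, p2) the frame's first axis lies along p1 - p0 and
    the second completes a right-handed frame with the triangle normal
    (oriented by the CCW vertex order, i.e. upward for graph surfaces).
    Returns ``(P, P_inv)`` with P of shape (T, 2, 2); P's columns are the
    frame coordinates of the edges p1 - p0 and p2 - p0.  The construction
    uses only intrinsic edge geometry, so P is invariant under rigid motions
    of the source mesh.
    """
    p0, p1, p2 = mesh.triangle_corners()
    e1 = p1 - p0
    e2 = p2 - p0
    normal = np.cross(e1, e2)
    area2 = np.linalg.norm(normal, axis=1)  # = 2 * area3d
    if np.any(area2 < 1e-14):
        bad = int(np.argmin(area2))
        raise ValueError(f"degenerate source triangle {bad} (zero area)")
    len1 = np.linalg.norm(e1, axis=1)
    u = e1 / len1[:, None]
    n = normal / area2[:, None]
    v = np.cross(n, u)
    P = np.empty((mesh.n_triangles, 2, 2))
    P[:, 0, 0] = len1
    P[:, 1, 0] = 0.0
    P[:, 0, 1] = np.einsum("ij,ij->i", e2, u)
    P[:, 1, 1] = np.einsum("ij,ij->i", e2, v)
    det = P[:, 0, 0] * P[:, 1, 1]
    P_inv = np.empty_like(P)
    P_inv[:, 0, 0] = P[:, 1, 1]
    P_inv[:, 1, 1] = P[:, 0, 0]
    P_inv[:, 0, 1] = -P[:, 0, 1]
    P_inv[:, 1, 0] = 0.0
    P_inv /= det[:, None, None]
    return P, P_inv


def _uv_edge_matrices(mesh: TriMesh, uv: np.ndarray) -> np.ndarray:
    t = mesh.triangles
    uv = np.asarray(uv, dtype=np.float64)
    Q = np.empty((len(t), 2, 2))
    Q[:, :, 0] = uv[t[:, 1]] - uv[t[:, 0]]
    Q[:, :, 1] = uv[t[:, 2]] - uv[t[:, 0]]
    return Q


def _signed_svd_2x2(J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed singular values of a stack of 2x2 matrices.

    sigma1 >= |sigma2|, and sigma2 carries the sign of det J, so
    sigma1 * sigma2 == det J exactly.
    """
    a = 0.5 * (J[:, 0, 0] + J[:, 1, 1])
    b = 0.5 * (J[:, 0, 0] - J[:, 1, 1])
    c = 0.5 * (J[:, 1, 0] + J[:, 0, 1])
    d = 0.5 * (J[:, 1, 0] - J[:, 0, 1])
    h1 = np.hypot(a, d)
    h2 = np.hypot(b, c)
    return h1 + h2, h1 - h2


def triangle_jacobians(
    mesh: TriMesh, uv: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jacobian df_t = Q_t P_t^{-1} and its signed singular values per triangle."""
    uv = np.asarray(uv, dtype=np.float64)
    if uv.shape != (mesh.n_vertices, 2):
        raise ValueError(
            f"uv shape {uv.shape} does not match mesh ({mesh.n_vertices} vertices)"
        )
    _, P_inv = source_frames(mesh)
    J = _uv_edge_matrices(mesh, uv) @ P_inv
    s1, s2 = _signed_svd_2x2(J)
    return J, s1, s2


# ---------------------------------------------------------------------------
# Tutte (convex-combination) embedding
# ---------------------------------------------------------------------------

def _edge_weights(mesh: TriMesh, kind: str) -> dict[tuple[int, int], float]:
    t = mesh.triangles
    if kind == "uniform":
        weights: dict[tuple[int, int], float] = {}
        for tri in t:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                weights[(int(a), int(b))] = 1.0
                weights[(int(b), int(a))] = 1.0
        return weights
    if kind != "mean_value":
        raise ValueError(f"unknown Tutte weight kind {kind!r}")
    v = mesh.vertices
    weights = {}
    # Mean-value weight of directed edge (i, j): sum over the triangles
    # containing it of tan(angle_at_i / 2) / |v_i - v_j|.
    for tri in t:
        for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            a, b, c = int(tri[i]), int(tri[j]), int(tri[k])
            u = v[b] - v[a]
            w = v[c] - v[a]
            lu = np.linalg.norm(u)
            lw = np.linalg.norm(w)
            cos = float(np.dot(u, w)) / (lu * lw)
            sin = float(np.linalg.norm(np.cross(u, w))) / (lu * lw)
            half_tan = sin / (1.0 + min(cos, 1.0))  # tan(theta/2), stable
            weights[(a, b)] = weights.get((a, b), 0.0) + half_tan / lu
            weights[(a, c)] = weights.get((a, c), 0.0) + half_tan / lw
    return weights


def tutte_embed(mesh: TriMesh, weights: str = "mean_value") -> PlanarEmbedding:
    """Bijective convex-combination embedding onto the unit disk.

    Boundary vertices are spread on the unit circle in boundary-loop order,
    spaced proportionally to the 3D boundary edge lengths; every interior
    vertex is the convex combination of its neighbours under the chosen
    positive weights, found by solving one sparse linear system.  On a disk
    mesh the result has det df_t > 0 for every triangle.
    """
    loop = boundary_loop(mesh)
    v = mesh.vertices
    edge_vec = v[np.roll(loop, -1)] - v[loop]
    seg = np.linalg.norm(edge_vec, axis=1)
    angles = 2.0 * np.pi * np.concatenate([[0.0], np.cumsum(seg)[:-1]]) / seg.sum()
    nv = mesh.n_vertices
    uv = np.zeros((nv, 2))
    uv[loop, 0] = np.cos(angles)
    uv[loop, 1] = np.sin(angles)

    is_boundary = np.zeros(nv, dtype=bool)
    is_boundary[loop] = True
    interior = np.flatnonzero(~is_boundary)
    if len(interior):
        w = _edge_weights(mesh, weights)
        row_of = {int(vi): r for r, vi in enumerate(interior)}
        rows, cols, vals = [], [], []
        rhs = np.zeros((len(interior), 2))
        diag = np.zeros(len(interior))
        for (a, b), wab in w.items():
            r = row_of.get(a)
            if r is None:
                continue
            diag[r] += wab
            if is_boundary[b]:
                rhs[r] += wab * uv[b]
            else:
                rows.append(r)
                cols.append(row_of[b])
                vals.append(-wab)
        rows.extend(range(len(interior)))
        cols.extend(range(len(interior)))
        vals.extend(diag)
        L = sp.csc_matrix(
            (vals, (rows, cols)), shape=(len(interior), len(interior))
        )
        try:
            lu = splu(L)
        except RuntimeError as exc:  # singular factorization
            raise ValueError(f"Tutte system is singular: {exc}") from exc
        uv[interior, 0] = lu.solve(rhs[:, 0])
        uv[interior, 1] = lu.solve(rhs[:, 1])
    return PlanarEmbedding.from_uv(mesh, uv)


# ---------------------------------------------------------------------------
# Barrier-energy descent
# ---------------------------------------------------------------------------

def _objective_and_grad_J(J: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle energy value and gradient with respect to the Jacobian."""
    det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    frob2 = np.einsum("tij,tij->t", J, J)
    adjT = np.empty_like(J)  # d(det)/dJ
    adjT[:, 0, 0] = J[:, 1, 1]
    adjT[:, 1, 1] = J[:, 0, 0]
    adjT[:, 0, 1] = -J[:, 1, 0]
    adjT[:, 1, 0] = -J[:, 0, 1]
    if name == "symmetric_dirichlet":
        Jinv = adjT.transpose(0, 2, 1).copy()
        Jinv[:, 0, 1], Jinv[:, 1, 0] = -J[:, 0, 1] / det, -J[:, 1, 0] / det
        Jinv[:, 0, 0] = J[:, 1, 1] / det
        Jinv[:, 1, 1] = J[:, 0, 0] / det
        frob2_inv = np.einsum("tij,tij->t", Jinv, Jinv)
        value = 0.25 * (frob2 + frob2_inv)
        # d/dJ ||J^-1||^2 = -2 (J^-1 J^-T J^-1)^T
        JiJiT = Jinv @ Jinv.transpose(0, 2, 1)
        grad = 0.5 * (J - (Jinv.transpose(0, 2, 1) @ JiJiT.transpose(0, 2, 1)))
        return value, grad
    if name == "mips":
        value = frob2 / det
        grad = 2.0 * J / det[:, None, None] - (frob2 / det**2)[:, None, None] * adjT
        return value, grad
    raise ValueError(f"unsupported objective {name!r}")


def _sd_hessian_modes(J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PSD-projected eigensystem of the symmetric Dirichlet Hessian.

    For J with signed SVD U diag(s1, s2) V^T the Hessian of
    Psi = (s1^2 + s1^-2 + s2^2 + s2^-2)/4 in J-space has the orthonormal
    eigenmatrices u1 v1^T, u2 v2^T, (u1 v2^T + u2 v1^T)/sqrt2 and
    (u2 v1^T - u1 v2^T)/sqrt2 with eigenvalues Psi_11, Psi_22,
    (Psi_1 - Psi_2)/(s1 - s2) and (Psi_1 + Psi_2)/(s1 + s2); only the last
    (the twist mode) can be negative and is clamped for the projection.
    Returns ``(lam, modes)`` of shapes (T, 4) and (T, 4, 2, 2).
    """
    E = 0.5 * (J[:, 0, 0] + J[:, 1, 1])
    F = 0.5 * (J[:, 0, 0] - J[:, 1, 1])
    G = 0.5 * (J[:, 1, 0] + J[:, 0, 1])
    H = 0.5 * (J[:, 1, 0] - J[:, 0, 1])
    h1 = np.hypot(E, H)
    h2 = np.hypot(F, G)
    s1, s2 = h1 + h2, h1 - h2
    a1 = np.arctan2(H, E)
    a2 = np.arctan2(G, F)
    tu = 0.5 * (a2 + a1)
    tv = 0.5 * (a2 - a1)
    cu, su = np.cos(tu), np.sin(tu)
    cv, sv = np.cos(tv), np.sin(tv)
    u1 = np.stack([cu, su], axis=1)
    u2 = np.stack([-su, cu], axis=1)
    v1 = np.stack([cv, sv], axis=1)
    v2 = np.stack([-sv, cv], axis=1)
    outer = lambda a, b: a[:, :, None] * b[:, None, :]
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    modes = np.stack(
        [
            outer(u1, v1),
            outer(u2, v2),
            (outer(u1, v2) + outer(u2, v1)) * inv_sqrt2,
            (outer(u2, v1) - outer(u1, v2)) * inv_sqrt2,
        ],
        axis=1,
    )
    p1 = 0.5 * (s1 - s1**-3)
    p2 = 0.5 * (s2 - s2**-3)
    lam1 = 0.25 * (2.0 + 6.0 * s1**-4)
    lam2 = 0.25 * (2.0 + 6.0 * s2**-4)
    gap = s1 - s2
    lam_flip = np.where(
        gap > 1e-8 * np.maximum(s1, 1.0), (p1 - p2) / np.where(gap == 0, 1, gap), lam1
    )
    lam_twist = (p1 + p2) / (s1 + s2)
    lam = np.stack([lam1, lam2, lam_flip, lam_twist], axis=1)
    return np.maximum(lam, 1e-12), modes


class _EnergyModel:
    """Area-weighted mean barrier energy of a map, with vertex gradient."""

    def __init__(self, mesh: TriMesh, name: str):
        self.mesh = mesh
        self.name = name
        _, self.P_inv = source_frames(mesh)
        areas = mesh.area3d()
        self.weights = areas / areas.sum()
        # Per-triangle shape-gradient vectors B: J_ab = sum_k (uv_k)_a B_kb
        t = mesh.triangles
        T = len(t)
        self.B = np.empty((T, 3, 2))
        self.B[:, 1, :] = self.P_inv[:, 0, :]
        self.B[:, 2, :] = self.P_inv[:, 1, :]
        self.B[:, 0, :] = -(self.B[:, 1, :] + self.B[:, 2, :])
        # dof layout (k-major, x then y) for the 6x6 Hessian blocks
        dof = np.empty((T, 6), dtype=np.int64)
        dof[:, 0::2] = 2 * t
        dof[:, 1::2] = 2 * t + 1
        self._h_rows = np.repeat(dof, 6, axis=1).ravel()
        self._h_cols = np.tile(dof, (1, 6)).ravel()

    def jacobians(self, uv: np.ndarray) -> np.ndarray:
        return _uv_edge_matrices(self.mesh, uv) @ self.P_inv

    def dets(self, J: np.ndarray) -> np.ndarray:
        return J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]

    def energy(self, uv: np.ndarray) -> float:
        J = self.jacobians(uv)
        if np.any(self.dets(J) <= 0):
            return np.inf
        value, _ = _objective_and_grad_J(J, self.name)
        return float(np.dot(self.weights, value))

    def energy_grad(self, uv: np.ndarray) -> tuple[float, np.ndarray]:
        J = self.jacobians(uv)
        value, gJ = _objective_and_grad_J(J, self.name)
        total = float(np.dot(self.weights, value))
        # chain rule: J = Q P^-1, dE/dQ = dE/dJ P^-T, scatter Q-columns to vertices
        gQ = self.weights[:, None, None] * (gJ @ self.P_inv.transpose(0, 2, 1))
        grad = np.zeros_like(uv)
        t = self.mesh.triangles
        np.add.at(grad, t[:, 1], gQ[:, :, 0])
        np.add.at(grad, t[:, 2], gQ[:, :, 1])
        np.add.at(grad, t[:, 0], -(gQ[:, :, 0] + gQ[:, :, 1]))
        return total, grad

    def hessian(self, uv: np.ndarray) -> sp.csc_matrix:
        """Projected-PSD Hessian of the area-weighted symmetric Dirichlet
        energy with respect to the stacked uv coordinates (2V x 2V)."""
        J = self.jacobians(uv)
        lam, modes = _sd_hessian_modes(J)
        # g[t, m] = mode matrix pulled back to the 6 triangle dofs
        g = np.einsum("tmab,tkb->tmka", modes, self.B).reshape(len(J), 4, 6)
        blocks = np.einsum("t,tm,tmi,tmj->tij", self.weights, lam, g, g)
        n = 2 * self.mesh.n_vertices
        return sp.coo_matrix(
            (blocks.ravel(), (self._h_rows, self._h_cols)), shape=(n, n)
        ).tocsc()

    def max_flip_free_step(self, uv: np.ndarray, direction: np.ndarray) -> float:
        """Smallest positive root of det(df_t(uv + s*direction)) = 0 over t."""
        J = self.jacobians(uv)
        D = self.jacobians(direction + 0.0) - self.jacobians(np.zeros_like(uv))
        a = self.dets(D)
        b = (
            J[:, 0, 0] * D[:, 1, 1]
            + D[:, 0, 0] * J[:, 1, 1]
            - J[:, 0, 1] * D[:, 1, 0]
            - D[:, 0, 1] * J[:, 1, 0]
        )
        c = self.dets(J)
        best = np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            # linear case: c + b s = 0
            lin = np.where((np.abs(a) < 1e-14) & (b < 0), -c / b, np.inf)
            disc = b * b - 4 * a * c
            sq = np.sqrt(np.maximum(disc, 0.0))
            quad_ok = (np.abs(a) >= 1e-14) & (disc >= 0)
            r1 = np.where(quad_ok, (-b - sq) / (2 * a), np.inf)
            r2 = np.where(quad_ok, (-b + sq) / (2 * a), np.inf)
        for roots in (lin, r1, r2):
            pos = roots[roots > 0]
            if len(pos):
                best = min(best, float(pos.min()))
        return best


def minimize_distortion(
    mesh: TriMesh,
    init: PlanarEmbedding,
    cfg: FlattenConfig = FlattenConfig(),
) -> PlanarEmbedding:
    """Monotone flip-free descent of the configured barrier energy.

    Uses an L-BFGS descent direction with a backtracking line search whose
    first trial step is capped at ``flip_step_fraction`` times the smallest
    positive root of det(df_t) = 0 along the direction, so every accepted
    iterate keeps det df_t > 0 for all t.  The energy trace of accepted
    iterates is non-increasing by construction.  Deterministic.
    """
    if not init.is_injective:
        raise ValueError(
            f"initial embedding has {init.n_inverted} inverted triangle(s); "
            "this solver does not repair non-injective maps"
        )
    model = _EnergyModel(mesh, cfg.optimized_energy)
    uv = init.uv.copy()
    free = np.ones(mesh.n_vertices, dtype=bool)
    if cfg.boundary == "fixed":
        free[boundary_loop(mesh)] = False
    free_dofs = np.repeat(free, 2)

    energy, grad = model.energy_grad(uv)
    grad[~free] = 0.0
    trace = [(0, energy)]
    iterates = [uv.copy()] if cfg.record_iterates else []
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []

    for it in range(1, cfg.max_iters + 1):
        if np.max(np.abs(grad)) < cfg.grad_tolerance:
            break
        direction = None
        if cfg.method == "newton":
            direction = _newton_direction(model, uv, grad, free_dofs)
        if direction is None:
            direction = _lbfgs_direction(grad.ravel(), s_hist, y_hist).reshape(uv.shape)
            direction[~free] = 0.0
        slope = float(np.sum(direction * grad))
        if slope >= 0:  # not a descent direction: fall back to steepest descent
            direction = -grad
            slope = -float(np.sum(grad * grad))
        step_cap = cfg.flip_step_fraction * model.max_flip_free_step(uv, direction)
        step = min(1.0, step_cap)
        accepted = False
        while step > 1e-16:
            new_uv = uv + step * direction
            new_energy = model.energy(new_uv)
            if new_energy <= energy + 1e-4 * step * slope:
                accepted = True
                break
            step *= cfg.line_search_shrink
        if not accepted:
            break
        prev_uv, prev_grad = uv, grad
        uv = new_uv
        new_energy, grad = model.energy_grad(uv)
        grad[~free] = 0.0
        trace.append((it, new_energy))
        if cfg.record_iterates:
            iterates.append(uv.copy())
        if cfg.method == "lbfgs":
            s = (uv - prev_uv).ravel()
            y = (grad - prev_grad).ravel()
            if float(s @ y) > 1e-16:
                s_hist.append(s)
                y_hist.append(y)
                if len(s_hist) > cfg.lbfgs_memory:
                    s_hist.pop(0)
                    y_hist.pop(0)
        rel_drop = (energy - new_energy) / max(abs(energy), 1e-30)
        energy = new_energy
        if rel_drop < cfg.rel_tolerance:
            break

    result = PlanarEmbedding.from_uv(
        mesh, uv, energy_trace=tuple(trace), iterates=tuple(iterates)
    )
    if not result.is_injective:  # pragma: no cover - excluded by the step cap
        raise RuntimeError("flip-free line search produced an inverted triangle")
    return result


def _newton_direction(
    model: _EnergyModel, uv: np.ndarray, grad: np.ndarray, free_dofs: np.ndarray
) -> np.ndarray | None:
    """Solve H d = -grad on the free dofs; None if the solve fails.

    A small diagonal Tikhonov term absorbs the rigid-motion null space of
    the free-boundary problem.
    """
    H = model.hessian(uv)
    n = H.shape[0]
    reg = 1e-10 * (H.diagonal().mean() + 1.0)
    H = H + reg * sp.identity(n, format="csc")
    g = grad.ravel()
    try:
        if free_dofs.all():
            d = -splu(H).solve(g)
        else:
            idx = np.flatnonzero(free_dofs)
            Hff = H[idx][:, idx].tocsc()
            d = np.zeros(n)
            d[idx] = -splu(Hff).solve(g[idx])
    except RuntimeError:  # pragma: no cover - singular despite regularization
        return None
    if not np.all(np.isfinite(d)):
        return None
    return d.reshape(uv.shape)


def _lbfgs_direction(
    grad: np.ndarray, s_hist: list[np.ndarray], y_hist: list[np.ndarray]
) -> np.ndarray:
    """Two-loop recursion; falls back to -grad with no history."""
    q = grad.copy()
    if not s_hist:
        return -q
    alphas = []
    rhos = [1.0 / float(y @ s) for s, y in zip(s_hist, y_hist)]
    for s, y, rho in zip(reversed(s_hist), reversed(y_hist), reversed(rhos)):
        a = rho * float(s @ q)
        alphas.append(a)
        q -= a * y
    gamma = float(s_hist[-1] @ y_hist[-1]) / float(y_hist[-1] @ y_hist[-1])
    q *= gamma
    for (s, y, rho), a in zip(zip(s_hist, y_hist, rhos), reversed(alphas)):
        beta = rho * float(y @ q)
        q += (a - beta) * s
    return -q


def flatten(mesh: TriMesh, cfg: FlattenConfig = FlattenConfig()) -> PlanarEmbedding:
    """Tutte initialization followed by barrier-energy minimization."""
    init = tutte_embed(mesh, weights=cfg.tutte_weights)
    return minimize_distortion(mesh, init, cfg)
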