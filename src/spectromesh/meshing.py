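"""Triangle meshes of spectrogram surfaces.

The surface grid is triangulated in the (x, y) plane and lifted by the vertex
heights, so connectivity depends only on the grid, never on z.  For a uniform
grid every quad is co-circular and the Delaunay triangulation is ambiguous;
the tie is broken deterministically toward the "/" diagonal so connectivity
is reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SpectrogramSurface

__all__ = ["TriMesh", "build_mesh", "boundary_loop", "write_off", "read_off", "write_obj"]


@dataclass(frozen=True)
class TriMesh:
    """A triangulated surface: vertices in 3-space and triangle index triples.

    Triangles are counter-clockwise in the (x, y) projection and form a
    manifold disk (single boundary loop).  ``area3d`` is the triangle area
    measured on the source surface in 3-space; ``f_cg`` is the frequency
    (y) coordinate of each triangle's centroid.
    """

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (T, 3) int

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (T, 3)")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle index out of range")
        if t.size and np.any(
            (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        ):
            raise ValueError("degenerate triangle (repeated vertex index)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v, t = self.vertices, self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def area3d(self) -> np.ndarray:
        """Area of each triangle measured in 3-space."""
        p0, p1, p2 = self.triangle_corners()
        cross = np.cross(p1 - p0, p2 - p0)
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area2d_signed(self) -> np.ndarray:
        """Signed area of each triangle's (x, y) projection (positive = CCW)."""
        p0, p1, p2 = self.triangle_corners()
        e1 = (p1 - p0)[:, :2]
        e2 = (p2 - p0)[:, :2]
        return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])

    def f_cg(self) -> np.ndarray:
        """Frequency of each triangle's centre of gravity (mean vertex y)."""
        p0, p1, p2 = self.triangle_corners()
        return (p0[:, 1] + p1[:, 1] + p2[:, 1]) / 3.0

    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (lo, hi) index pairs."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)


def build_mesh(surface: SpectrogramSurface) -> TriMesh:
    """Triangulate the surface grid: N^2 vertices, 2(N-1)^2 CCW triangles.

    Each grid cell is split along its "/" diagonal (the deterministic
    Delaunay tie-break for co-circular quads).
    """
    times, freqs, z = surface.times, surface.freqs, surface.z
    nt, nf = len(times), len(freqs)
    if nt < 2 or nf < 2:
        raise ValueError("surface grid must be at least 2x2")
    for name, ax in (("times", times), ("freqs", freqs)):
        if np.any(np.diff(ax) <= 0):
            raise ValueError(f"degenerate grid: repeated {name} coordinates")

    # Vertex (i, j) = (x_i, y_j, z(x_i, y_j)); index = j * nt + i.
    xx, yy = np.meshgrid(times, freqs, indexing="xy")
    vertices = np.stack([xx.ravel(), yy.ravel(), z.ravel()], axis=1)

    i, j = np.meshgrid(np.arange(nt - 1), np.arange(nf - 1), indexing="xy")
    v00 = (j * nt + i).ravel()  # (x_i, y_j)
    v10 = v00 + 1               # (x_{i+1}, y_j)
    v01 = v00 + nt              # (x_i, y_{j+1})
    v11 = v01 + 1
    # "/" diagonal joins v10 and v01; both triangles CCW in (x, y).
    lower = np.stack([v00, v10, v01], axis=1)
    upper = np.stack([v10, v11, v01], axis=1)
    triangles = np.concatenate([lower, upper])
    return TriMesh(vertices=vertices, triangles=triangles)


def boundary_loop(mesh: TriMesh) -> np.ndarray:
    """The single boundary cycle, counter-clockwise, starting at its
    smallest vertex index.

    Raises ``ValueError`` on non-manifold edges (an edge in more than two
    triangles) or when the mesh does not have disk topology (no boundary or
    more than one loop).
    """
    t = mesh.triangles
    directed = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    if np.any(counts > 2):
        bad = uniq[counts > 2][0]
        raise ValueError(f"non-manifold edge {tuple(bad)} (in >2 triangles)")
    boundary_und = {tuple(e) for e in uniq[counts == 1]}
    if not boundary_und:
        raise ValueError("mesh has no boundary (not a disk)")
    # Boundary edges keep triangle orientation: successor map a -> b.
    succ: dict[int, int] = {}
    for a, b in directed:
        if (min(a, b), max(a, b)) in boundary_und:
            if a in succ:
                raise ValueError(f"non-manifold boundary at vertex {a}")
            succ[int(a)] = int(b)
    start = min(succ)
    loop = [start]
    cur = succ[start]
    while cur != start:
        loop.append(cur)
        cur = succ.get(cur)
        if cur is None or len(loop) > len(succ):
            raise ValueError("boundary is not a single closed loop")
    if len(loop) != len(succ):
        raise ValueError(
            f"mesh has more than one boundary loop "
            f"({len(succ) - len(loop)} boundary edges unreached)"
        )
    return np.asarray(loop, dtype=np.int64)


# ---------------------------------------------------------------------------
# Plain-text mesh I/O
# ---------------------------------------------------------------------------

def write_off(mesh: TriMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path: str) -> TriMesh:
    with open(path) as fh:
        tokens = [
            tok
            for line in fh
            if (stripped := line.split("#")[0].strip())
            for tok in stripped.split()
        ]
    if not tokens or tokens[0] != "OFF":
        raise ValueError(f"{path} is not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos : pos + 3 * nv], dtype=np.float64).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError("only triangle faces are supported")
        tris.append([int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])])
        pos += k + 1
    return TriMesh(vertices=verts, triangles=np.asarray(tris, dtype=np.int64))


def write_obj(mesh: TriMesh, path: str, uv: np.ndarray | None = None) -> None:
    """OBJ export, optionally with per-vertex texture (uv) records."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        if uv is not None:
            for q in np.asarray(uv, dtype=np.float64):
                fh.write(f"vt {q[0]:.17g} {q[1]:.17g}\n")
        for t in mesh.triangles:
            a, b, c = (int(i) + 1 for i in t)  # OBJ is 1-based
            if uv is not None:
                fh.write(f"f {a}/{a} {b}/{b} {c}/{c}\n")
            else:
                fh.write(f"f {a} {b} {c}\n")
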