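"""Tutte embedding, Jacobians with signed singular values, barrier descent."""

import numpy as np
import pytest

from spectromesh.flattening import (
    FlattenConfig,
    PlanarEmbedding,
    _EnergyModel,
    flatten,
    minimize_distortion,
    source_frames,
    triangle_jacobians,
    tutte_embed,
)
from spectromesh.meshing import TriMesh
from tests.conftest import random_grid_mesh


def single_triangle_mesh(p0, p1, p2):
    return TriMesh(
        vertices=np.array([p0, p1, p2], dtype=float),
        triangles=np.array([[0, 1, 2]]),
    )


def brute_force_signed_svd(mesh, uv):
    """Independent oracle: explicit edge-matrix Jacobian + numpy SVD."""
    s1_all, s2_all = [], []
    for tri in mesh.triangles:
        p0, p1, p2 = mesh.vertices[tri]
        e1, e2 = p1 - p0, p2 - p0
        n = np.cross(e1, e2)
        n = n / np.linalg.norm(n)
        u = e1 / np.linalg.norm(e1)
        v = np.cross(n, u)
        P = np.array([[e1 @ u, e2 @ u], [e1 @ v, e2 @ v]])
        q0, q1, q2 = uv[tri]
        Q = np.array([[q1[0] - q0[0], q2[0] - q0[0]], [q1[1] - q0[1], q2[1] - q0[1]]])
        J = Q @ np.linalg.inv(P)
        s = np.linalg.svd(J, compute_uv=False)
        sign = np.sign(np.linalg.det(J))
        s1_all.append(s[0])
        s2_all.append(sign * s[1])
    return np.array(s1_all), np.array(s2_all)


class TestTriangleJacobians:
    def test_identity_map_of_planar_mesh(self, flat_mesh):
        uv = flat_mesh.vertices[:, :2]
        jac, s1, s2 = triangle_jacobians(flat_mesh, uv)
        np.testing.assert_allclose(s1, 1.0, atol=1e-12)
        np.testing.assert_allclose(s2, 1.0, atol=1e-12)
        # df maps frame coordinates to the plane: J^T J must be identity
        gram = jac.transpose(0, 2, 1) @ jac
        np.testing.assert_allclose(
            gram, np.tile(np.eye(2), (len(gram), 1, 1)), atol=1e-12
        )

    def test_uniform_scaling_and_reflection(self):
        mesh = single_triangle_mesh([0, 0, 0], [1, 0, 0], [0.2, 0.9, 0])
        uv = 2.0 * mesh.vertices[:, :2]
        _, s1, s2 = triangle_jacobians(mesh, uv)
        np.testing.assert_allclose([s1[0], s2[0]], [2.0, 2.0], atol=1e-12)
        uv_flip = uv * np.array([1.0, -1.0])
        _, s1, s2 = triangle_jacobians(mesh, uv_flip)
        assert s2[0] == pytest.approx(-2.0, abs=1e-12)
        assert s1[0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_svd_on_random_triangles(self, rng):
        """1,000 random triangles, including reflected images, to 1e-10."""
        for k in range(1000):
            pts = rng.standard_normal((3, 3))
            mesh = single_triangle_mesh(*pts)
            uv = rng.standard_normal((3, 2))
            _, s1, s2 = triangle_jacobians(mesh, uv)
            o1, o2 = brute_force_signed_svd(mesh, uv)
            np.testing.assert_allclose(s1, o1, atol=1e-10)
            np.testing.assert_allclose(s2, o2, atol=1e-10)

    def test_rigid_motion_of_source_leaves_sigmas_unchanged(self, bump_mesh, rng):
        from scipy.spatial.transform import Rotation

        uv = tutte_embed(bump_mesh).uv
        _, s1, s2 = triangle_jacobians(bump_mesh, uv)
        R = Rotation.random(rng=rng).as_matrix()
        moved = TriMesh(
            vertices=bump_mesh.vertices @ R.T + np.array([5.0, -2.0, 1.0]),
            triangles=bump_mesh.triangles,
        )
        _, r1, r2 = triangle_jacobians(moved, uv)
        np.testing.assert_allclose(r1, s1, atol=1e-10)
        np.testing.assert_allclose(r2, s2, atol=1e-10)

    def test_degenerate_source_triangle_identified(self):
        mesh = TriMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0.0]]),
            triangles=np.array([[0, 1, 2], [0, 1, 3]]),
        )
        with pytest.raises(ValueError, match="triangle 0"):
            source_frames(mesh)

    def test_shape_mismatch_rejected(self, flat_mesh):
        with pytest.raises(ValueError, match="uv shape"):
            triangle_jacobians(flat_mesh, np.zeros((3, 2)))


class TestTutteEmbed:
    def test_interior_vertex_is_mean_of_boundary_with_uniform_weights(
        self, square_fan_mesh
    ):
        emb = tutte_embed(square_fan_mesh, weights="uniform")
        np.testing.assert_allclose(emb.uv[4], emb.uv[:4].mean(axis=0), atol=1e-12)

    def test_boundary_only_mesh(self, rng):
        from spectromesh.meshing import build_mesh
        from spectromesh.synthetic import height_field_surface

        mesh = build_mesh(height_field_surface("random", 2, amplitude=0.4, seed=1))
        emb = tutte_embed(mesh)
        assert emb.n_inverted == 0
        np.testing.assert_allclose(np.linalg.norm(emb.uv, axis=1), 1.0, atol=1e-12)

    def test_boundary_on_unit_circle_in_loop_order(self, bump_mesh):
        from spectromesh.meshing import boundary_loop

        loop = boundary_loop(bump_mesh)
        emb = tutte_embed(bump_mesh)
        r = np.linalg.norm(emb.uv[loop], axis=1)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)
        ang = np.unwrap(np.arctan2(emb.uv[loop, 1], emb.uv[loop, 0]))
        assert np.all(np.diff(ang) > 0)  # CCW, strictly advancing

    @pytest.mark.parametrize("weights", ["uniform", "mean_value"])
    def test_bijective_on_seeded_height_fields(self, weights):
        for seed in range(25):
            mesh = random_grid_mesh(12, amplitude=0.8, seed=seed)
            emb = tutte_embed(mesh, weights=weights)
            assert emb.n_inverted == 0, f"seed {seed} produced a flip"

    def test_unknown_weights_rejected(self, flat_mesh):
        with pytest.raises(ValueError, match="weight"):
            tutte_embed(flat_mesh, weights="cotangent")


class TestMinimizeDistortion:
    def test_flat_surface_flattens_isometrically(self):
        mesh = random_grid_mesh(16, amplitude=0.0, seed=0)
        emb = flatten(mesh)
        np.testing.assert_allclose(emb.sigma1, 1.0, atol=1e-6)
        np.testing.assert_allclose(emb.sigma2, 1.0, atol=1e-6)
        assert emb.energy_trace[-1][1] == pytest.approx(1.0, abs=1e-9)

    def test_energy_not_above_tutte_init(self, bump_mesh):
        init = tutte_embed(bump_mesh)
        model = _EnergyModel(bump_mesh, "symmetric_dirichlet")
        final = minimize_distortion(bump_mesh, init)
        assert final.energy_trace[-1][1] <= model.energy(init.uv) + 1e-12

    def test_trace_monotone_nonincreasing(self, bump_mesh):
        emb = flatten(bump_mesh)
        energies = [e for _, e in emb.energy_trace]
        assert all(b <= a for a, b in zip(energies, energies[1:]))

    def test_already_isometric_init_converges_immediately(self):
        mesh = single_triangle_mesh([0, 0, 1.0], [1, 0, 1.5], [0.1, 1.2, 0.7])
        P, _ = source_frames(mesh)
        uv = np.vstack([[0.0, 0.0], P[0, :, 0], P[0, :, 1]])
        init = PlanarEmbedding.from_uv(mesh, uv)
        np.testing.assert_allclose([init.sigma1[0], init.sigma2[0]], 1.0, atol=1e-12)
        out = minimize_distortion(mesh, init)
        assert len(out.energy_trace) == 1  # gradient tolerance met at iterate 0

    def test_inverted_init_rejected(self, flat_mesh):
        uv = flat_mesh.vertices[:, :2] * np.array([1.0, -1.0])
        bad = PlanarEmbedding.from_uv(flat_mesh, uv)
        assert bad.n_inverted == flat_mesh.n_triangles
        with pytest.raises(ValueError, match="inverted"):
            minimize_distortion(flat_mesh, bad)

    def test_all_iterates_flip_free_when_recorded(self, bump_mesh):
        cfg = FlattenConfig(record_iterates=True)
        init = tutte_embed(bump_mesh)
        emb = minimize_distortion(bump_mesh, init, cfg)
        assert len(emb.iterates) == len(emb.energy_trace)
        for uv in emb.iterates:
            _, _, s2 = triangle_jacobians(bump_mesh, uv)
            assert np.all(s2 > 0)

    @pytest.mark.parametrize(
        "cfg",
        [
            FlattenConfig(method="lbfgs"),
            FlattenConfig(method="lbfgs", optimized_energy="mips"),
            FlattenConfig(boundary="fixed"),
        ],
    )
    def test_other_solver_modes_descend_and_stay_injective(self, bump_mesh, cfg):
        init = tutte_embed(bump_mesh)
        emb = minimize_distortion(bump_mesh, init, cfg)
        assert emb.is_injective
        energies = [e for _, e in emb.energy_trace]
        assert all(b <= a for a, b in zip(energies, energies[1:]))

    def test_fixed_boundary_keeps_boundary_on_circle(self, bump_mesh):
        from spectromesh.meshing import boundary_loop

        emb = minimize_distortion(
            bump_mesh, tutte_embed(bump_mesh), FlattenConfig(boundary="fixed")
        )
        r = np.linalg.norm(emb.uv[boundary_loop(bump_mesh)], axis=1)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)


class TestEnergyModelGradients:
    @pytest.mark.parametrize("objective", ["symmetric_dirichlet", "mips"])
    def test_gradient_matches_central_differences(self, objective, rng):
        mesh = random_grid_mesh(4, amplitude=0.5, seed=2)
        model = _EnergyModel(mesh, objective)
        uv = tutte_embed(mesh).uv
        _, grad = model.energy_grad(uv)
        h = 1e-6
        for v, a in [(0, 0), (5, 1), (10, 0), (15, 1)]:
            d = np.zeros_like(uv)
            d[v, a] = h
            fd = (model.energy(uv + d) - model.energy(uv - d)) / (2 * h)
            assert grad[v, a] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_flip_step_bound_is_sharp(self, rng):
        mesh = random_grid_mesh(4, amplitude=0.3, seed=5)
        model = _EnergyModel(mesh, "symmetric_dirichlet")
        uv = tutte_embed(mesh).uv
        direction = rng.standard_normal(uv.shape)
        s_max = model.max_flip_free_step(uv, direction)
        if np.isfinite(s_max):
            _, _, s2 = triangle_jacobians(mesh, uv + 0.999 * s_max * direction)
            assert np.all(s2 > 0)
            _, _, s2 = triangle_jacobians(mesh, uv + 1.5 * s_max * direction)
            assert np.any(s2 <= 1e-9)


class TestFlattenConfig:
    def test_free_boundary_requires_barrier_energy(self):
        with pytest.raises(ValueError, match="unsupported objective"):
            FlattenConfig(optimized_energy="arap")

    def test_newton_requires_symmetric_dirichlet(self):
        with pytest.raises(ValueError, match="Newton"):
            FlattenConfig(optimized_energy="mips", method="newton")

    def test_bad_shrink_rejected(self):
        with pytest.raises(ValueError, match="shrink"):
            FlattenConfig(line_search_shrink=1.5)
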