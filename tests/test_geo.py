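"""Kernel geographic projection and the two smoothing stages."""

import numpy as np
import pytest

import lvfield as lv
from lvfield.geo import auto_sigma, gaussian_kernel, make_grid

from conftest import random_coords, random_trait_matrix


def pc_field(pcs, vectors, ids=None):
    n = pcs.shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    return lv.VelocityField("pc", pcs, vectors, ids=ids)


def embedding_of(pcs, ids=None):
    n = pcs.shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    return lv.PCEmbedding(ids, pcs, np.eye(max(2, pcs.shape[1]))[:, :2], np.ones(2), np.zeros(2))


class TestTransitionProbabilities:
    def compass(self):
        # sample 0 at origin; neighbours at E, N, W, S
        pcs = np.array([[0.0, 0.0], [1, 0], [0, 1], [-1, 0], [0, -1]])
        v = np.zeros((5, 2))
        v[0] = [1.0, 0.0]
        return pcs, v

    def test_softmax_of_cosines_hand_value(self):
        """Softmax over cosine alignments: neighbours at the four compass
        points with velocity due East and tau=1 give e^{(1,0,-1,0)} / sum."""
        pcs, v = self.compass()
        kern = lv.transition_probabilities(pc_field(pcs, v), embedding_of(pcs), 4, tau=1.0)
        row = {j: p for j, p in zip(kern.neighbour_index[0], kern.P[0])}
        e = np.exp(np.array([1.0, 0.0, -1.0, 0.0]))
        expected = e / e.sum()  # E, N, W, S
        for j, exp_p in zip([1, 2, 3, 4], expected):
            assert row[j] == pytest.approx(exp_p, abs=1e-12)

    def test_low_temperature_concentrates_on_aligned_neighbour(self):
        pcs, v = self.compass()
        kern = lv.transition_probabilities(pc_field(pcs, v), embedding_of(pcs), 4, tau=1e-3)
        row = {j: p for j, p in zip(kern.neighbour_index[0], kern.P[0])}
        assert row[1] == pytest.approx(1.0, abs=1e-9)

    def test_zero_velocity_row_is_uniform(self):
        pcs, _ = self.compass()
        kern = lv.transition_probabilities(pc_field(pcs, np.zeros((5, 2))), embedding_of(pcs), 4)
        np.testing.assert_allclose(kern.P, 0.25)

    def test_rows_are_stochastic_for_any_tau(self, rng):
        pcs = rng.normal(size=(12, 2))
        v = rng.normal(size=(12, 2))
        for tau in (0.01, 0.05, 1.0, 10.0):
            kern = lv.transition_probabilities(pc_field(pcs, v), embedding_of(pcs), 5, tau)
            np.testing.assert_allclose(kern.P.sum(axis=1), 1.0, atol=1e-12)
            assert (kern.P >= 0).all()

    def test_self_excluded_from_neighbours(self, rng):
        pcs = rng.normal(size=(8, 2))
        kern = lv.transition_probabilities(
            pc_field(pcs, rng.normal(size=(8, 2))), embedding_of(pcs), 7
        )
        for l in range(8):
            assert l not in kern.neighbour_index[l]


class TestProjectGeo:
    def test_uniform_row_gives_zero_vector(self, rng):
        coords = random_coords(rng, n=6)
        kern = lv.TransitionKernel(
            coords.sample_ids,
            np.tile(np.arange(1, 6), (6, 1)) % 6,
            np.full((6, 5), 0.2),
            tau=0.05,
        )
        out = lv.project_geo(kern, coords)
        np.testing.assert_allclose(out.vectors, 0.0, atol=1e-12)

    def test_two_neighbour_hand_value(self):
        # neighbours due East and West of sample 0 with P = (1, 0)
        coords = lv.CoordinateTable(["a", "b", "c"], np.array([0.0, 1.0, -1.0]), np.zeros(3))
        kern = lv.TransitionKernel(
            ["a", "b", "c"],
            np.array([[1, 2], [0, 2], [0, 1]]),
            np.array([[1.0, 0.0], [0.5, 0.5], [0.5, 0.5]]),
            tau=0.05,
        )
        out = lv.project_geo(kern, coords)
        np.testing.assert_allclose(out.vectors[0], [1.0, 0.0], atol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        """Vectorised projection equals an explicit double loop to 1e-12."""
        n, s = 10, 4
        coords = random_coords(rng, n=n)
        pcs = rng.normal(size=(n, 2))
        v = rng.normal(size=(n, 2))
        kern = lv.transition_probabilities(pc_field(pcs, v), embedding_of(pcs), s)
        out = lv.project_geo(kern, coords)
        xy = coords.xy
        for l in range(n):
            expected = np.zeros(2)
            for jj, j in enumerate(kern.neighbour_index[l]):
                disp = xy[j] - xy[l]
                norm = np.linalg.norm(disp)
                if norm > 0:
                    expected += (kern.P[l, jj] - 1.0 / s) * disp / norm
            np.testing.assert_allclose(out.vectors[l], expected, atol=1e-12)

    def test_translation_and_rotation_equivariance(self, rng):
        n, s = 9, 4
        coords = random_coords(rng, n=n)
        pcs = rng.normal(size=(n, 2))
        v = rng.normal(size=(n, 2))
        kern = lv.transition_probabilities(pc_field(pcs, v), embedding_of(pcs), s)
        base = lv.project_geo(kern, coords).vectors
        shifted = lv.CoordinateTable(coords.sample_ids, coords.lon + 3, coords.lat - 2)
        np.testing.assert_allclose(lv.project_geo(kern, shifted).vectors, base, atol=1e-12)
        th = 0.3
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy_rot = coords.xy @ rot.T
        rotated = lv.CoordinateTable(coords.sample_ids, xy_rot[:, 0], xy_rot[:, 1])
        np.testing.assert_allclose(
            lv.project_geo(kern, rotated).vectors, base @ rot.T, atol=1e-12
        )


class TestSpatialSmooth:
    def test_equal_lengths_unchanged(self, rng):
        coords = random_coords(rng, n=5)
        angles = rng.uniform(0, 2 * np.pi, 5)
        geo = lv.VelocityField(
            "geo", coords.xy, 0.7 * np.column_stack([np.cos(angles), np.sin(angles)]),
            ids=coords.sample_ids,
        )
        pc = pc_field(rng.normal(size=(5, 2)),
                      0.3 * np.column_stack([np.cos(angles), np.sin(angles)]),
                      ids=coords.sample_ids)
        out = lv.spatial_smooth(geo, pc, coords, sigma_geo=2.0)
        np.testing.assert_allclose(out.lengths(), 0.3, atol=1e-12)

    def test_directions_untouched(self, rng):
        coords = random_coords(rng, n=8)
        geo = lv.VelocityField("geo", coords.xy, rng.normal(size=(8, 2)), ids=coords.sample_ids)
        pc = pc_field(rng.normal(size=(8, 2)), rng.normal(size=(8, 2)), ids=coords.sample_ids)
        out = lv.spatial_smooth(geo, pc, coords)
        u_in = geo.vectors / geo.lengths()[:, None]
        u_out = out.vectors / out.lengths()[:, None]
        np.testing.assert_allclose(u_out, u_in, atol=1e-12)

    def test_two_clusters_homogenise_within_not_across(self):
        """Two distant pairs with different lengths under a small bandwidth:
        lengths agree within each pair, differ across pairs."""
        coords = lv.CoordinateTable(
            ["a", "b", "c", "d"],
            np.array([0.0, 0.1, 100.0, 100.1]),
            np.zeros(4),
        )
        geo = lv.VelocityField(
            "geo", coords.xy, np.array([[1.0, 0], [1, 0], [1, 0], [1, 0]]),
            ids=coords.sample_ids,
        )
        pc = pc_field(
            np.zeros((4, 2)),
            np.array([[1.0, 0], [3, 0], [5.0, 0], [7, 0]]),
            ids=coords.sample_ids,
        )
        out = lv.spatial_smooth(geo, pc, coords, sigma_geo=0.5)
        lens = out.lengths()
        assert lens[0] == pytest.approx(lens[1], rel=0.02)
        assert lens[2] == pytest.approx(lens[3], rel=0.02)
        assert abs(lens[0] - lens[2]) > 1.0
        # hand value: within a pair the kernel-weighted mean of (1, 3) is
        # dominated by weights w(0)=1, w(0.1); both lengths near 2
        assert 1.9 < lens[0] < 2.1

    def test_zero_vectors_stay_zero(self, rng):
        coords = random_coords(rng, n=5)
        vec = rng.normal(size=(5, 2))
        vec[2] = 0.0
        geo = lv.VelocityField("geo", coords.xy, vec, ids=coords.sample_ids)
        pc = pc_field(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), ids=coords.sample_ids)
        out = lv.spatial_smooth(geo, pc, coords)
        np.testing.assert_array_equal(out.vectors[2], [0.0, 0.0])


class TestGridSmooth:
    def test_identical_vectors_reproduced_on_grid(self, rng):
        coords = random_coords(rng, n=6)
        vec = np.tile([[0.3, -0.4]], (6, 1))
        field = lv.VelocityField("geo", coords.xy, vec, ids=coords.sample_ids)
        grid = lv.grid_smooth(field, coords, nx=10, ny=10)
        sup = grid.supported
        np.testing.assert_allclose(grid.vectors[sup], np.tile([0.3, -0.4], (sup.sum(), 1)), atol=1e-12)

    def test_small_bandwidth_recovers_nearest_sample_vector(self, rng):
        coords = lv.CoordinateTable(["a", "b"], np.array([0.0, 10.0]), np.array([0.0, 0.0]))
        vec = np.array([[1.0, 0.0], [0.0, 1.0]])
        field = lv.VelocityField("geo", coords.xy, vec, ids=["a", "b"])
        grid = lv.grid_smooth(
            field, coords, grid_coords=np.array([[0.0, 0.0]]),
            s_grid=2, sigma_geo=1e-3, support_radius=1.0,
        )
        np.testing.assert_allclose(grid.vectors[0], [1.0, 0.0], atol=1e-9)

    def test_matches_naive_kernel_sum(self, rng):
        coords = random_coords(rng, n=7)
        field = lv.VelocityField("geo", coords.xy, rng.normal(size=(7, 2)), ids=coords.sample_ids)
        sigma = 3.0
        s = 4
        grid = lv.grid_smooth(field, coords, s_grid=s, sigma_geo=sigma, nx=6, ny=6)
        xy = coords.xy
        for g in range(grid.n_points):
            cg = grid.grid_coords[g]
            d = np.linalg.norm(xy - cg, axis=1)
            nbrs = np.argsort(d, kind="stable")[:s]
            w = np.exp(-d[nbrs] ** 2 / (2 * sigma**2))
            expected = (w[:, None] * field.vectors[nbrs]).sum(axis=0) / w.sum()
            if d.min() > 2 * sigma:
                expected = np.zeros(2)
            np.testing.assert_allclose(grid.vectors[g], expected, atol=1e-12)

    def test_unsupported_points_zeroed(self, rng):
        coords = lv.CoordinateTable(["a", "b", "c"], np.array([0.0, 1.0, 2.0]), np.zeros(3))
        field = lv.VelocityField("geo", coords.xy, np.ones((3, 2)), ids=coords.sample_ids)
        grid = lv.grid_smooth(field, coords, sigma_geo=0.1, support_radius=0.05, nx=5, ny=5)
        assert (~grid.supported).any()
        np.testing.assert_array_equal(grid.vectors[~grid.supported], 0.0)

    def test_degenerate_bounding_box_rejected(self):
        coords = lv.CoordinateTable(["a", "b", "c"], np.zeros(3), np.zeros(3))
        with pytest.raises(lv.ValidationError, match="coincide|degenerate"):
            make_grid(coords)


class TestScaleInvariance:
    def test_grid_directions_invariant_to_global_length_scaling(self, rng):
        coords = random_coords(rng, n=8)
        vec = rng.normal(size=(8, 2))
        f1 = lv.VelocityField("geo", coords.xy, vec, ids=coords.sample_ids)
        f2 = lv.VelocityField("geo", coords.xy, 7.3 * vec, ids=coords.sample_ids)
        g1 = lv.grid_smooth(f1, coords, nx=8, ny=8)
        g2 = lv.grid_smooth(f2, coords, nx=8, ny=8)
        sup = g1.supported
        u1 = g1.vectors[sup] / np.linalg.norm(g1.vectors[sup], axis=1)[:, None]
        u2 = g2.vectors[sup] / np.linalg.norm(g2.vectors[sup], axis=1)[:, None]
        np.testing.assert_allclose(u1, u2, atol=1e-12)
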