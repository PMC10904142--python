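"""The GCP module: equivariance of every sub-operation and of the whole."""

import numpy as np
import pytest

from gcpnet.autodiff import Tensor
from gcpnet.gcp_core import GCP, GCPConfig, ResGCP, ScalarVector, scalarize
from gcpnet.geometry import centralize, knn_graph, localize, random_rotation


def make_geometry(seed=0, n=8, k=3):
    rng = np.random.default_rng(seed)
    x, _ = centralize(rng.normal(size=(n, 3)))
    edges = knn_graph(x, k)
    return x, edges, localize(x, edges)


def rotate_vec(v: np.ndarray, q: np.ndarray) -> np.ndarray:
    return v @ q.T


class TestChannelDownscaling:
    def test_zero_input_maps_to_zero(self, rng):
        gcp = GCP(rng, (4, 6), (5, 2), GCPConfig(lambda_down=3))
        z = gcp.downscale_z(Tensor(np.zeros((7, 6, 3))))
        vs = gcp.downscale_vs(Tensor(np.zeros((7, 6, 3))))
        np.testing.assert_array_equal(z.data, 0.0)
        np.testing.assert_array_equal(vs.data, 0.0)
        assert z.shape == (7, 2, 3)      # ceil(6/3) = 2 channels
        assert vs.shape == (7, 3, 3)     # always three probe channels

    def test_identity_map_with_lambda_one(self, rng):
        gcp = GCP(rng, (4, 3), (5, 2), GCPConfig(lambda_down=1))
        gcp.params["w_dz"].data = np.eye(3)
        v = rng.normal(size=(5, 3, 3))
        np.testing.assert_allclose(gcp.downscale_z(Tensor(v)).data, v)

    def test_rotation_equivariance(self, rng):
        gcp = GCP(rng, (4, 5), (5, 2), GCPConfig())
        v = rng.normal(size=(6, 5, 3))
        q = random_rotation(rng)
        for op in (gcp.downscale_z, gcp.downscale_vs):
            rotated_out = op(Tensor(rotate_vec(v, q))).data
            np.testing.assert_allclose(rotated_out,
                                       rotate_vec(op(Tensor(v)).data, q),
                                       atol=1e-12)


class TestScalarize:
    def test_zero_probes_give_zero(self):
        x, edges, frames = make_geometry()
        q = scalarize(Tensor(np.zeros((len(edges), 3, 3))), frames.matrix,
                      edges, "edge")
        np.testing.assert_array_equal(q.data, 0.0)

    def test_probe_equal_to_frame_axis_gives_unit_entry(self):
        x, edges, frames = make_geometry()
        vs = np.zeros((len(edges), 3, 3))
        vs[:, 0, :] = frames.a           # channel 1 = the a axis itself
        q = scalarize(Tensor(vs), frames.matrix, edges, "edge").data
        expected = np.zeros((len(edges), 9))
        expected[:, 0] = 1.0             # channel-major, axis order (a, b, c)
        np.testing.assert_allclose(q, expected, atol=1e-10)

    def test_invariant_under_joint_rotation(self, rng):
        x, edges, _ = make_geometry(1)
        vs = rng.normal(size=(len(edges), 3, 3))
        q_ref = scalarize(Tensor(vs), localize(x, edges).matrix, edges, "edge").data
        rot = random_rotation(rng)
        q_rot = scalarize(Tensor(rotate_vec(vs, rot)),
                          localize(x @ rot.T, edges).matrix, edges, "edge").data
        np.testing.assert_allclose(q_rot, q_ref, atol=1e-12)

    def test_point_inversion_flips_a_and_c_entries_only(self, rng):
        # probes held fixed, geometry inverted: entries against a and c flip
        x, edges, _ = make_geometry(2)
        vs = rng.normal(size=(len(edges), 3, 3))
        q_ref = scalarize(Tensor(vs), localize(x, edges).matrix, edges, "edge").data
        q_inv = scalarize(Tensor(vs), localize(-x, edges).matrix, edges, "edge").data
        sign = np.tile([-1.0, 1.0, -1.0], 3)
        np.testing.assert_allclose(q_inv, q_ref * sign, atol=1e-12)

    def test_node_mode_averages_over_out_edges_and_zeroes_isolated(self, rng):
        x, edges, frames = make_geometry(3, n=6, k=2)
        vs = rng.normal(size=(6, 3, 3))
        q = scalarize(Tensor(vs), frames.matrix, edges, "node", n_nodes=7).data
        assert q.shape == (7, 9)
        np.testing.assert_array_equal(q[6], 0.0)   # node with no out-edges
        # manual mean for node 0
        mask = edges[:, 0] == 0
        manual = np.einsum("ecx,eax->eca", np.repeat(vs[0][None], mask.sum(), 0),
                           frames.matrix[mask]).reshape(mask.sum(), 9).mean(0)
        np.testing.assert_allclose(q[0], manual, atol=1e-12)


class TestScalarUpdate:
    def test_zero_inputs_propagate_through_silu(self, rng):
        gcp = GCP(rng, (4, 3), (5, 2), GCPConfig())
        s_out, sv = gcp.update_scalars(
            Tensor(np.zeros((3, 4))), Tensor(np.zeros((3, 9))),
            Tensor(np.zeros((3, 1, 3))))
        # zero inputs reach the affine map except for the eps-guarded
        # ||z|| features (1e-8 per channel), so sv is zero to that guard
        assert np.abs(sv.data).max() < 1e-8
        assert np.abs(s_out.data).max() < 1e-8           # silu(0) = 0

    def test_z_norm_feature_is_euclidean_length(self, rng):
        gcp = GCP(rng, (1, 3), (2, 1), GCPConfig(lambda_down=3))
        gcp.params["w_s"].data = np.zeros_like(gcp.params["w_s"].data)
        # scalar layout: [s (1), q (9), ||z|| (1)]; pick out the norm slot
        gcp.params["w_s"].data[10, 0] = 1.0
        gcp.params["b_s"].data[:] = 0.0
        z = Tensor(np.array([[[3.0, 4.0, 0.0]]]))
        _, sv = gcp.update_scalars(Tensor(np.zeros((1, 1))),
                                   Tensor(np.zeros((1, 9))), z)
        np.testing.assert_allclose(sv.data[0, 0], 5.0, atol=1e-7)

    def test_rejects_non_finite_scalars(self, rng):
        gcp = GCP(rng, (2, 0), (3, 0), GCPConfig())
        with pytest.raises(ValueError, match="finite"):
            gcp(ScalarVector(Tensor(np.array([[np.inf, 0.0]])), None),
                None, None, "node", 1)


class TestVectorUpdate:
    def test_open_gate_recovers_linear_map(self, rng):
        gcp = GCP(rng, (4, 3), (5, 2), GCPConfig())
        gcp.params["b_g"].data[:] = 1e4          # sigmoid -> 1
        gcp.params["w_g"].data[:] = 0.0
        z = Tensor(rng.normal(size=(6, 1, 3)))
        sv = Tensor(rng.normal(size=(6, 5)))
        from gcpnet.autodiff import channel_map
        vu = channel_map(z, gcp.params["w_uz"]).data
        np.testing.assert_allclose(gcp.update_vectors(z, sv).data, vu, atol=1e-12)

    def test_zero_z_gives_zero_vectors(self, rng):
        gcp = GCP(rng, (4, 3), (5, 2), GCPConfig())
        out = gcp.update_vectors(Tensor(np.zeros((6, 1, 3))),
                                 Tensor(rng.normal(size=(6, 5))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_equivariance_with_invariant_gate(self, rng):
        gcp = GCP(rng, (4, 3), (5, 2), GCPConfig())
        z = rng.normal(size=(6, 1, 3))
        sv = Tensor(rng.normal(size=(6, 5)))
        q = random_rotation(rng)
        out_ref = gcp.update_vectors(Tensor(z), sv).data
        out_rot = gcp.update_vectors(Tensor(rotate_vec(z, q)), sv).data
        np.testing.assert_allclose(out_rot, rotate_vec(out_ref, q), atol=1e-12)


class TestGCPForward:
    def _inputs(self, seed, invert=False, rotate=None):
        rng = np.random.default_rng(seed)
        x, edges, _ = make_geometry(seed)
        s = rng.normal(size=(8, 4))
        v = rng.normal(size=(8, 3, 3))
        if rotate is not None:
            x, v = x @ rotate.T, rotate_vec(v, rotate)
        if invert:
            x, v = -x, -v
        frames = localize(x, edges)
        return ScalarVector(Tensor(s), Tensor(v)), frames.matrix, edges

    def test_se3_audit_scalars_invariant_vectors_equivariant(self, rng):
        gcp = GCP(np.random.default_rng(0), (4, 3), (5, 2), GCPConfig())
        sv, f, edges = self._inputs(4)
        out_ref = gcp(sv, f, edges, "node", 8)
        q = random_rotation(rng)
        sv_r, f_r, _ = self._inputs(4, rotate=q)
        out_rot = gcp(sv_r, f_r, edges, "node", 8)
        np.testing.assert_allclose(out_rot.s.data, out_ref.s.data, atol=1e-12)
        np.testing.assert_allclose(out_rot.V.data,
                                   rotate_vec(out_ref.V.data, q), atol=1e-12)

    def test_mirror_pairs_differ_with_frames_but_not_without(self):
        for use_frames, should_differ in ((True, True), (False, False)):
            gcp = GCP(np.random.default_rng(0), (4, 3), (5, 2),
                      GCPConfig(use_frames=use_frames))
            sv, f, edges = self._inputs(5)
            sv_m, f_m, _ = self._inputs(5, invert=True)
            out = gcp(sv, f, edges, "node", 8).s.data
            out_m = gcp(sv_m, f_m, edges, "node", 8).s.data
            diff = np.abs(out - out_m).max()
            assert (diff > 1e-3) == should_differ

    def test_rejects_width_mismatch(self, rng):
        gcp = GCP(rng, (4, 3), (5, 2), GCPConfig())
        sv, f, edges = self._inputs(6)
        bad = ScalarVector(sv.s, Tensor(np.zeros((8, 2, 3))))
        with pytest.raises(ValueError, match="width mismatch"):
            gcp(bad, f, edges, "node", 8)

    def test_rejects_all_zero_output_widths(self, rng):
        with pytest.raises(ValueError):
            GCP(rng, (4, 3), (0, 0), GCPConfig())
        with pytest.raises(ValueError, match="equivariance"):
            GCP(rng, (4, 0), (2, 1), GCPConfig())


class TestResGCP:
    def test_zero_initialized_final_maps_give_identity(self, rng):
        res = ResGCP(rng, (4, 2), GCPConfig())
        res.gcp.params["w_s"].data[:] = 0.0
        res.gcp.params["b_s"].data[:] = 0.0
        res.gcp.params["w_uz"].data[:] = 0.0
        x, edges, frames = make_geometry(7)
        sv = ScalarVector(Tensor(rng.normal(size=(8, 4))),
                          Tensor(rng.normal(size=(8, 2, 3))))
        out = res(sv, frames.matrix, edges, "node", 8)
        np.testing.assert_allclose(out.s.data, sv.s.data, atol=1e-15)
        np.testing.assert_allclose(out.V.data, sv.V.data, atol=1e-15)

    def test_equals_gcp_plus_input(self, rng):
        res = ResGCP(np.random.default_rng(3), (4, 2), GCPConfig())
        x, edges, frames = make_geometry(8)
        sv = ScalarVector(Tensor(rng.normal(size=(8, 4))),
                          Tensor(rng.normal(size=(8, 2, 3))))
        direct = res.gcp(sv, frames.matrix, edges, "node", 8)
        wrapped = res(sv, frames.matrix, edges, "node", 8)
        np.testing.assert_allclose(wrapped.s.data, direct.s.data + sv.s.data)
        np.testing.assert_allclose(wrapped.V.data, direct.V.data + sv.V.data)
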