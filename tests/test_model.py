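"""Featurization contracts and the encode-process-decode network."""

import numpy as np
import pytest

import hemograph as hg
from hemograph.errors import ConfigurationError
from hemograph.model import (
    ACCELERATION_COLS,
    VELOCITY_COLS,
    EncodeProcessDecode,
    ModelConfig,
    add_training_noise,
    apply_boundary_conditions,
    count_parameters,
    featurize_edges,
    featurize_from_trajectory,
    featurize_nodes,
    inflow_context,
    mlp_parameter_count,
    one_hot_types,
)


@pytest.fixture(scope="module")
def small_setup(tube_coarse, waveform):
    traj = hg.make_analytic_trajectory(tube_coarse, waveform, dt=0.01,
                                       n_cycles=0.06)
    return tube_coarse, waveform, traj


def _frozen_model(traj, cfg, waveform, seed=0):
    model = EncodeProcessDecode(cfg, seed=seed)
    nf = featurize_from_trajectory(traj, 1, cfg, waveform)
    _, _, ef = featurize_edges(traj.mesh)
    model.normalizer.accumulate(
        nf, ef, traj.frames[2].velocity - traj.frames[1].velocity
    )
    model.normalizer.freeze()
    return model


class TestNodeFeatures:
    def test_feature_widths(self, small_setup):
        mesh, wf, traj = small_setup
        base = featurize_from_trajectory(traj, 1, ModelConfig(features="baseline"), wf)
        enh = featurize_from_trajectory(traj, 1, ModelConfig(features="in"), wf)
        assert base.shape[1] == 11
        assert enh.shape[1] == 17

    def test_inflow_context_mean_min_max(self):
        vel = np.zeros((5, 3))
        vel[:3, 0] = [1.0, 2.0, 3.0]
        mask = np.array([True, True, True, False, False])
        np.testing.assert_allclose(inflow_context(vel, mask), [2.0, 1.0, 3.0])

    def test_context_broadcast_to_every_node(self, small_setup):
        mesh, wf, traj = small_setup
        feats = featurize_from_trajectory(traj, 1, ModelConfig(features="in"), wf)
        ctx = feats[:, 14:17]
        assert np.all(ctx == ctx[0])

    def test_one_hot_rows_sum_to_one(self, small_setup):
        mesh, _, _ = small_setup
        oh = one_hot_types(mesh.node_type)
        np.testing.assert_array_equal(oh.sum(axis=1), 1.0)
        assert oh.shape[1] == 4

    def test_acceleration_needs_previous_frame(self, small_setup):
        mesh, wf, traj = small_setup
        with pytest.raises(ConfigurationError):
            featurize_from_trajectory(traj, 0, ModelConfig(features="in"), wf)

    def test_acceleration_is_backward_difference(self, small_setup):
        mesh, wf, traj = small_setup
        feats = featurize_from_trajectory(traj, 2, ModelConfig(features="in"), wf)
        expected = traj.frames[2].velocity - traj.frames[1].velocity
        np.testing.assert_allclose(feats[:, ACCELERATION_COLS], expected,
                                   atol=1e-12)


class TestEdgeFeatures:
    def test_axis_edge(self):
        mesh = hg.VolumetricMesh(
            positions=np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0],
                                [0, 0, 1.0]]),
            tetrahedra=np.array([[0, 1, 2, 3]]),
        ).orient()
        senders, receivers, ef = featurize_edges(mesh)
        k = np.flatnonzero((senders == 0) & (receivers == 1))[0]
        np.testing.assert_allclose(ef[k], [1, 0, 0, 1], atol=1e-15)
        kr = np.flatnonzero((senders == 1) & (receivers == 0))[0]
        np.testing.assert_allclose(ef[kr], [-1, 0, 0, 1], atol=1e-15)

    def test_norm_column_matches_distance(self, tube_coarse):
        senders, receivers, ef = featurize_edges(tube_coarse)
        d = np.linalg.norm(
            tube_coarse.positions[receivers] - tube_coarse.positions[senders],
            axis=1,
        )
        np.testing.assert_allclose(ef[:, 3], d, atol=1e-12)

    def test_both_directions_present(self, tube_coarse):
        senders, receivers, _ = featurize_edges(tube_coarse)
        und = hg.extract_edges(tube_coarse)
        assert senders.shape[0] == 2 * und.shape[0]


class TestTrainingNoise:
    def test_zero_eta_is_identity(self, small_setup):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(features="in")
        feats = featurize_from_trajectory(traj, 1, cfg, wf)
        out = add_training_noise(feats, 0.0, 100.0, np.random.default_rng(0), cfg)
        assert out is feats

    def test_seeded_reproducibility(self, small_setup):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(features="in")
        feats = featurize_from_trajectory(traj, 1, cfg, wf)
        a = add_training_noise(feats, 0.05, 100.0, np.random.default_rng(7), cfg)
        b = add_training_noise(feats, 0.05, 100.0, np.random.default_rng(7), cfg)
        np.testing.assert_array_equal(a, b)

    def test_only_dynamical_columns_perturbed(self, small_setup):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(features="in")
        feats = featurize_from_trajectory(traj, 1, cfg, wf)
        out = add_training_noise(feats, 0.1, 100.0, np.random.default_rng(1), cfg)
        static = np.r_[3:11, 14:17]
        np.testing.assert_array_equal(out[:, static], feats[:, static])
        assert np.any(out[:, VELOCITY_COLS] != feats[:, VELOCITY_COLS])

    def test_empirical_std(self):
        cfg = ModelConfig(features="baseline")
        feats = np.zeros((100_000, 11))
        eta, sigma_v = 0.03, 250.0
        out = add_training_noise(feats, eta, sigma_v, np.random.default_rng(2), cfg)
        emp = out[:, 0:3].std()
        assert emp == pytest.approx(eta * sigma_v, rel=0.05)


class TestNetwork:
    def test_permutation_equivariance(self, small_setup):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(latent_width=16, message_passing_rounds=3,
                          features="in")
        model = _frozen_model(traj, cfg, wf)
        nf = featurize_from_trajectory(traj, 1, cfg, wf)
        senders, receivers, ef = featurize_edges(mesh)
        out = model.predict_delta(nf, ef, senders, receivers)
        rng = np.random.default_rng(0)
        perm = rng.permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        out_p = model.predict_delta(nf[perm], ef, inv[senders].astype(senders.dtype),
                                    inv[receivers].astype(receivers.dtype))
        np.testing.assert_allclose(out_p, out[perm], atol=1e-6)

    def test_zeroed_decoder_outputs_zero(self, small_setup):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(latent_width=8, message_passing_rounds=2, features="in")
        model = _frozen_model(traj, cfg, wf)
        for W, b in model.decoder["layers"]:
            W.data[:] = 0.0
            b.data[:] = 0.0
        model.normalizer.out_mean = np.zeros(3)
        nf = featurize_from_trajectory(traj, 1, cfg, wf)
        senders, receivers, ef = featurize_edges(mesh)
        delta = model.predict_delta(nf, ef, senders, receivers)
        np.testing.assert_array_equal(delta, 0.0)

    def test_default_config_runs_15_blocks(self):
        cfg = ModelConfig()
        model = EncodeProcessDecode(cfg, seed=0)
        assert len(model.blocks) == 15
        assert cfg.latent_width == 128

    def test_checkpoint_round_trip(self, small_setup, tmp_path):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(latent_width=8, message_passing_rounds=2, features="in")
        model = _frozen_model(traj, cfg, wf)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = EncodeProcessDecode.load(path)
        nf = featurize_from_trajectory(traj, 1, cfg, wf)
        senders, receivers, ef = featurize_edges(mesh)
        np.testing.assert_array_equal(
            model.predict_delta(nf, ef, senders, receivers),
            back.predict_delta(nf, ef, senders, receivers),
        )


class TestLargeGraphForward:
    def test_reference_scale_forward_completes(self, waveform):
        """One inference pass of the full reference architecture (width 128,
        15 rounds, 17 features) on a ~20k-node mesh runs on a single CPU."""
        spec = hg.GeometrySpec()  # default 0.3 mm target edge length
        mesh = hg.make_semi_idealized_geometry(spec, seed=0)
        assert mesh.n_nodes > 15_000
        traj = hg.make_analytic_trajectory(mesh, waveform, dt=0.08,
                                           n_cycles=0.3,
                                           kind="rigid-rotation")
        cfg = ModelConfig(features="in", dtype="float32")
        model = EncodeProcessDecode(cfg, seed=0)
        nf = featurize_from_trajectory(traj, 1, cfg, waveform=None)
        senders, receivers, ef = featurize_edges(mesh)
        model.normalizer.accumulate(
            nf, ef, traj.frames[2].velocity - traj.frames[1].velocity)
        model.normalizer.freeze()
        delta = model.predict_delta(nf, ef, senders, receivers)
        assert delta.shape == (mesh.n_nodes, 3)
        assert np.all(np.isfinite(delta))


class TestParameterCount:
    def test_toy_hand_tally(self):
        # width 4, 1 hidden layer, in 2 -> out 3, no layernorm:
        # (2*4+4) + (4*3+3) = 27
        assert mlp_parameter_count(2, 4, 1, 3, layernorm=False) == 27
        # with layernorm on the 3-wide output: +6
        assert mlp_parameter_count(2, 4, 1, 3, layernorm=True) == 33

    def test_count_matches_instantiated_model(self):
        cfg = ModelConfig(latent_width=8, message_passing_rounds=2,
                          features="baseline")
        model = EncodeProcessDecode(cfg, seed=0)
        assert model.n_parameters() == count_parameters(cfg)

    def test_monotone_in_rounds(self):
        counts = [
            count_parameters(ModelConfig(message_passing_rounds=r))
            for r in (1, 5, 15)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_reference_config_order_of_magnitude(self):
        """The width-128 / 15-round / 17-feature tally lands in the millions
        (reported, not pinned: the architecture's exact count is config-
        dependent)."""
        n = count_parameters(ModelConfig())
        assert 1e6 < n < 5e6


class TestPredictNext:
    def test_zeroed_decoder_identity_with_bcs(self, small_setup):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(latent_width=8, message_passing_rounds=2, features="in")
        model = _frozen_model(traj, cfg, wf)
        for W, b in model.decoder["layers"]:
            W.data[:] = 0.0
            b.data[:] = 0.0
        model.normalizer.out_mean = np.zeros(3)
        model.normalizer.out_std = np.ones(3)
        frame = hg.predict_next(model, traj, 1, wf)
        inlet = mesh.node_type == hg.INLET
        wall = mesh.node_type == hg.WALL
        free = ~inlet & ~wall
        np.testing.assert_array_equal(frame.velocity[free],
                                      traj.frames[1].velocity[free])
        np.testing.assert_array_equal(frame.velocity[wall], 0.0)
        expected_inlet = hg.parabolic_inlet(mesh, traj.frames[2].time, wf)
        np.testing.assert_allclose(frame.velocity[inlet],
                                   expected_inlet[inlet], atol=1e-12)

    def test_wall_exactly_zero_any_model(self, small_setup):
        mesh, wf, traj = small_setup
        cfg = ModelConfig(latent_width=8, message_passing_rounds=2, features="in")
        model = _frozen_model(traj, cfg, wf, seed=42)
        frame = hg.predict_next(model, traj, 1, wf)
        np.testing.assert_array_equal(
            frame.velocity[mesh.node_type == hg.WALL], 0.0
        )

    def test_inlet_flux_tracks_waveform(self, waveform):
        """The prescribed inlet of a prediction carries the waveform's flow
        within quadrature tolerance."""
        from hemograph.synth import inlet_surface_flux

        mesh = hg.make_tube_mesh(radius=2.0, length=4.0, h=0.3)
        traj = hg.make_analytic_trajectory(mesh, waveform, dt=0.01,
                                           n_cycles=0.06)
        cfg = ModelConfig(latent_width=8, message_passing_rounds=2, features="in")
        model = _frozen_model(traj, cfg, waveform)
        frame = hg.predict_next(model, traj, 1, waveform)
        q = inlet_surface_flux(mesh, frame.velocity)
        assert q == pytest.approx(waveform(traj.frames[2].time), rel=0.02)

    def test_boundary_override_helper(self, small_setup):
        mesh, wf, traj = small_setup
        u = np.full((mesh.n_nodes, 3), 5.0)
        inlet_field = hg.parabolic_inlet(mesh, 0.4, wf)
        out = apply_boundary_conditions(mesh, u, inlet_field)
        assert np.all(out[mesh.node_type == hg.WALL] == 0.0)
        inlet = mesh.node_type == hg.INLET
        np.testing.assert_array_equal(out[inlet], inlet_field[inlet])
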