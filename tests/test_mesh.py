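"""Mesh containers, connectivity, classification, normals, interpolation,
slicing and trajectory I/O."""

import numpy as np
import pytest

import hemograph as hg
from hemograph.errors import (
    ConfigurationError,
    EmptySliceError,
    FormatError,
    StructuralError,
)
from hemograph.io import read_trajectory, write_trajectory
from hemograph.mesh import (
    DiscSpec,
    FlowFrame,
    Trajectory,
    VolumetricMesh,
    boundary_faces,
    interpolate_fields,
    plane_slice,
    probe_values,
)


def _two_tet_mesh():
    """Two tets sharing a triangular face: 5 nodes, 9 undirected edges."""
    pos = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float
    )
    return VolumetricMesh(
        positions=pos, tetrahedra=np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    ).orient()


class TestConnectivity:
    def test_single_tet_gives_complete_graph(self, single_tet):
        edges = hg.extract_edges(single_tet)
        assert edges.shape == (6, 2)
        assert not np.any(edges[:, 0] == edges[:, 1])

    def test_shared_face_counted_once(self):
        edges = hg.extract_edges(_two_tet_mesh())
        assert edges.shape == (9, 2)
        # every unordered pair appears exactly once
        assert np.unique(edges, axis=0).shape[0] == 9

    def test_edge_count_union_bound(self, tube_coarse):
        edges = hg.extract_edges(tube_coarse)
        assert edges.shape[0] <= 6 * tube_coarse.n_cells

    def test_degenerate_tet_rejected(self):
        mesh = VolumetricMesh(
            positions=np.eye(4, 3), tetrahedra=np.array([[0, 1, 2, 2]])
        )
        with pytest.raises(StructuralError):
            hg.extract_edges(mesh)

    def test_permutation_stability(self, rng=np.random.default_rng(7)):
        mesh = _two_tet_mesh()
        perm = rng.permutation(mesh.n_nodes)
        inv = np.argsort(perm)
        relabeled = VolumetricMesh(
            positions=mesh.positions[inv], tetrahedra=perm[mesh.tetrahedra]
        )
        e1 = {tuple(sorted(map(int, e))) for e in hg.extract_edges(mesh)}
        e2 = {
            tuple(sorted((int(inv[a]), int(inv[b]))))
            for a, b in hg.extract_edges(relabeled)
        }
        assert e1 == e2


class TestClassification:
    def test_tube_labels(self, tube_coarse):
        pos = tube_coarse.positions
        lab = tube_coarse.node_type
        mid_rim = (
            (np.abs(np.hypot(pos[:, 0], pos[:, 1]) - 2.0) < 1e-9)
            & (pos[:, 2] > 0.1)
            & (pos[:, 2] < 5.9)
        )
        assert np.all(lab[mid_rim] == hg.WALL)
        from hemograph.mesh import boundary_nodes

        interior = np.setdiff1d(np.arange(tube_coarse.n_nodes),
                                boundary_nodes(tube_coarse))
        assert np.all(lab[interior] == hg.INTERIOR)

    def test_every_boundary_node_labeled(self, tube_coarse):
        from hemograph.mesh import boundary_nodes

        lab = tube_coarse.node_type[boundary_nodes(tube_coarse)]
        assert np.all(np.isin(lab, [hg.INLET, hg.WALL, hg.OUTLET]))

    def test_four_onehot_categories(self):
        from hemograph.mesh import N_NODE_TYPES, NODE_TYPE_NAMES

        assert N_NODE_TYPES == 4
        assert NODE_TYPE_NAMES == ("inlet", "wall", "interior", "outlet")

    def test_overlapping_discs_rejected(self, tube_coarse):
        spec = DiscSpec(center=(0, 0, 0), normal=(0, 0, 1), radius=2.0)
        with pytest.raises(ConfigurationError):
            hg.classify_nodes(tube_coarse, spec, spec)


class TestWallNormals:
    def test_cylinder_normals_radial(self, tube_h03):
        pos = tube_h03.positions
        lateral = (tube_h03.node_type == hg.WALL) & (pos[:, 2] > 0.3) & (
            pos[:, 2] < 5.7
        )
        n = tube_h03.wall_normals[lateral]
        radial = pos[lateral].copy()
        radial[:, 2] = 0.0
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert np.abs(np.einsum("ij,ij->i", n, radial) - 1.0).max() < 1e-2

    def test_unit_norm(self, tube_coarse):
        wall = tube_coarse.node_type == hg.WALL
        norms = np.linalg.norm(tube_coarse.wall_normals[wall], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_planar_patch_normal_exact(self):
        """Nodes whose incident boundary faces are coplanar (the interior of
        the inlet disc) get exactly the plane normal."""
        mesh = hg.make_tube_mesh(radius=2.0, length=4.0, h=0.5)
        from hemograph.mesh import boundary_nodes

        labels = np.full(mesh.n_nodes, hg.INTERIOR)
        labels[boundary_nodes(mesh)] = hg.WALL
        mesh.node_type = labels
        normals = hg.wall_normals(mesh)
        pos = mesh.positions
        inner_disc = (
            (labels == hg.WALL)
            & (np.abs(pos[:, 2]) < 1e-12)
            & (np.hypot(pos[:, 0], pos[:, 1]) < 2.0 - 0.25)
        )
        assert inner_disc.sum() > 10
        np.testing.assert_allclose(
            normals[inner_disc],
            np.tile([0.0, 0.0, -1.0], (int(inner_disc.sum()), 1)),
            atol=1e-12,
        )


class TestInterpolation:
    def test_constant_field_exact(self, tube_coarse):
        wf = hg.InflowWaveform()
        frames = [FlowFrame(time=0.0, velocity=np.tile([1.0, 2.0, 3.0],
                                                       (tube_coarse.n_nodes, 1)))]
        traj = Trajectory(mesh=tube_coarse, frames=frames, dt=0.01)
        dst = hg.make_tube_mesh(radius=1.8, length=5.0, h=0.6)
        out, report = interpolate_fields(traj, dst)
        np.testing.assert_allclose(out.frames[0].velocity,
                                   np.tile([1.0, 2.0, 3.0], (dst.n_nodes, 1)),
                                   atol=1e-12)
        assert report.n_outside == 0

    def test_linear_field_exact(self, tube_coarse):
        A = np.array([[0.1, 2.0, 0.0], [1.0, 0.0, -3.0], [0.0, 0.5, 1.5]])
        vel = tube_coarse.positions @ A.T
        traj = Trajectory(
            mesh=tube_coarse,
            frames=[FlowFrame(time=0.0, velocity=vel)],
            dt=0.01,
        )
        dst = hg.make_tube_mesh(radius=1.5, length=4.0, h=0.7)
        out, _ = interpolate_fields(traj, dst)
        np.testing.assert_allclose(
            out.frames[0].velocity, dst.positions @ A.T, atol=1e-10
        )

    def test_round_trip_smooth_field(self, tube_h03, waveform):
        """Fine -> coarse -> fine transfer of a smooth field stays within a
        few percent, as for the light-mesh validation protocol."""
        traj = hg.make_analytic_trajectory(tube_h03, waveform, dt=0.01,
                                           n_cycles=0.02)
        coarse = hg.make_tube_mesh(radius=2.0, length=6.0, h=0.6)
        down, _ = interpolate_fields(traj, coarse)
        back, _ = interpolate_fields(down, tube_h03)
        ref = traj.frames[0].velocity
        rel = np.linalg.norm(back.frames[0].velocity - ref) / np.linalg.norm(ref)
        assert rel < 0.05

    def test_probe_at_node_and_outside(self, poiseuille_traj):
        mesh = poiseuille_traj.mesh
        node = mesh.n_nodes // 2
        series = probe_values(poiseuille_traj, mesh.positions[[node]])
        got = series[:, 0, :]
        want = np.stack([f.velocity[node] for f in poiseuille_traj.frames])
        np.testing.assert_allclose(got, want, atol=1e-9)
        with pytest.raises(hg.errors.DomainError):
            probe_values(poiseuille_traj, np.array([[50.0, 50.0, 50.0]]))


class TestPlaneSlice:
    def test_single_tet_midplane(self, single_tet):
        """Plane z = 0.5 through the unit tet cuts a right triangle with
        legs 0.5: area 1/8."""
        f = FlowFrame(time=0.0, velocity=np.zeros((4, 3)))
        sl = plane_slice(single_tet, f, (0, 0, 0.5), (0, 0, 1))
        assert sl.area == pytest.approx(0.125, rel=1e-12)

    def test_tube_cross_section_area(self, tube_h03):
        f = FlowFrame(time=0.0, velocity=np.zeros((tube_h03.n_nodes, 3)))
        sl = plane_slice(tube_h03, f, (0, 0, 3.0), (0, 0, 1))
        assert sl.area == pytest.approx(np.pi * 4.0, rel=0.02)

    def test_constant_field_on_slice(self, tube_coarse):
        vel = np.tile([3.0, -1.0, 2.0], (tube_coarse.n_nodes, 1))
        sl = plane_slice(tube_coarse, FlowFrame(time=0.0, velocity=vel),
                         (0, 0, 3.0), (0, 0, 1))
        np.testing.assert_allclose(
            sl.velocity, np.tile([3.0, -1.0, 2.0], (sl.velocity.shape[0], 1)),
            atol=1e-12,
        )

    def test_no_intersection_raises(self, tube_coarse):
        f = FlowFrame(time=0.0, velocity=np.zeros((tube_coarse.n_nodes, 3)))
        with pytest.raises(EmptySliceError):
            plane_slice(tube_coarse, f, (0, 0, 50.0), (0, 0, 1))


class TestTrajectoryIO:
    @pytest.mark.parametrize("fmt,suffix", [
        ("vtu-series", "case.pvd"), ("hdf5", "case.h5"), ("xdmf", "case.xdmf"),
    ])
    def test_round_trip_lossless(self, tmp_path, poiseuille_traj, fmt, suffix):
        path = tmp_path / suffix
        traj = poiseuille_traj
        traj.frames[0].pressure = np.linspace(0.0, 40.0, traj.mesh.n_nodes)
        for f in traj.frames[1:]:
            f.pressure = np.zeros(traj.mesh.n_nodes)
        write_trajectory(traj, path, format=fmt)
        back = read_trajectory(path, format=fmt)
        assert back.n_frames == traj.n_frames
        np.testing.assert_allclose(back.mesh.positions, traj.mesh.positions,
                                   rtol=1e-12)
        assert np.array_equal(back.mesh.tetrahedra, traj.mesh.tetrahedra)
        for a, b in zip(back.frames, traj.frames):
            np.testing.assert_allclose(a.velocity, b.velocity, rtol=1e-12)
            np.testing.assert_allclose(a.pressure, b.pressure, rtol=1e-12,
                                       atol=1e-300)
        assert back.dt == pytest.approx(traj.dt, abs=1e-12)

    def test_single_frame_zero_field(self, tmp_path, single_tet):
        single_tet.node_type = np.full(4, hg.WALL)
        hg.wall_normals(single_tet)
        traj = Trajectory(
            mesh=single_tet,
            frames=[FlowFrame(time=0.0, velocity=np.zeros((4, 3)))],
            dt=0.01,
        )
        p = tmp_path / "one.pvd"
        write_trajectory(traj, p, format="vtu-series")
        back = read_trajectory(p)
        assert back.n_frames == 1
        np.testing.assert_array_equal(back.frames[0].velocity, 0.0)

    def test_dt_inferred_from_times(self, tmp_path, tube_coarse, waveform):
        traj = hg.make_analytic_trajectory(tube_coarse, waveform, dt=0.01,
                                           n_cycles=0.04)
        p = tmp_path / "series.pvd"
        write_trajectory(traj, p, format="vtu-series")
        assert read_trajectory(p).dt == pytest.approx(0.01, abs=1e-9)

    def test_empty_trajectory_rejected(self, tmp_path, tube_coarse):
        traj = Trajectory(mesh=tube_coarse, frames=[], dt=0.01)
        with pytest.raises(StructuralError):
            write_trajectory(traj, tmp_path / "x.h5", format="hdf5")

    def test_hdf5_stores_dt_attribute(self, tmp_path, poiseuille_traj):
        import h5py

        p = tmp_path / "t.h5"
        write_trajectory(poiseuille_traj, p, format="hdf5")
        with h5py.File(p) as h5:
            assert h5.attrs["dt"] == pytest.approx(0.01)

    def test_missing_velocity_field_names_file(self, tmp_path, single_tet):
        from hemograph.io import write_vtu, read_vtu

        single_tet.node_type = None
        single_tet.wall_normals = None
        path = tmp_path / "f.vtu"
        write_vtu(path, single_tet, FlowFrame(time=0.0, velocity=np.zeros((4, 3))))
        with pytest.raises(FormatError, match="nosuch"):
            read_vtu(path, velocity_name="nosuch")

    def test_write_bit_stable(self, tmp_path, poiseuille_traj):
        a, b = tmp_path / "a.h5", tmp_path / "b.h5"
        write_trajectory(poiseuille_traj, a, format="hdf5")
        write_trajectory(poiseuille_traj, b, format="hdf5")
        import h5py

        with h5py.File(a) as ha, h5py.File(b) as hb:
            assert np.array_equal(ha["frames/velocity"][()],
                                  hb["frames/velocity"][()])


class TestInvariants:
    def test_positive_volumes_after_orient(self, tube_coarse):
        assert np.all(tube_coarse.cell_volumes() > 0)

    def test_boundary_faces_of_single_tet(self, single_tet):
        faces, owners = boundary_faces(single_tet)
        assert faces.shape == (4, 3)
        assert np.all(owners == 0)

    def test_frame_times_on_uniform_grid(self, tube_coarse):
        frames = [
            FlowFrame(time=0.0, velocity=np.zeros((tube_coarse.n_nodes, 3))),
            FlowFrame(time=0.5, velocity=np.zeros((tube_coarse.n_nodes, 3))),
        ]
        with pytest.raises(StructuralError):
            Trajectory(mesh=tube_coarse, frames=frames, dt=0.01)
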