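"""Packing-geometry measurements against generator ground truth."""

import warnings

import numpy as np
import pytest

from crystomo.geometry import (
    axes_to_table,
    find_pairs,
    fit_crystal_plane,
    fit_crystal_plane_from_pairs,
    kink_from_particle_rows,
    measure_axes_from_density,
    measure_head_height,
    measure_inclination,
    measure_interface_rotation,
    measure_pair_angle,
    midmembrane_positions,
    predict_dimer_angle,
    reposition_average,
    trace_membrane_kink,
)
from crystomo.particles import ParticleTable
from crystomo.synthetic import CrystalSpec, PhantomSpec, build_crystal_volume
from crystomo.transforms import RigidTransform
from crystomo.volume import DensityVolume


@pytest.fixture(scope="module")
def rigid_crystal(default_config):
    """Noiseless, jitter-free default crystal (exact read-back oracle)."""
    spec = CrystalSpec(seed=5, jitter_sigma_xy=0.0, jitter_sigma_angle=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vol, table = build_crystal_volume(spec, default_config.phantom)
    return spec, vol, table


def _plane(table, phantom, vs):
    mid = midmembrane_positions(table, vs, phantom.center_height)
    pa = find_pairs(table, vs, positions=mid)
    _, normal = fit_crystal_plane_from_pairs(mid, pa.pairs)
    return mid, pa, normal


class TestGroundTruthReadback:
    def test_inclination_exact_without_jitter(self, rigid_crystal,
                                              default_config):
        spec, vol, table = rigid_crystal
        _, _, normal = _plane(table, default_config.phantom, vol.voxel_size)
        angles, mean = measure_inclination(table, vol.voxel_size,
                                           plane_normal=normal)
        assert mean == pytest.approx(16.0, abs=1e-6)
        assert angles.std() < 1e-6

    def test_zero_inclination_generator(self, default_config):
        spec = CrystalSpec(seed=5, inclination_theta=0.0,
                           jitter_sigma_xy=0.0, jitter_sigma_angle=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol, table = build_crystal_volume(spec, default_config.phantom)
        angles, mean = measure_inclination(table, vol.voxel_size,
                                           plane_normal=np.array([0, 0, 1.0]))
        assert mean < 1e-6

    def test_pair_angle_matches_generator(self, rigid_crystal, default_config):
        spec, vol, table = rigid_crystal
        mid, pa, _ = _plane(table, default_config.phantom, vol.voxel_size)
        assert len(pa.pairs) >= 4
        vals, mean = measure_pair_angle(pa.pairs, table)
        assert mean == pytest.approx(24.0, abs=0.2)

    def test_interface_rotation_matches_generator(self, rigid_crystal,
                                                  default_config):
        spec, vol, table = rigid_crystal
        mid, pa, normal = _plane(table, default_config.phantom, vol.voxel_size)
        assert len(pa.interfaces) >= 4
        vals, mean = measure_interface_rotation(pa.interfaces, table,
                                                plane_normal=normal)
        assert mean == pytest.approx(90.0, abs=0.1)

    def test_zero_interface_rotation_generator(self, default_config):
        spec = CrystalSpec(seed=5, interface_rotation=0.0,
                           jitter_sigma_xy=0.0, jitter_sigma_angle=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol, table = build_crystal_volume(spec, default_config.phantom)
        mid, pa, normal = _plane(table, default_config.phantom, vol.voxel_size)
        _, mean = measure_interface_rotation(pa.interfaces, table,
                                             plane_normal=normal)
        assert min(mean, 180.0 - mean) == pytest.approx(0.0, abs=0.1)

    def test_spherical_trig_identity_on_axes(self, rigid_crystal):
        # cos(pair) = cos^2(theta) + sin^2(theta) cos(delta_phi)
        spec, vol, table = rigid_crystal
        theta = np.radians(spec.inclination_theta)
        dphi = np.radians(spec.pair_azimuth_delta)
        expected = np.degrees(np.arccos(
            np.cos(theta) ** 2 + np.sin(theta) ** 2 * np.cos(dphi)))
        mid, pa, _ = _plane(table, PhantomSpec(), vol.voxel_size)
        vals, _ = measure_pair_angle(pa.pairs, table)
        assert np.allclose(vals, expected, atol=1e-6)


class TestPairs:
    def test_cutoff_zero_finds_nothing(self, rigid_crystal):
        _, vol, table = rigid_crystal
        pa = find_pairs(table, vol.voxel_size, same_face_cutoff=0.0,
                        cross_face_cutoff=0.0)
        assert pa.pairs == [] and pa.interfaces == []

    def test_order_invariance_vs_bruteforce(self, crystal_volume,
                                            default_config, rng):
        # jittered crystal: distances are tie-free, so mutual-NN pairing
        # is well defined independent of record order
        vol, table = crystal_volume
        vs = vol.voxel_size
        mid = midmembrane_positions(table, vs, 90.0)
        pa = find_pairs(table, vs, positions=mid)
        # shuffle the table; pairing must be the same set of id pairs
        perm = rng.permutation(len(table))
        df = table.df.iloc[perm].reset_index(drop=True)
        shuffled = ParticleTable(df)
        mid_s = midmembrane_positions(shuffled, vs, 90.0)
        pa_s = find_pairs(shuffled, vs, positions=mid_s)
        ids = table.df["id"].to_numpy()
        ids_s = shuffled.df["id"].to_numpy()
        set_a = {frozenset((ids[i], ids[j])) for i, j in pa.pairs}
        set_b = {frozenset((ids_s[i], ids_s[j])) for i, j in pa_s.pairs}
        assert set_a == set_b
        # brute-force mutual-nearest-neighbour oracle
        oracle = set()
        for face in ("up", "down"):
            idx = np.where(table.faces() == face)[0]
            d = np.linalg.norm(mid[idx, None] - mid[None, idx], axis=2)
            np.fill_diagonal(d, np.inf)
            for a in range(len(idx)):
                b = int(np.argmin(d[a]))
                if d[a, b] <= 140.0 and int(np.argmin(d[b])) == a:
                    oracle.add(frozenset((ids[idx[a]], ids[idx[b]])))
        assert set_a == oracle

    def test_global_rotation_equivariance(self, rigid_crystal):
        """All angle readouts are invariant to one rigid rotation of the
        whole table and plane."""
        _, vol, table = rigid_crystal
        vs = vol.voxel_size
        g = RigidTransform(17.0, 9.0, -31.0).matrix
        df = table.df.copy()
        pos = table.positions_xyz() * vs
        newpos = pos @ g.T
        df["x"], df["y"], df["z"] = (newpos[:, 0] / vs, newpos[:, 1] / vs,
                                     newpos[:, 2] / vs)
        for k, t in enumerate(table.transforms()):
            r = RigidTransform.from_matrix(g @ t.matrix)
            df.loc[df.index[k], ["rot", "tilt", "psi"]] = (r.rot, r.tilt, r.psi)
        rotated = ParticleTable(df)
        mid0 = midmembrane_positions(table, vs, 90.0)
        mid1 = midmembrane_positions(rotated, vs, 90.0)
        pa0 = find_pairs(table, vs, positions=mid0)
        pa1 = find_pairs(rotated, vs, positions=mid1)
        n0 = np.array([0.0, 0.0, 1.0])
        n1 = g @ n0
        _, i0 = measure_inclination(table, vs, plane_normal=n0)
        _, i1 = measure_inclination(rotated, vs, plane_normal=n1)
        assert i1 == pytest.approx(i0, abs=1e-6)
        _, p0 = measure_pair_angle(pa0.pairs, table)
        _, p1 = measure_pair_angle(pa1.pairs, rotated)
        assert p1 == pytest.approx(p0, abs=1e-6)
        _, r0 = measure_interface_rotation(pa0.interfaces, table,
                                           plane_normal=n0)
        _, r1 = measure_interface_rotation(pa1.interfaces, rotated,
                                           plane_normal=n1,
                                           flip_axis=g @ np.array([1.0, 0, 0]))
        assert r1 == pytest.approx(r0, abs=1e-6)


class TestPlaneFit:
    def test_simple_plane(self, rng):
        pts = rng.normal(size=(30, 3))
        pts[:, 2] = 0.2 * pts[:, 0] - 0.1 * pts[:, 1] + 3.0
        _, n = fit_crystal_plane(pts)
        expected = np.array([-0.2, 0.1, 1.0])
        expected /= np.linalg.norm(expected)
        assert abs(n @ expected) > 0.9999

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(5.0)] * 3, axis=1)
        with pytest.raises(ValueError, match="collinear"):
            fit_crystal_plane(pts)


class TestReposition:
    def test_single_identity_paste(self, phantom_volume):
        table = ParticleTable.from_records([{
            "id": 0, "x": 48.0, "y": 48.0, "z": 48.0,
            "rot": 0.0, "tilt": 0.0, "psi": 0.0,
            "face": "up", "halfset": "A", "score": 1.0,
        }])
        out = reposition_average((96, 96, 96), table, phantom_volume)
        box = phantom_volume.shape[0]
        half = box // 2
        region = out.grid[48 - half:48 + half + box % 2,
                          48 - half:48 + half + box % 2,
                          48 - half:48 + half + box % 2]
        cc = np.corrcoef(region.ravel(), phantom_volume.grid.ravel())[0, 1]
        assert cc > 0.9999

    def test_overlap_is_additive(self, phantom_volume):
        recs = []
        for i in range(2):
            recs.append({"id": i, "x": 48.0, "y": 48.0, "z": 48.0,
                         "rot": 0.0, "tilt": 0.0, "psi": 0.0,
                         "face": "up", "halfset": "A", "score": 1.0})
        table = ParticleTable.from_records(recs)
        out = reposition_average((96, 96, 96), table, phantom_volume)
        single = reposition_average(
            (96, 96, 96), ParticleTable(table.df.iloc[:1]), phantom_volume)
        assert np.allclose(out.grid, 2.0 * single.grid, atol=1e-4)

    def test_ground_truth_reinsertion_correlates(self, rigid_crystal,
                                                 default_config,
                                                 phantom_volume):
        _, vol, table = rigid_crystal
        out = reposition_average(vol.shape, table, phantom_volume)
        # compare the protein region covered by table particles (edge
        # particles are excluded from the table by the margin policy, so
        # restrict to the interior of the field of view)
        zc = vol.axis_coords(0)
        vs = vol.voxel_size
        xy = np.arange(vol.shape[1]) * vs
        interior = ((xy > 160.0) & (xy < 480.0))
        protein = ((np.abs(zc)[:, None, None] > 30) & (vol.grid > 0.3)
                   & interior[None, :, None] & interior[None, None, :])
        cc = np.corrcoef(out.grid[protein], vol.grid[protein])[0, 1]
        assert cc > 0.9


class TestKink:
    def test_ridge_trace_on_generator_volume(self, crystal_volume,
                                             default_config):
        vol, _ = crystal_volume
        spec = default_config.crystal
        kinks, mean = trace_membrane_kink(vol, spec.row_spacing(),
                                          direction=spec.row_normal())
        assert mean == pytest.approx(43.0, abs=1.5)

    def test_flat_membrane_traces_flat(self, default_config):
        spec = CrystalSpec(seed=5, kink_kappa=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol, _ = build_crystal_volume(spec, default_config.phantom)
        _, mean = trace_membrane_kink(vol, spec.row_spacing(),
                                      direction=spec.row_normal())
        assert mean < 1.5

    def test_row_anchored_kink_from_table(self, crystal_volume,
                                          default_config):
        vol, table = crystal_volume
        spec = default_config.crystal
        kinks, mean = kink_from_particle_rows(
            table, vol.voxel_size, default_config.phantom.center_height,
            spec.row_spacing(), spec.row_normal())
        assert mean == pytest.approx(43.0, abs=2.5)

    def test_predict_dimer_angle(self):
        assert predict_dimer_angle(43.0) == 86.0
        assert predict_dimer_angle(0.0) == 0.0
        assert predict_dimer_angle(45.0) == 90.0
        with pytest.raises(ValueError):
            predict_dimer_angle(95.0)


class TestDensityAxes:
    def test_axes_recovered_on_clean_crystal(self, crystal_volume):
        vol, table = crystal_volume
        axes, ok, heads = measure_axes_from_density(vol, table)
        assert ok.mean() > 0.8
        truth = np.array([t.matrix @ [0, 0, 1.0] for t in table.transforms()])
        errs = [np.degrees(np.arccos(np.clip(abs(truth[i] @ axes[i]), -1, 1)))
                for i in range(len(table)) if ok[i]]
        assert np.mean(errs) < 8.0

    def test_axes_to_table_roundtrip(self, crystal_volume):
        vol, table = crystal_volume
        axes, ok, _ = measure_axes_from_density(vol, table)
        geo = axes_to_table(table, axes, ok)
        back = np.array([t.matrix @ [0, 0, 1.0] for t in geo.transforms()])
        kept = np.where(ok)[0]
        for k, i in enumerate(kept):
            assert np.allclose(back[k], axes[i], atol=1e-9)


def test_head_height_on_generator_volume(crystal_volume):
    vol, _ = crystal_volume
    height, per_blob = measure_head_height(vol)
    # geometric truth: 150 cos(16 deg) = 144.2 A above the midplane
    assert height == pytest.approx(14.42, abs=0.8)
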