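"""Subvolume extraction, alignment scoring, gold-standard machinery."""

import numpy as np
import pytest

from crystomo.average import (
    AlignmentConstraints,
    RefinementSchedule,
    Stage,
    align_subvolume,
    bin_volume,
    extract_subvolumes,
    fourier_lowpass,
    make_initial_reference,
    merge_halfmaps,
    wedge_compensated_average,
)
from crystomo.particles import ParticleTable
from crystomo.synthetic import PhantomSpec, build_phantom
from crystomo.transforms import RigidTransform, rotation_angle_deg
from crystomo.volume import DensityVolume, flip_x180, rotate_grid


def _records(positions, faces=None):
    out = []
    for i, p in enumerate(positions):
        out.append({
            "id": i, "x": p[2], "y": p[1], "z": p[0],
            "rot": 0.0, "tilt": 0.0, "psi": 0.0,
            "face": (faces[i] if faces else "up"),
            "halfset": "A" if i % 2 == 0 else "B", "score": 0.0,
        })
    return out


class TestExtraction:
    def test_centered_particle_peak_at_box_center(self):
        grid = np.zeros((64, 64, 64), np.float32)
        grid[40, 30, 20] = 5.0
        tomo = DensityVolume(grid, 1.0)
        table = ParticleTable.from_records(_records([(40, 30, 20)]))
        stack, flips, kept = extract_subvolumes(tomo, table, box=32)
        assert stack.shape == (1, 32, 32, 32)
        assert np.unravel_index(np.argmax(stack[0]), stack[0].shape) == (16, 16, 16)

    def test_order_preserved_for_many_records(self, rng):
        grid = rng.normal(size=(64, 64, 64)).astype(np.float32)
        tomo = DensityVolume(grid, 1.0)
        pos = [(int(z), int(y), int(x)) for z, y, x in
               rng.integers(20, 44, size=(40, 3))]
        table = ParticleTable.from_records(_records(pos))
        stack, flips, kept = extract_subvolumes(tomo, table, box=16)
        assert len(stack) == 40 and kept == list(range(40))
        for k in (0, 17, 39):
            z, y, x = pos[k]
            assert np.array_equal(
                stack[k], grid[z - 8:z + 8, y - 8:y + 8, x - 8:x + 8])

    def test_extraction_reinsertion_identity(self, rng):
        grid = rng.normal(size=(48, 48, 48)).astype(np.float32)
        tomo = DensityVolume(grid, 1.0)
        table = ParticleTable.from_records(_records([(24, 24, 24)]))
        stack, _, _ = extract_subvolumes(tomo, table, box=24)
        back = np.zeros_like(grid)
        back[12:36, 12:36, 12:36] = stack[0]
        assert np.array_equal(back[12:36, 12:36, 12:36],
                              grid[12:36, 12:36, 12:36])

    def test_skip_policy_warns_on_edge_particles(self):
        tomo = DensityVolume(np.zeros((32, 32, 32), np.float32), 1.0)
        table = ParticleTable.from_records(_records([(2, 16, 16), (16, 16, 16)]))
        with pytest.warns(UserWarning, match="skipped"):
            stack, _, kept = extract_subvolumes(tomo, table, box=16,
                                                pad_policy="skip")
        assert kept == [1]

    def test_pad_policy_zero_fills(self):
        grid = np.ones((32, 32, 32), np.float32)
        tomo = DensityVolume(grid, 1.0)
        table = ParticleTable.from_records(_records([(2, 16, 16)]))
        stack, _, _ = extract_subvolumes(tomo, table, box=16, pad_policy="pad")
        assert stack[0, 0].sum() == 0.0        # padded region
        assert stack[0, -1].sum() == 16 * 16   # inside region


class TestInitialReference:
    def test_identical_boxes_average_to_member(self, rng):
        box = rng.normal(size=(16, 16, 16)).astype(np.float32)
        stack = np.stack([box] * 5)
        ref = make_initial_reference(stack, np.array(["up"] * 5))
        assert np.allclose(ref, box, atol=1e-6)

    def test_down_faces_contribute_flipped(self):
        box = np.zeros((16, 16, 16), np.float32)
        box[4, 8, 8] = 1.0
        stack = np.stack([box, flip_x180(box)])
        ref = make_initial_reference(stack, np.array(["up", "down"]))
        assert ref[4, 8, 8] == 1.0  # flipped-down lands on the up feature

    def test_noise_reduction_follows_sqrt_n(self, rng):
        n = 32
        stack = rng.normal(0, 2.0, size=(n, 12, 12, 12)).astype(np.float32)
        ref = make_initial_reference(stack, np.array(["up"] * n))
        assert ref.std() == pytest.approx(2.0 / np.sqrt(n), rel=0.15)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            make_initial_reference(np.zeros((0, 8, 8, 8), np.float32),
                                   np.array([]))


class TestAlignSubvolume:
    @pytest.fixture(scope="class")
    def phantom(self):
        return build_phantom(PhantomSpec(), 6.66, box=48).grid

    def test_identity_scores_one(self, phantom):
        t, s = align_subvolume(
            phantom, phantom, AlignmentConstraints(max_shift=4),
            orientations=[RigidTransform()], local_norm=False)
        assert s == pytest.approx(1.0, abs=1e-6)
        assert rotation_angle_deg(t) < 1e-9
        assert np.all(np.abs(t.shift) < 0.01)

    def test_known_transform_recovered_within_grid_step(self, phantom):
        true = RigidTransform(25.0, 10.0, 40.0, shift=(3.0, -2.0, 1.0))
        sub = rotate_grid(phantom, true)
        ref_b = bin_volume(phantom, 2)
        sub_b = bin_volume(sub, 2)
        c = AlignmentConstraints(max_shift=6)
        t, _ = align_subvolume(sub_b, ref_b, c, angular_step=12.0)
        t2, _ = align_subvolume(sub, phantom, c, angular_step=4.0, center=t)
        t3, _ = align_subvolume(sub, phantom, c, angular_step=2.0, center=t2)
        assert rotation_angle_deg(t3, true) <= 4.0
        assert np.all(np.abs(t3.shift - true.shift) <= 1.0)

    def test_out_of_constraint_rotation_clamped(self, phantom):
        # true tilt beyond the bound: returned tilt obeys the constraint
        true = RigidTransform(0.0, 60.0, 0.0)
        sub = rotate_grid(phantom, true)
        c = AlignmentConstraints(max_xy_rot=45.0, max_shift=2)
        t, s_con = align_subvolume(bin_volume(sub, 2), bin_volume(phantom, 2),
                                   c, angular_step=15.0)
        assert abs(t.tilt) <= 45.0 + 1e-9
        # unconstrained search reaches the true optimum with higher score
        t_free, s_free = align_subvolume(
            bin_volume(sub, 2), bin_volume(phantom, 2),
            AlignmentConstraints(max_xy_rot=90.0, max_shift=2),
            angular_step=15.0)
        assert s_free > s_con

    def test_wedge_honesty_matches_plain_ncc(self, phantom, rng):
        """With no wedge mask the score equals plain normalized CC."""
        sub = phantom + rng.normal(0, 0.1, phantom.shape).astype(np.float32)
        t, s = align_subvolume(sub, phantom,
                               AlignmentConstraints(max_shift=1),
                               orientations=[RigidTransform()],
                               local_norm=False)
        a = sub - sub.mean()
        b = phantom - phantom.mean()
        ncc = float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))
        assert s == pytest.approx(ncc, abs=1e-6)

    def test_empty_wedge_intersection_raises(self, phantom):
        with pytest.raises(ValueError, match="wedge"):
            align_subvolume(phantom, phantom, AlignmentConstraints(),
                            wedge=np.zeros_like(phantom),
                            orientations=[RigidTransform()])


class TestAveragingAndMerge:
    def test_wedge_average_of_identical_boxes(self, rng):
        box = rng.normal(size=(16, 16, 16)).astype(np.float32)
        out = wedge_compensated_average(
            np.stack([box] * 4), [RigidTransform()] * 4, None)
        assert np.allclose(out, box, atol=1e-5)

    def test_merge_is_exact_mean(self, rng):
        a = DensityVolume(rng.normal(size=(8, 8, 8)).astype(np.float32), 1.0)
        b = DensityVolume(rng.normal(size=(8, 8, 8)).astype(np.float32), 1.0)
        m = merge_halfmaps(a, b)
        assert np.allclose(m.grid, (a.grid + b.grid) / 2.0, atol=1e-7)

    def test_merge_identical_and_negated(self):
        a = DensityVolume(np.ones((8, 8, 8), np.float32), 1.0)
        assert np.allclose(merge_halfmaps(a, a).grid, a.grid)
        neg = DensityVolume(-a.grid, 1.0)
        assert np.allclose(merge_halfmaps(a, neg).grid, 0.0)

    def test_merge_shape_mismatch(self):
        a = DensityVolume(np.ones((8, 8, 8), np.float32), 1.0)
        b = DensityVolume(np.ones((10, 10, 10), np.float32), 1.0)
        with pytest.raises(ValueError):
            merge_halfmaps(a, b)


class TestSchedule:
    def test_defaults_valid(self):
        s = RefinementSchedule()
        assert [st.binning for st in s.stages] == [2, 2, 1]
        assert [st.resolution_limit for st in s.stages] == [60.0, 40.0, 30.0]

    def test_binning_must_not_increase(self):
        with pytest.raises(ValueError):
            RefinementSchedule([Stage(1, 60.0, 10.0), Stage(2, 30.0, 5.0)])

    def test_resolution_must_not_coarsen(self):
        with pytest.raises(ValueError):
            RefinementSchedule([Stage(2, 30.0, 10.0), Stage(1, 60.0, 5.0)])

    def test_constraints_validated(self):
        with pytest.raises(ValueError):
            AlignmentConstraints(max_xy_rot=100.0)
        with pytest.raises(ValueError):
            AlignmentConstraints(max_shift=-1.0)
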