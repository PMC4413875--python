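"""Gold-standard subtomogram alignment and averaging.

Particles are split randomly into two half-sets that are refined
independently and only compared through the Fourier shell correlation of
their final averages.  Alignment is a constrained exhaustive search: the
out-of-plane tilt of the reference axis is limited (default ±45°) while
the azimuth and the spin about the particle axis are unrestricted, and
translations are found by FFT cross-correlation limited to a per-axis
shift bound (default 12 voxels).  Scoring is a normalized cross
correlation computed over the Fourier voxels inside the missing-wedge
mask, so that absent information cannot contribute to the score.

Particles picked on the opposite membrane face are rotated 180° about the
x axis before alignment; the stored transform composes that flip back in,
so the table always maps the single reference into the tomogram frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .particles import ParticleTable
from .transforms import (
    RigidTransform,
    X_FLIP,
    compose_transforms,
    invert_transform,
    rotation_angle_deg,
)
from .volume import DensityVolume, flip_x180, rotate_grid

__all__ = [
    "AlignmentConstraints",
    "RefinementSchedule",
    "Stage",
    "extract_subvolumes",
    "make_initial_reference",
    "align_subvolume",
    "refine_gold_standard",
    "merge_halfmaps",
    "fourier_lowpass",
]


@dataclass(frozen=True)
class AlignmentConstraints:
    max_xy_rot: float = 45.0      # degrees, out-of-plane tilt bound
    max_shift: float = 12.0       # voxels, per-axis bound
    z_rot_unrestricted: bool = True
    resolution_limit: float | None = None  # Å

    def __post_init__(self):
        if not (0 < self.max_xy_rot <= 90):
            raise ValueError("max_xy_rot must be in (0, 90]")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")


@dataclass(frozen=True)
class Stage:
    binning: int
    resolution_limit: float   # Å
    angular_step: float       # degrees
    iterations: int = 2
    search: str = "local"     # "global" | "psi" | "local"
    shift_limit: float | None = None   # unbinned voxels; None = constraint bound

    def __post_init__(self):
        if self.search not in ("global", "psi", "local"):
            raise ValueError("search must be 'global', 'psi' or 'local'")


@dataclass
class RefinementSchedule:
    """Coarse-to-fine alignment plan.

    The default mirrors the standard progression — binned volumes at a
    60 Å limit first, then 40 Å, then the unbinned volume at 30 Å — with
    search modes that respect what each band can see: the low-resolution
    stage determines the axis orientation (spin about the long axis is
    invisible there), the middle stage keeps the spin search exhaustive,
    and the final stage refines locally.
    """

    stages: list[Stage] = field(default_factory=lambda: [
        Stage(binning=2, resolution_limit=60.0, angular_step=12.0,
              iterations=2, search="global", shift_limit=3.0),
        Stage(binning=2, resolution_limit=40.0, angular_step=10.0,
              iterations=2, search="psi", shift_limit=6.0),
        Stage(binning=1, resolution_limit=30.0, angular_step=3.0,
              iterations=2, search="local"),
    ])

    def __post_init__(self):
        bins = [s.binning for s in self.stages]
        res = [s.resolution_limit for s in self.stages]
        if any(b2 > b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("stage binning must be non-increasing")
        if any(r2 > r1 for r1, r2 in zip(res, res[1:])):
            raise ValueError("stage resolution limits must be non-increasing")
        if any(b not in (1, 2, 4) for b in bins):
            raise ValueError("binning must be one of 1, 2, 4")


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_subvolumes(
    tomogram: DensityVolume,
    table: ParticleTable,
    box: int,
    pad_policy: str = "pad",
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Extract one cubic box per table record, centered on its position.

    Returns (stack, flip_flags, kept_indices).  ``flip_flags`` marks
    down-face records, which must be rotated 180° about x before
    alignment.  With ``pad_policy='pad'`` boxes reaching outside the
    tomogram are zero-padded; with ``'skip'`` they are dropped with a
    warning.
    """
    if pad_policy not in ("pad", "skip"):
        raise ValueError("pad_policy must be 'pad' or 'skip'")
    grid = tomogram.grid
    nz, ny, nx = grid.shape
    half = box // 2
    centers = np.rint(table.positions_zyx()).astype(int)
    faces = table.faces()
    stack, flips, kept = [], [], []
    skipped = 0
    for i, (cz, cy, cx) in enumerate(centers):
        lo = np.array([cz, cy, cx]) - half
        hi = lo + box
        if (lo < 0).any() or (hi > [nz, ny, nx]).any():
            if pad_policy == "skip":
                skipped += 1
                continue
            sub = np.zeros((box, box, box), dtype=np.float32)
            src_lo = np.maximum(lo, 0)
            src_hi = np.minimum(hi, [nz, ny, nx])
            dst_lo = src_lo - lo
            dst_hi = dst_lo + (src_hi - src_lo)
            sub[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
                grid[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
        else:
            sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
        stack.append(sub)
        flips.append(faces[i] == "down")
        kept.append(i)
    if skipped:
        warnings.warn(f"skipped {skipped} particles with boxes outside the tomogram")
    if not stack:
        return np.zeros((0, box, box, box), np.float32), np.zeros(0, bool), []
    return np.stack(stack), np.array(flips), kept


def make_initial_reference(stack: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Plain average of unaligned boxes; down-face boxes are x-flipped first."""
    faces = np.asarray(faces)
    if len(stack) == 0 or not np.any((faces == "up") | (faces == "down")):
        raise ValueError("need at least one subvolume to build a reference")
    if not np.any(faces == "up"):
        raise ValueError("need at least one up-face subvolume")
    acc = np.zeros(stack.shape[1:], dtype=np.float64)
    for sub, face in zip(stack, faces):
        acc += flip_x180(sub) if face == "down" else sub
    return (acc / len(stack)).astype(np.float32)


# ---------------------------------------------------------------------------
# Fourier helpers
# ---------------------------------------------------------------------------

def fourier_lowpass(arr: np.ndarray, voxel_size: float, cutoff_A: float,
                    soft_px: float = 2.0) -> np.ndarray:
    """Soft-edged spherical lowpass at ``cutoff_A`` (Å)."""
    n = arr.shape[0]
    k = _freq_radius(arr.shape)          # cycles/voxel
    kc = voxel_size / cutoff_A
    edge = soft_px / n
    mask = np.clip((kc + edge / 2 - k) / edge, 0.0, 1.0)
    return np.fft.ifftn(np.fft.fftn(arr) * mask).real.astype(np.float32)


def _freq_radius(shape) -> np.ndarray:
    axes = [np.fft.fftfreq(n) for n in shape]
    kz = axes[0][:, None, None]
    ky = axes[1][None, :, None]
    kx = axes[2][None, None, :]
    return np.sqrt(kz**2 + ky**2 + kx**2)


def bin_volume(arr: np.ndarray, factor: int) -> np.ndarray:
    """Integer binning by block averaging (dims must divide the factor)."""
    if factor == 1:
        return arr
    n = (np.array(arr.shape) // factor) * factor
    a = arr[: n[0], : n[1], : n[2]]
    return a.reshape(
        n[0] // factor, factor, n[1] // factor, factor, n[2] // factor, factor
    ).mean(axis=(1, 3, 5)).astype(np.float32)


def _shift_allowed_mask(shape, max_shift: float,
                        center=None, window: float | None = None) -> np.ndarray:
    """Mask of cross-correlation map indices with per-axis |shift| <= bound.

    With ``center``/``window``, additionally require each axis shift to
    lie within ``window`` of the given previous shift — a local search
    that keeps the translational optimum from hopping onto a packing
    neighbour once an anchor is known.
    """
    idx = []
    for ax, n in enumerate(shape):
        s = np.arange(n).astype(float)
        s[s > n / 2] -= n  # wrapped signed shift
        ok = np.abs(s) <= max_shift
        if center is not None and window is not None:
            ok &= np.abs(s - center[ax]) <= window
        idx.append(ok)
    return (idx[0][:, None, None] & idx[1][None, :, None] & idx[2][None, None, :])


def _wrap_shift(indices, shape) -> np.ndarray:
    out = np.array(indices, dtype=float)
    for i, n in enumerate(shape):
        if out[i] > n / 2:
            out[i] -= n
    return out


# ---------------------------------------------------------------------------
# Orientation grids
# ---------------------------------------------------------------------------

def global_orientation_grid(step: float, max_tilt: float) -> list[RigidTransform]:
    """ZYZ grid with tilt in [0, max_tilt], azimuth and spin free."""
    out = [RigidTransform(0.0, 0.0, p) for p in np.arange(0.0, 360.0, step)]
    for tilt in np.arange(step, max_tilt + 1e-9, step):
        for rot in np.arange(0.0, 360.0, step):
            for psi in np.arange(0.0, 360.0, step):
                out.append(RigidTransform(rot, tilt, psi))
    return out


def local_orientation_grid(center: RigidTransform, step: float,
                           span: int = 1) -> list[RigidTransform]:
    deltas = step * np.arange(-span, span + 1)
    out = []
    for dr in deltas:
        for dt in deltas:
            for dp in deltas:
                out.append(RigidTransform(center.rot + dr, center.tilt + dt,
                                          center.psi + dp))
    return out


def psi_global_grid(center: RigidTransform, step: float,
                    rot_span: int = 2, tilt_span: int = 1) -> list[RigidTransform]:
    """Spin-exhaustive grid: psi over the full circle, axis near center.

    Low-resolution stages determine the particle axis but say nothing
    about the spin around it; this grid lets the spin be re-decided
    wholesale once the resolution can see the peripheral features.
    """
    out = []
    for dr in step * np.arange(-rot_span, rot_span + 1):
        for dt in step * np.arange(-tilt_span, tilt_span + 1):
            for psi in np.arange(0.0, 360.0, step):
                out.append(RigidTransform(center.rot + dr, center.tilt + dt, psi))
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def rotate_wedge(wedge: np.ndarray, rotation: RigidTransform) -> np.ndarray:
    """Rotate a Fourier wedge mask (unshifted layout) by a rotation."""
    shifted = np.fft.fftshift(wedge.astype(np.float32))
    rot = rotate_grid(shifted, RigidTransform(rotation.rot, rotation.tilt,
                                              rotation.psi))
    return np.fft.ifftshift(rot)


def align_subvolume(
    subvol: np.ndarray,
    reference: np.ndarray,
    constraints: AlignmentConstraints,
    wedge: np.ndarray | None = None,
    ref_wedge: np.ndarray | None = None,
    orientations: list[RigidTransform] | None = None,
    angular_step: float = 10.0,
    center: RigidTransform | None = None,
    shift_window: float | None = None,
    local_norm: bool = True,
) -> tuple[RigidTransform, float]:
    """Best rigid transform mapping ``reference`` onto ``subvol``.

    Searches the orientation grid (global within constraints, or local
    around ``center``), with an FFT translational search per orientation
    restricted to the per-axis shift bound.  The score is the normalized
    cross correlation over Fourier voxels in the intersection of the
    particle wedge and the rotated reference wedge, so information the
    reference lacks in some direction can neither help nor penalize a
    pose.  Ties are broken toward the smallest rotation, then smallest
    shift (via the search order).
    """
    if subvol.shape != reference.shape:
        raise ValueError("subvolume and reference must have the same box")
    if wedge is not None and not np.any(wedge):
        raise ValueError("empty wedge intersection: no Fourier voxels to score")
    if orientations is None:
        if center is None:
            orientations = global_orientation_grid(angular_step, constraints.max_xy_rot)
        else:
            orientations = local_orientation_grid(center, angular_step)
    # smallest-rotation-first ordering implements the tie-break rule
    orientations = sorted(orientations, key=rotation_angle_deg)

    sub = subvol.astype(np.float64) - subvol.mean()
    fs = np.fft.fftn(sub)
    s_center = None if center is None else center.shift
    allowed = _shift_allowed_mask(subvol.shape, constraints.max_shift,
                                  center=s_center, window=shift_window)

    best = (-np.inf, None, None)  # score, transform index, shift
    found = False
    for oi, orient in enumerate(orientations):
        rot = RigidTransform(orient.rot, orient.tilt, orient.psi)
        res = _score_orientation(fs, reference, rot, wedge, ref_wedge, allowed,
                                 local_norm=local_norm)
        if res is None:
            continue
        found = True
        score, shift = res
        if score > best[0] + 1e-12:
            best = (float(score), oi, shift)
    if not found:
        raise ValueError("empty wedge intersection: no Fourier voxels to score")
    score, oi, shift = best
    orient = orientations[oi]
    transform = RigidTransform(orient.rot, orient.tilt, orient.psi, shift)
    return transform, score


def _score_orientation(fs, reference, rot, wedge, ref_wedge, allowed,
                       local_norm=True):
    """Translational search for one orientation.

    Scores are locally normalized cross correlations: the denominator
    uses the data energy under the rotated reference's support at each
    candidate shift, so a pose cannot win merely by parking the
    reference on the brightest patch of the box.  Both volumes are
    restricted to the intersection of their wedges.
    """
    n_tot = fs.size
    rot_ref = rotate_grid(reference, rot)
    fr = np.fft.fftn(rot_ref.astype(np.float64) - rot_ref.mean())
    mask = wedge
    if ref_wedge is not None:
        rw = rotate_wedge(ref_wedge, rot) > 0.5
        mask = rw if mask is None else (mask > 0.5) & rw
    if mask is not None:
        if not np.any(mask):
            return None
        fsm = fs * mask
        fr = fr * mask
    else:
        fsm = fs
    norm_r = np.sqrt((np.abs(fr) ** 2).sum() / n_tot)
    if norm_r == 0:
        return None
    cov = np.fft.ifftn(fsm * np.conj(fr)).real  # = sum_x d(x) r(x - s)
    if local_norm:
        d_w = np.fft.ifftn(fsm).real
        support = (np.abs(rot_ref) > 0.1 * np.abs(rot_ref).max()).astype(float)
        n_sup = support.sum()
        if n_sup < 8:
            return None
        f_sup = np.fft.fftn(support)
        e_loc = np.fft.ifftn(np.fft.fftn(d_w**2) * np.conj(f_sup)).real
        e_loc = np.clip(e_loc, 1e-12 * e_loc.max() + 1e-30, None)
        cc = cov / (np.sqrt(e_loc) * norm_r)
    else:
        norm_s = np.sqrt((np.abs(fsm) ** 2).sum() / n_tot)
        if norm_s == 0:
            return None
        cc = cov / (norm_s * norm_r)
    cc_masked = np.where(allowed, cc, -np.inf)
    peak = np.unravel_index(np.argmax(cc_masked), cc.shape)
    return float(cc_masked[peak]), _subpixel_peak(cc, peak)


def _subpixel_peak(cc: np.ndarray, peak) -> np.ndarray:
    """Per-axis parabolic interpolation of the correlation peak (wrapped)."""
    shape = cc.shape
    out = []
    for ax, p in enumerate(peak):
        n = shape[ax]
        idx_m = tuple(peak[:ax]) + ((p - 1) % n,) + tuple(peak[ax + 1:])
        idx_p = tuple(peak[:ax]) + ((p + 1) % n,) + tuple(peak[ax + 1:])
        ym, y0, yp = cc[idx_m], cc[tuple(peak)], cc[idx_p]
        denom = ym - 2 * y0 + yp
        delta = 0.0 if abs(denom) < 1e-12 else 0.5 * (ym - yp) / denom
        out.append(p + np.clip(delta, -0.5, 0.5))
    return _wrap_shift(out, shape)


def _align_stack_global(
    stack_lp: np.ndarray,
    ref_lp: np.ndarray,
    constraints: AlignmentConstraints,
    wedge: np.ndarray | None,
    step: float,
    ref_wedge: np.ndarray | None = None,
) -> tuple[list[RigidTransform], np.ndarray]:
    """Exhaustive orientation search for a whole stack at once.

    Each rotated reference (and its rotated wedge) is computed once and
    scored against every particle, which makes the global pass affordable.
    """
    orientations = sorted(
        global_orientation_grid(step, constraints.max_xy_rot), key=rotation_angle_deg
    )
    n_tot = stack_lp[0].size
    # the data-side mask is the particle wedge only, so the wedge-filtered
    # data and its squared spectrum can be precomputed once per particle
    fs_list, fd2_list = [], []
    for sub in stack_lp:
        f = np.fft.fftn(sub.astype(np.float64) - sub.mean())
        if wedge is not None:
            f = f * wedge
        fs_list.append(f)
        d_w = np.fft.ifftn(f).real
        fd2_list.append(np.fft.fftn(d_w**2))
    allowed = _shift_allowed_mask(stack_lp.shape[1:], constraints.max_shift)
    best_scores = np.full(len(stack_lp), -np.inf)
    best_t: list[RigidTransform | None] = [None] * len(stack_lp)
    for orient in orientations:
        rot = RigidTransform(orient.rot, orient.tilt, orient.psi)
        rot_ref = rotate_grid(ref_lp, rot)
        fr = np.fft.fftn(rot_ref.astype(np.float64) - rot_ref.mean())
        if wedge is not None:
            fr = fr * wedge
        norm_r = np.sqrt((np.abs(fr) ** 2).sum() / n_tot)
        if norm_r == 0:
            continue
        support = (np.abs(rot_ref) > 0.1 * np.abs(rot_ref).max()).astype(float)
        if support.sum() < 8:
            continue
        f_sup = np.conj(np.fft.fftn(support))
        for pi, (fs, fd2) in enumerate(zip(fs_list, fd2_list)):
            cov = np.fft.ifftn(fs * np.conj(fr)).real
            e_loc = np.fft.ifftn(fd2 * f_sup).real
            e_loc = np.clip(e_loc, 1e-12 * abs(e_loc).max() + 1e-30, None)
            cc = cov / (np.sqrt(e_loc) * norm_r)
            cc_masked = np.where(allowed, cc, -np.inf)
            peak = np.unravel_index(np.argmax(cc_masked), cc.shape)
            score = cc_masked[peak]
            if score > best_scores[pi] + 1e-12:
                shift = _subpixel_peak(cc, peak)
                best_scores[pi] = float(score)
                best_t[pi] = RigidTransform(orient.rot, orient.tilt, orient.psi,
                                            shift)
    return best_t, best_scores


def _align_stack_relative(
    stack_lp: np.ndarray,
    centers: list[RigidTransform],
    ref_lp: np.ndarray,
    constraints: AlignmentConstraints,
    wedge: np.ndarray | None,
    ref_wedge: np.ndarray | None,
    spins: np.ndarray,
    wobble_step: float,
    voxel_size: float,
    mask_radius: float,
    shift_window: float,
) -> tuple[list[RigidTransform], np.ndarray]:
    """Spin/wobble search performed in the reference frame.

    Each particle is rotated once by the inverse of its current pose (its
    wedge with it); the candidate reference rotations — full-circle spins
    composed with a small wobble grid — are shared by the whole stack, so
    the number of resamplings grows with (particles + orientations), not
    their product.  The data is masked to the alignment region, which in
    the reference frame is the static axis cylinder.
    """
    box = stack_lp.shape[1:]
    wobbles = [RigidTransform(dr, dt, 0.0)
               for dr in wobble_step * np.arange(-1, 2)
               for dt in wobble_step * np.arange(-1, 2)]
    # shared rotated references: R = Rz(spin) then wobble
    shared = []
    for w in wobbles:
        for psi in spins:
            rot = compose_transforms(w, RigidTransform(psi, 0.0, 0.0))
            rr = rotate_grid(ref_lp, rot)
            fr = np.fft.fftn(rr.astype(np.float64) - rr.mean())
            rw = None
            if ref_wedge is not None:
                rw = rotate_wedge(ref_wedge, rot) > 0.5
            shared.append((rot, fr, rw))

    out_t: list[RigidTransform] = []
    out_s = np.zeros(len(stack_lp))
    ones = np.ones(box, dtype=np.float32)
    static_mask = _alignment_mask(ones, voxel_size, mask_radius)
    n_tot = int(np.prod(box))
    for pi, (sub, c) in enumerate(zip(stack_lp, centers)):
        c_rot = RigidTransform(c.rot, c.tilt, c.psi)
        inv_rot = invert_transform(c_rot)
        d = rotate_grid(sub, inv_rot) * static_mask
        fs = np.fft.fftn(d.astype(np.float64) - d.mean())
        wd = None
        if wedge is not None:
            wd = rotate_wedge(wedge, inv_rot) > 0.5
        s_prev = inv_rot.matrix_zyx @ c.shift
        allowed = _shift_allowed_mask(box, constraints.max_shift,
                                      center=s_prev, window=shift_window)
        best = (-np.inf, None, None)
        for rot, fr, rw in shared:
            mask = wd
            if rw is not None:
                mask = rw if mask is None else (mask & rw)
            if mask is not None:
                fsm = fs * mask
                frm = fr * mask
            else:
                fsm, frm = fs, fr
            norm_s = np.sqrt((np.abs(fsm) ** 2).sum() / n_tot)
            norm_r = np.sqrt((np.abs(frm) ** 2).sum() / n_tot)
            if norm_s == 0 or norm_r == 0:
                continue
            cc = np.fft.ifftn(fsm * np.conj(frm)).real / (norm_s * norm_r)
            cc_masked = np.where(allowed, cc, -np.inf)
            peak = np.unravel_index(np.argmax(cc_masked), cc.shape)
            score = cc_masked[peak]
            if score > best[0] + 1e-12:
                best = (float(score), rot, _subpixel_peak(cc, peak))
        score, rot, shift = best
        if rot is None:
            out_t.append(c)
            out_s[pi] = -np.inf
            continue
        # d ~ transform(ref, (rot, shift)); map back through the center pose
        t_rel = RigidTransform(rot.rot, rot.tilt, rot.psi, shift)
        out_t.append(compose_transforms(c_rot, t_rel))
        out_s[pi] = score
    return out_t, out_s


# ---------------------------------------------------------------------------
# Gold-standard refinement
# ---------------------------------------------------------------------------

def wedge_compensated_average(
    stack: np.ndarray,
    transforms: list[RigidTransform],
    wedge: np.ndarray | None,
    return_coverage: bool = False,
):
    """Average subvolumes in the reference frame, dividing the Fourier sum
    by the per-voxel count of contributing (rotated) wedges, floored at 1.

    ``return_coverage=True`` also returns the mask of Fourier voxels where
    at least half a wedge contributed — the average's own information
    support, needed for honest wedge-intersection scoring.
    """
    box = stack.shape[1:]
    f_sum = np.zeros(box, dtype=np.complex128)
    counts = np.zeros(box, dtype=np.float64)
    wedge_shifted = None if wedge is None else np.fft.fftshift(wedge)
    for sub, t in zip(stack, transforms):
        inv = invert_transform(t)
        back = rotate_grid(sub, inv)
        f_sum += np.fft.fftn(back.astype(np.float64))
        if wedge is None:
            counts += 1.0
        else:
            w_rot = rotate_grid(
                wedge_shifted, RigidTransform(inv.rot, inv.tilt, inv.psi)
            )
            counts += np.fft.ifftshift(np.clip(w_rot, 0.0, 1.0))
    denom = np.maximum(counts, 1.0)
    avg = np.fft.ifftn(f_sum / denom).real.astype(np.float32)
    if return_coverage:
        return avg, (counts >= 0.5).astype(np.float32)
    return avg


def refine_gold_standard(
    stack: np.ndarray,
    table: ParticleTable,
    schedule: RefinementSchedule,
    constraints: AlignmentConstraints,
    voxel_size: float,
    wedge_theta: float | None = 60.0,
    mask_radius: float | None = None,
    seed: int = 0,
) -> tuple[DensityVolume, DensityVolume, ParticleTable, list[dict]]:
    """Iterative alignment/averaging of two independent half-sets.

    ``stack`` holds raw extracted boxes in table order; down-face boxes
    are x-flipped internally.  Returns the two half maps, the refined
    table (positions updated by the recovered shifts, rotations mapping
    reference to tomogram frame) and a per-iteration log of mean scores.

    The reference is soft-masked to ``mask_radius`` Å about its center
    before each alignment pass, so that neighbouring lattice particles
    and the continuous bilayer (common to every box) cannot dominate the
    orientation score; every iteration of the first (binned) stage is a
    full global orientation search, which lets particles escape the
    azimuthally smeared solution that the unaligned starting reference
    favours.
    """
    from .synthetic import wedge_mask  # local import to avoid a cycle

    if len(stack) != len(table):
        raise ValueError("stack and table lengths differ")
    df = table.df.copy()
    if df["halfset"].isna().any() or (df["halfset"] == "").any():
        table = table.assign_halfsets(seed)
        df = table.df.copy()
    faces = table.faces()
    work = np.stack([
        flip_x180(s) if f == "down" else s for s, f in zip(stack, faces)
    ]).astype(np.float32)
    box = work.shape[1]
    wedge_full = None if wedge_theta is None else wedge_mask((box,) * 3, wedge_theta)
    if mask_radius is None:
        mask_radius = 0.2 * box * voxel_size

    halfsets = df["halfset"].to_numpy()
    positions = table.positions_zyx()
    history: list[dict] = []
    half_maps: dict[str, np.ndarray] = {}
    aligned: dict[str, list[RigidTransform]] = {}
    scores: dict[str, np.ndarray] = {}

    members = {lab: np.where(halfsets == lab)[0] for lab in ("A", "B")}
    for lab, mem in members.items():
        if len(mem) == 0:
            raise ValueError(f"half-set {lab} is empty")
    # a single seeded subvolume bootstraps the starting reference: a plain
    # average of unaligned boxes converges to a chimera when the lattice
    # packs the motif at two azimuths, and the bootstrap breaks both the
    # azimuth and, at the spin-search stage, the spin degeneracy.  The
    # SAME bootstrap particle seeds both half-sets — a common starting
    # model (standard gold-standard practice) that keeps the two half
    # frames mutually aligned so geometry can be read across halves; the
    # bootstrap's arbitrary pose is a global gauge that cancels in every
    # geometric readout.
    rng_boot = np.random.default_rng(seed + 17)
    boot_global = int(rng_boot.integers(len(work)))
    boot = {lab: boot_global for lab in members}

    cur_all: list[RigidTransform | None] = [None] * len(work)
    scores_all = np.zeros(len(work))
    clean: np.ndarray | None = None

    for si, stage in enumerate(schedule.stages):
        b = stage.binning
        vs = voxel_size * b
        wedge_b = None if wedge_theta is None else wedge_mask(
            tuple(s // b for s in work.shape[1:]), wedge_theta
        )
        # once axes and positions are known, subtract the (spin-smeared)
        # average pasted at every neighbouring particle: the packing
        # neighbours otherwise act as lattice-locked decoys in the spin
        # search.  Uses input positions and current axis estimates only.
        if stage.search == "psi" and clean is None and \
                not any(t is None for t in cur_all):
            model = wedge_compensated_average(work, cur_all, wedge_full)
            clean = _subtract_neighbors(
                work, model, positions, cur_all, faces, wedge_full,
                voxel_size=voxel_size,
            )
        align_src = clean if clean is not None else work
        binned_avg = np.stack([bin_volume(s, b) for s in work])
        if align_src is work:
            binned_align = binned_avg
        else:
            binned_align = np.stack([bin_volume(s, b) for s in align_src])
        binned_lp = np.stack([
            fourier_lowpass(s, vs, stage.resolution_limit)
            for s in binned_align
        ])
        limit = constraints.max_shift
        if stage.shift_limit is not None:
            limit = min(limit, stage.shift_limit)
        c_stage = AlignmentConstraints(
            max_xy_rot=constraints.max_xy_rot,
            max_shift=max(limit / b, 1.0),
            resolution_limit=stage.resolution_limit,
        )
        for label in ("A", "B"):
            mem = members[label]
            cur = [cur_all[i] for i in mem]
            prev_mean, drops = -np.inf, 0
            for it in range(stage.iterations):
                first_of_mode = it == 0 and stage.search in ("global", "psi")
                if all(t is None for t in cur) or first_of_mode:
                    ref = binned_align[boot[label]].copy()
                    ref_wedge = wedge_b
                else:
                    # the multi-orientation average has near-complete
                    # Fourier coverage; skip the per-orientation wedge
                    # intersection for it
                    ref = wedge_compensated_average(
                        binned_avg[mem], [_scaled(t, 1.0 / b) for t in cur],
                        wedge_b,
                    )
                    ref_wedge = None
                ref_lp = fourier_lowpass(
                    _alignment_mask(ref, vs, mask_radius),
                    vs, stage.resolution_limit,
                )
                if stage.search == "global":
                    new, new_scores = _align_stack_global(
                        binned_lp[mem], ref_lp, c_stage, wedge_b,
                        stage.angular_step, ref_wedge=ref_wedge,
                    )
                else:
                    if stage.search == "psi":
                        spins = np.arange(0.0, 360.0, stage.angular_step)
                    else:
                        spins = stage.angular_step * np.arange(-1, 2)
                    centers = [_scaled(t, 1.0 / b) for t in cur]
                    new, new_scores = _align_stack_relative(
                        binned_lp[mem], centers, ref_lp, c_stage, wedge_b,
                        ref_wedge, spins, stage.angular_step, vs,
                        mask_radius, shift_window=max(4.0 / b, 2.0),
                    )
                cur = [_scaled(t, b) for t in new]
                mean_score = float(np.mean(new_scores))
                history.append({
                    "half": label, "stage": si, "iteration": it,
                    "binning": b, "resolution_limit": stage.resolution_limit,
                    "search": stage.search, "mean_score": mean_score,
                })
                if mean_score < prev_mean:
                    drops += 1
                    if drops >= 2:
                        warnings.warn(
                            f"half-set {label}: mean score decreased twice; "
                            "stopping refinement early"
                        )
                        break
                else:
                    drops = 0
                prev_mean = mean_score
            for li, i in enumerate(mem):
                cur_all[i] = cur[li]
                scores_all[i] = new_scores[li]

    # face linkage: the spin gauge can settle independently for the two
    # membrane faces (the cross-face relation is only sampled through the
    # reference).  Align the down-subset average onto the up-subset
    # average over spin (and a small axis wobble); apply the correction
    # to every down particle.  The face-class averages are clean in their
    # particle features while their packing context is smeared, so this
    # one-dimensional search is not exposed to the lattice decoys that
    # plague per-particle spin assignment.
    fine = schedule.stages[-1]
    vs1 = voxel_size
    up_idx = np.where(faces == "up")[0]
    down_idx = np.where(faces == "down")[0]
    if len(up_idx) and len(down_idx):
        avg_up = wedge_compensated_average(
            work[up_idx], [cur_all[i] for i in up_idx], wedge_full)
        avg_down = wedge_compensated_average(
            work[down_idx], [cur_all[i] for i in down_idx], wedge_full)
        ref_up = fourier_lowpass(
            _alignment_mask(avg_up, vs1, mask_radius), vs1,
            fine.resolution_limit)
        d_lp = fourier_lowpass(
            _alignment_mask(avg_down, vs1, mask_radius), vs1,
            fine.resolution_limit)
        q, _ = align_subvolume(
            d_lp, ref_up,
            AlignmentConstraints(max_xy_rot=constraints.max_xy_rot,
                                 max_shift=3.0),
            orientations=[
                RigidTransform(dr, dt, psi)
                for psi in np.arange(0.0, 360.0, 3.0)
                for dr in (-3.0, 0.0, 3.0)
                for dt in (-3.0, 0.0, 3.0)
            ],
            local_norm=False,
        )
        for i in down_idx:
            cur_all[i] = compose_transforms(cur_all[i], q)

    for label in ("A", "B"):
        mem = members[label]
        cur = [cur_all[i] for i in mem]
        half_maps[label] = wedge_compensated_average(work[mem], cur, wedge_full)
        aligned[label] = cur
        scores[label] = scores_all[mem]

    # write back: compose the x-flip for down-face particles, update positions
    out = df.copy()
    for label in ("A", "B"):
        members = np.where(halfsets == label)[0]
        for mi, idx in enumerate(members):
            t_align = aligned[label][mi]
            if faces[idx] == "down":
                t_full = compose_transforms(X_FLIP, t_align)
            else:
                t_full = t_align
            sz, sy, sx = t_full.shift
            out.loc[idx, ["rot", "tilt", "psi"]] = (t_full.rot, t_full.tilt,
                                                    t_full.psi)
            out.loc[idx, "x"] = np.rint(df.loc[idx, "x"]) + sx
            out.loc[idx, "y"] = np.rint(df.loc[idx, "y"]) + sy
            out.loc[idx, "z"] = np.rint(df.loc[idx, "z"]) + sz
            out.loc[idx, "score"] = scores[label][mi]
    refined = ParticleTable(out)
    map_a = DensityVolume(half_maps["A"], voxel_size)
    map_b = DensityVolume(half_maps["B"], voxel_size)
    return map_a, map_b, refined, history


def _scaled(t: RigidTransform, factor: float) -> RigidTransform:
    return RigidTransform(t.rot, t.tilt, t.psi, t.shift * factor)


def _subtract_neighbors(
    work: np.ndarray,
    model: np.ndarray,
    positions: np.ndarray,
    poses: list[RigidTransform],
    faces: np.ndarray,
    wedge: np.ndarray | None,
    voxel_size: float = 6.66,
    reach_extra: float = 22.0,
) -> np.ndarray:
    """Remove the modelled density of packing neighbours from each box.

    ``model`` is the current average in the reference frame (spin-smeared
    is fine — the dominant neighbour features are axially symmetric); it
    is pasted at every neighbouring particle's picked position with its
    current pose, wedge-filtered to mimic the acquisition, amplitude-
    matched by least squares and subtracted.  The particle's own density
    is left untouched.
    """
    n, box = len(work), work.shape[1]
    out = np.empty_like(work)
    # keep only the model's own particle envelope: the average also holds
    # smeared context (bilayer, second-shell neighbours) whose copies
    # would land junk right on the particle being cleaned
    model = _alignment_mask(model, voxel_size, radius=72.0, z_min=-125.0)
    # full tomogram-frame poses
    full = []
    for t, f in zip(poses, faces):
        full.append(compose_transforms(X_FLIP, t) if f == "down" else t)
    reach = box / 2.0 + reach_extra  # voxels
    flip_m = X_FLIP.matrix_zyx
    for i in range(n):
        acc = np.zeros((box, box, box), dtype=np.float64)
        found = False
        for j in range(n):
            if j == i:
                continue
            dpos = positions[j] - positions[i]
            if np.max(np.abs(dpos)) > reach:
                continue
            t = full[j]
            paste = RigidTransform(t.rot, t.tilt, t.psi, dpos + t.shift)
            acc += rotate_grid(model, paste)
            found = True
        if not found:
            out[i] = work[i]
            continue
        if faces[i] == "down":
            acc = flip_x180(acc)
        if wedge is not None:
            acc = np.fft.ifftn(np.fft.fftn(acc) * wedge).real
        denom = float((acc * acc).sum())
        if denom <= 0:
            out[i] = work[i]
            continue
        alpha = float((work[i] * acc).sum()) / denom
        alpha = np.clip(alpha, 0.0, 2.0)
        out[i] = (work[i] - alpha * acc).astype(np.float32)
    return out


def _data_mask(shape, voxel_size: float, radius: float,
               pose: RigidTransform, z_min: float = -60.0,
               soft: float = 15.0) -> np.ndarray:
    """Alignment-region mask carried to a particle's estimated pose."""
    ones = np.ones(shape, dtype=np.float32)
    base = _alignment_mask(ones, voxel_size, radius, z_min=z_min, soft=soft)
    return rotate_grid(base, RigidTransform(pose.rot, pose.tilt, pose.psi,
                                            pose.shift))


def _alignment_mask(arr: np.ndarray, voxel_size: float, radius: float,
                    z_min: float = -60.0, soft: float = 15.0) -> np.ndarray:
    """Soft cylinder about the reference axis, cut below ``z_min`` (Å).

    The particle is elongated along the reference axis while the bilayer
    and the neighbouring lattice particles are laterally extended, so a
    cylinder keeps the motif and removes most of the rest.  The region
    below the stalk base is cut as well: the bilayer forms a vertex
    "tent" there whose fold direction follows the lattice rows rather
    than the particle, and leaving it in locks the spin search onto the
    lattice instead of the peripheral stalk.
    """
    n = arr.shape[0]
    c = (n - 1) / 2.0
    idx = (np.arange(n) - c) * voxel_size
    r = np.sqrt(idx[None, :, None] ** 2 + idx[None, None, :] ** 2)
    lateral = np.clip((radius + soft / 2 - r) / soft, 0.0, 1.0)
    axial = np.clip((idx - z_min + soft / 2) / soft, 0.0, 1.0)[:, None, None]
    mask = lateral * axial
    return (arr * np.broadcast_to(mask, arr.shape)).astype(np.float32)


def merge_halfmaps(map_a: DensityVolume, map_b: DensityVolume) -> DensityVolume:
    if map_a.shape != map_b.shape:
        raise ValueError(f"half-map shapes differ: {map_a.shape} vs {map_b.shape}")
    return DensityVolume(
        (map_a.grid.astype(np.float64) + map_b.grid) / 2.0,
        map_a.voxel_size,
        map_a.origin.copy(),
    )
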