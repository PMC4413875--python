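"""Packing geometry: re-insertion and angle measurements.

The average can be pasted back into the tomogram frame with the inverse
of each particle's parameters, and per-particle long axes can be read
either from a particle table or directly from the tomogram density
(matched-filter localization of head and rotor ring around each pick).
The axes reduce to the quantities that describe the crystal packing: the
inclination of each long axis to the crystal-plane normal, the angle
between the axes of each same-face pair, the in-plane rotation relating
cross-membrane partners, the zigzag kink of the bilayer (by direct ridge
tracing where the membrane is sampled, or from the mid-membrane anchor
rows where the missing wedge hides it), and the dimer angle two joined
monomers would enclose.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .particles import ParticleTable
from .transforms import RigidTransform, X_FLIP
from .volume import DensityVolume, rotate_grid

__all__ = [
    "GeometryReport",
    "PairAssignments",
    "axes_to_table",
    "estimate_reference_axis",
    "find_pairs",
    "fit_crystal_plane",
    "fit_crystal_plane_from_pairs",
    "kink_from_particle_rows",
    "measure_axes_from_density",
    "measure_head_height",
    "measure_inclination",
    "measure_interface_rotation",
    "measure_pair_angle",
    "midmembrane_positions",
    "predict_dimer_angle",
    "reposition_average",
    "trace_membrane_kink",
]


@dataclass
class PairAssignments:
    pairs: list[tuple[int, int]]         # same-face mutual nearest neighbours
    interfaces: list[tuple[int, int]]    # (up index, down index)


@dataclass
class GeometryReport:
    inclination_deg: list[float] = field(default_factory=list)
    inclination_mean: float = float("nan")
    inclination_sd: float = float("nan")
    pair_angles_deg: list[float] = field(default_factory=list)
    pair_angle_mean: float = float("nan")
    pair_angle_sd: float = float("nan")
    interface_rotations_deg: list[float] = field(default_factory=list)
    interface_rotation_mean: float = float("nan")
    interface_rotation_sd: float = float("nan")
    kink_estimates_deg: list[float] = field(default_factory=list)
    kink_mean: float = float("nan")
    predicted_dimer_angle_deg: float = float("nan")
    head_height_nm: float = float("nan")

    def to_json(self, path=None) -> str:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# Plane fitting and axis extraction
# ---------------------------------------------------------------------------

def fit_crystal_plane(positions_xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points; returns (centroid, unit normal).

    The normal is oriented toward +z.  Degenerate (collinear) point sets
    raise a ValueError.
    """
    pts = np.asarray(positions_xyz, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 positions to fit a plane")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("degenerate plane fit: positions are collinear")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    return centroid, normal


def fit_crystal_plane_from_pairs(
    positions_xyz: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Plane through the midpoints of same-face pairs.

    Pair mates sit on adjacent zigzag vertex rows, so their midpoints lie
    on the crystal midplane by construction; fitting those cancels the
    ±h vertex alternation that tilts a plane fitted to raw positions in a
    finite field of view.  Falls back to all positions for < 3 pairs.
    """
    pts = np.asarray(positions_xyz, dtype=float)
    if len(pairs) >= 3:
        mids = np.array([(pts[i] + pts[j]) / 2.0 for i, j in pairs])
        return fit_crystal_plane(mids)
    return fit_crystal_plane(pts)


def _axes_xyz(table: ParticleTable,
              reference_axis: np.ndarray | None = None) -> np.ndarray:
    v = np.array([0.0, 0.0, 1.0]) if reference_axis is None else (
        np.asarray(reference_axis, dtype=float)
        / np.linalg.norm(reference_axis))
    return np.array([t.matrix @ v for t in table.transforms()])


def estimate_reference_axis(average: DensityVolume) -> np.ndarray:
    """Structural long axis of an average map (unit vector, xyz).

    The refined rotations map the reference frame into the tomogram; when
    the reference was bootstrapped from data its own long axis need not
    be +z, and per-particle axes in the tomogram are R @ v_ref.  The axis
    is estimated as the direction from the box center to the squared-
    density centroid, which the off-center catalytic head dominates.
    """
    grid = average.grid.astype(np.float64)
    c = (np.array(average.shape) - 1) / 2.0
    zc = (np.arange(average.shape[0]) - c[0]) * average.voxel_size
    yc = (np.arange(average.shape[1]) - c[1]) * average.voxel_size
    xc = (np.arange(average.shape[2]) - c[2]) * average.voxel_size
    # restrict to a cylinder about the nominal axis: the average also
    # carries the (laterally extended) bilayer, whose mass would drag a
    # whole-box centroid toward the membrane instead of the head
    r = np.sqrt(yc[None, :, None] ** 2 + xc[None, None, :] ** 2)
    sel = np.broadcast_to(r <= 66.0, grid.shape)
    w = np.clip(grid - np.median(grid), 0, None) ** 2
    w = np.where(sel, w, 0.0)
    if w.sum() <= 0:
        return np.array([0.0, 0.0, 1.0])
    tot = w.sum()
    vz = (w.sum(axis=(1, 2)) * zc).sum() / tot
    vy = (w.sum(axis=(0, 2)) * yc).sum() / tot
    vx = (w.sum(axis=(0, 1)) * xc).sum() / tot
    v = np.array([vx, vy, vz])
    n = np.linalg.norm(v)
    return np.array([0.0, 0.0, 1.0]) if n < 1e-6 else v / n


def midmembrane_positions(table: ParticleTable, voxel_size: float,
                          center_height: float,
                          reference_axis: np.ndarray | None = None
                          ) -> np.ndarray:
    """Positions (Å, xyz) projected down the long axis onto the membrane.

    The table stores the particle reference center, which sits
    ``center_height`` Å up the long axis from the rotor-ring midplane;
    walking back down the (refined) axis gives the in-membrane anchor
    points that define the crystal plane and the contact geometry.
    """
    pos = table.positions_xyz() * voxel_size
    axes = _axes_xyz(table, reference_axis)
    return pos - center_height * axes


def measure_inclination(
    table: ParticleTable,
    voxel_size: float = 1.0,
    plane_normal: np.ndarray | None = None,
    reference_axis: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Angle between each particle long axis and the crystal-plane normal.

    Down-face axes (any axis pointing into the opposite hemisphere) are
    flipped to the common hemisphere first.  The plane is fitted to the
    particle positions unless a normal is supplied.
    """
    if plane_normal is None:
        _, plane_normal = fit_crystal_plane(table.positions_xyz() * voxel_size)
    n = np.asarray(plane_normal, dtype=float)
    if np.linalg.norm(n) == 0:
        raise ValueError("plane normal must be non-zero")
    n = n / np.linalg.norm(n)
    axes = _axes_xyz(table, reference_axis)
    dots = axes @ n
    angles = np.degrees(np.arccos(np.clip(np.abs(dots), -1.0, 1.0)))
    return angles, float(angles.mean())


def find_pairs(
    table: ParticleTable,
    voxel_size: float,
    same_face_cutoff: float = 140.0,
    cross_face_cutoff: float = 70.0,
    positions: np.ndarray | None = None,
) -> PairAssignments:
    """Pair assignment from particle positions (cutoffs in Å).

    Same-face mutual nearest neighbours within the cutoff become pairs
    (each particle in at most one pair); each up particle's nearest down
    neighbour within the cross-face cutoff becomes an interface.  Pass
    ``positions`` (Å, xyz) to pair on, e.g., mid-membrane anchor points —
    cross-face partners touch at their rotor rings, not at their heads.
    """
    pos = table.positions_xyz() * voxel_size if positions is None else positions
    faces = table.faces()
    pairs: list[tuple[int, int]] = []
    for face in ("up", "down"):
        idx = np.where(faces == face)[0]
        if len(idx) < 2 or same_face_cutoff <= 0:
            continue
        tree = cKDTree(pos[idx])
        dist, nn = tree.query(pos[idx], k=2)
        for a in range(len(idx)):
            b = nn[a, 1]
            if dist[a, 1] <= same_face_cutoff and nn[b, 1] == a and a < b:
                pairs.append((int(idx[a]), int(idx[b])))
    interfaces: list[tuple[int, int]] = []
    up = np.where(faces == "up")[0]
    down = np.where(faces == "down")[0]
    if len(up) and len(down) and cross_face_cutoff > 0:
        tree = cKDTree(pos[down])
        dist, nn = tree.query(pos[up], k=1)
        for a, (d, b) in enumerate(zip(dist, nn)):
            if d <= cross_face_cutoff:
                interfaces.append((int(up[a]), int(down[b])))
    return PairAssignments(pairs, interfaces)


def measure_pair_angle(
    pairs: list[tuple[int, int]], table: ParticleTable,
    reference_axis: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Angle between the long axes of each pair, folded to [0°, 90°]."""
    axes = _axes_xyz(table, reference_axis)
    out = []
    for i, j in pairs:
        d = np.clip(abs(axes[i] @ axes[j]), -1.0, 1.0)
        out.append(np.degrees(np.arccos(d)))
    out = np.array(out)
    return out, float(out.mean()) if len(out) else float("nan")


def measure_interface_rotation(
    interfaces: list[tuple[int, int]],
    table: ParticleTable,
    plane_normal: np.ndarray | None = None,
    flip_axis: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Residual in-plane rotation between cross-membrane partners.

    The down particle is first mapped through the 180° flip convention
    (about the tomogram x axis by default — ``flip_axis`` rotates the
    convention along with any global rotation of the scene); the
    remaining rotation is projected onto the rotation about the plane
    normal and folded to [0°, 180°).
    """
    if plane_normal is None:
        n = np.array([0.0, 0.0, 1.0])
    else:
        n = np.asarray(plane_normal, dtype=float)
        n = n / np.linalg.norm(n)
    # basis with e3 = plane normal
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    basis = np.stack([e1, e2, n], axis=1)

    transforms = table.transforms()
    if flip_axis is None:
        flip = X_FLIP.matrix
    else:
        from scipy.spatial.transform import Rotation

        a = np.asarray(flip_axis, dtype=float)
        a = a - (a @ n) * n  # flip axis lies in the plane
        a /= np.linalg.norm(a)
        flip = Rotation.from_rotvec(np.pi * a).as_matrix()
    out = []
    for iu, idn in interfaces:
        ru = transforms[iu].matrix
        rd = transforms[idn].matrix
        q = rd @ np.linalg.inv(flip @ ru)
        qp = basis.T @ q @ basis   # express in plane frame; rotation ~ about e3
        ang = np.degrees(np.arctan2(qp[1, 0] - qp[0, 1], qp[0, 0] + qp[1, 1]))
        ang = ang % 360.0
        if ang > 180.0:
            ang = 360.0 - ang
        out.append(ang)
    out = np.array(out)
    return out, float(out.mean()) if len(out) else float("nan")


# ---------------------------------------------------------------------------
# Re-insertion
# ---------------------------------------------------------------------------

def reposition_average(
    tomogram_shape: tuple[int, int, int],
    table: ParticleTable,
    average: DensityVolume,
) -> DensityVolume:
    """Paste the average at every particle using its transform.

    The rotated copy is added at the particle position; overlaps are
    summed.  Pastes reaching outside the volume are clipped (counted in a
    warning).
    """
    nz, ny, nx = tomogram_shape
    box = average.shape[0]
    if box > min(tomogram_shape):
        raise ValueError("average box larger than tomogram")
    canvas = np.zeros(tomogram_shape, dtype=np.float64)
    half = box // 2
    clipped = 0
    for (z, y, x), t in zip(table.positions_zyx(), table.transforms()):
        iz, iy, ix = int(np.floor(z)), int(np.floor(y)), int(np.floor(x))
        frac = np.array([z - iz, y - iy, x - ix])
        pasted = rotate_grid(average.grid, RigidTransform(t.rot, t.tilt, t.psi,
                                                          shift=frac))
        lo = np.array([iz, iy, ix]) - half
        hi = lo + box
        src_lo = np.maximum(-lo, 0)
        src_hi = box - np.maximum(hi - [nz, ny, nx], 0)
        dst_lo = np.maximum(lo, 0)
        dst_hi = np.minimum(hi, [nz, ny, nx])
        if np.any(src_lo > 0) or np.any(src_hi < box):
            clipped += 1
        if np.any(dst_hi <= dst_lo):
            continue
        canvas[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] += \
            pasted[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    if clipped:
        warnings.warn(f"{clipped} re-inserted particles clipped at volume edges")
    return DensityVolume(canvas.astype(np.float32), average.voxel_size)


# ---------------------------------------------------------------------------
# Membrane tracing
# ---------------------------------------------------------------------------

def trace_membrane_kink(
    tomogram: DensityVolume,
    row_spacing: float,
    direction: np.ndarray | None = None,
    band_halfwidth: float = 45.0,
    membrane_z: float | None = None,
    membrane_thickness: float = 40.0,
    exclude_fraction: float = 0.6,
    min_segment_points: int = 3,
    column_quantile: float = 0.15,
    smooth_sigma: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Kink angles of the zigzag membrane from a density ridge trace.

    The tomogram is projected onto the in-plane axis perpendicular to the
    particle rows (``direction``, default +x); for each position u along
    that axis the membrane ridge z is located as the density maximum
    within a band around the membrane midplane (sub-voxel by parabolic
    fit).  A piecewise-linear model with breakpoints every ``row_spacing``
    Å (phase chosen by best fit) is fitted to the ridge, excluding a
    fraction of each segment around the vertices where the rotor rings
    sit (their cylindrical density holds the ridge at the vertex level
    and would flatten the trace); the kink at each vertex is the angle
    between the direction vectors of the adjacent segments.
    """
    vs = tomogram.voxel_size
    nz, ny, nx = tomogram.shape
    if direction is None:
        direction = np.array([1.0, 0.0])
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)

    zc = tomogram.axis_coords(0)
    if membrane_z is None:
        membrane_z = _estimate_membrane_z(tomogram)
    band = np.abs(zc - membrane_z) <= band_halfwidth
    if not np.any(band):
        raise ValueError("membrane band is empty; check membrane_z")
    from scipy.ndimage import gaussian_filter

    # light smoothing tames reconstruction noise before quantile profiling
    sub = gaussian_filter(tomogram.grid.astype(np.float64), smooth_sigma)[band]
    zb = zc[band]

    # bin the in-plane columns by u = r . d; the profile per bin is a low
    # quantile over columns: the bilayer is continuous along the rows
    # while stalk densities from the flanking particle rows interleave and
    # can touch up to half the columns, so a sub-median quantile is needed
    # to suppress them
    xs = np.arange(nx) * vs
    ys = np.arange(ny) * vs
    u = xs[None, :] * d[0] + ys[:, None] * d[1]       # (ny, nx)
    u_flat = u.ravel()
    bins = np.floor((u_flat - u_flat.min()) / vs).astype(int)
    n_bins = bins.max() + 1
    counts = np.bincount(bins, minlength=n_bins)
    good = counts > 0
    if not np.any(good):
        raise ValueError("ridge lost: no in-plane columns in the trace")
    sub_flat = sub.reshape(sub.shape[0], -1)          # (nzb, ny*nx)
    order = np.argsort(bins, kind="stable")
    splits = np.cumsum(counts)[:-1]
    prof = np.zeros((n_bins, sub.shape[0]))
    grouped = np.split(order, splits)
    for bi, cols in enumerate(grouped):
        if len(cols):
            prof[bi] = np.quantile(sub_flat[:, cols], column_quantile, axis=1)
    # remove the quantile's noise-floor offset using the band edges, where
    # only background lives
    edge_rows = np.r_[prof[:, :2].ravel(), prof[:, -2:].ravel()]
    baseline = float(np.median(edge_rows[np.isfinite(edge_rows)]))
    prof = prof - baseline

    u_axis = u_flat.min() + (np.arange(n_bins) + 0.5) * vs
    good_idx = np.where(good)[0]

    # pass 1: matched filter with a zero-mean slab template gives a coarse
    # ridge robust to stalk densities above and below the bilayer
    width_px = max(int(round(membrane_thickness / vs)), 3)
    template = np.ones(width_px)
    coarse = np.full(n_bins, np.nan)
    for bi in good_idx:
        p = prof[bi]
        if p.max() <= 0:
            continue
        c = np.correlate(p - p.mean(), template, mode="same")
        coarse[bi] = zb[int(np.argmax(c))]
    # median smoothing over ~half a row of bins
    from scipy.ndimage import median_filter

    coarse_f = median_filter(coarse, size=5, mode="nearest")

    # pass 2: slab support midpoint inside a narrow local band that the
    # stalks (which begin above the membrane surface) cannot reach
    local_half = membrane_thickness / 2.0 + 10.0
    peaks = [prof[bi].max() for bi in good_idx if prof[bi].max() > 0]
    if not peaks:
        raise ValueError("ridge lost: no density in the membrane band")
    slab_level = float(np.median(peaks))
    ridge_u, ridge_z = [], []
    for bi in good_idx:
        if not np.isfinite(coarse_f[bi]):
            continue
        sel = np.abs(zb - coarse_f[bi]) <= local_half
        if sel.sum() < 3:
            continue
        z = _slab_midpoint(prof[bi][sel], zb[sel], threshold=0.5 * slab_level)
        if z is None:
            continue
        ridge_u.append(u_axis[bi])
        ridge_z.append(z)
    if len(ridge_u) < 2 * min_segment_points:
        raise ValueError("ridge lost: too few traced columns")
    ridge_u = np.array(ridge_u)
    ridge_z = np.array(ridge_z)

    # choose the breakpoint phase that minimizes the piecewise-linear residual
    best = None
    for phase in np.linspace(0.0, row_spacing, 24, endpoint=False):
        res, slopes = _piecewise_fit(ridge_u, ridge_z, row_spacing, phase,
                                     exclude_fraction, min_segment_points)
        if res is not None and (best is None or res < best[0]):
            best = (res, slopes)
    if best is None:
        raise ValueError("ridge lost: could not fit membrane segments")
    _, slopes = best
    kinks = []
    for (s1, n1), (s2, n2) in zip(slopes[:-1], slopes[1:]):
        if n2 != n1 + 1:
            continue   # only adjacent segments share a vertex
        kinks.append(abs(np.degrees(np.arctan(s2) - np.arctan(s1))))
    kinks = np.array(kinks)
    if len(kinks) == 0:
        raise ValueError("ridge lost: no adjacent segment pairs")
    return kinks, float(kinks.mean())


def _slab_midpoint(p: np.ndarray, zb: np.ndarray,
                   threshold: float | None = None) -> float | None:
    """Midpoint of the super-threshold support of a slab-like profile.

    The bilayer appears as a wide plateau; thin stalk densities above or
    below it stay under the threshold and cannot pull the trace, unlike a
    centroid.  Crossings are located with linear interpolation.  The
    threshold should be half the typical slab level (a fixed value keeps
    low-contrast columns from admitting stalk density).
    """
    m = p.max()
    if m <= 0:
        return None
    thr = 0.5 * m if threshold is None else threshold
    if m < thr:
        return None
    above = np.where(p >= thr)[0]
    if len(above) == 0:
        return None
    i0, i1 = above[0], above[-1]
    z_lo = zb[i0]
    if i0 > 0 and p[i0] > p[i0 - 1]:
        f = (thr - p[i0 - 1]) / (p[i0] - p[i0 - 1])
        z_lo = zb[i0 - 1] + f * (zb[i0] - zb[i0 - 1])
    z_hi = zb[i1]
    if i1 < len(p) - 1 and p[i1] > p[i1 + 1]:
        f = (thr - p[i1 + 1]) / (p[i1] - p[i1 + 1])
        z_hi = zb[i1 + 1] - f * (zb[i1 + 1] - zb[i1])
    return float(0.5 * (z_lo + z_hi))


def _piecewise_fit(u, z, spacing, phase, exclude_fraction, min_points):
    seg_idx = np.floor((u - phase) / spacing).astype(int)
    frac = np.mod(u - phase, spacing) / spacing
    interior = (frac > exclude_fraction / 2) & (frac < 1 - exclude_fraction / 2)
    slopes = []
    res_sum, res_n = 0.0, 0
    for s in np.unique(seg_idx):
        sel = (seg_idx == s) & interior
        if sel.sum() < min_points:
            continue
        A = np.stack([u[sel], np.ones(sel.sum())], axis=1)
        coef, *_ = np.linalg.lstsq(A, z[sel], rcond=None)
        pred = A @ coef
        res_sum += float(((z[sel] - pred) ** 2).sum())
        res_n += int(sel.sum())
        slopes.append((float(coef[0]), int(s)))
    if len(slopes) < 2 or res_n == 0:
        return None, None
    return res_sum / res_n, [(sl, s) for sl, s in slopes]


def _estimate_membrane_z(tomogram: DensityVolume, window: float = 80.0) -> float:
    """Membrane midplane z (Å): density centroid near the volume center."""
    zc = tomogram.axis_coords(0)
    profile = tomogram.grid.mean(axis=(1, 2)).astype(np.float64)
    center = zc[len(zc) // 2]
    sel = np.abs(zc - center) <= window
    p = np.clip(profile[sel] - profile[sel].min(), 0, None)
    if p.sum() <= 0:
        return float(center)
    return float((p * zc[sel]).sum() / p.sum())


def measure_axes_from_density(
    tomogram: DensityVolume,
    table: ParticleTable,
    head_offset: float = 60.0,
    ring_offset: float = 90.0,
    head_radius: float = 50.0,
    ring_radii: tuple[float, float] = (12.0, 22.0),
    ring_height: float = 40.0,
    head_search: float = 34.0,
    ring_search: float = 13.0,
    refine_search: float = 20.0,
    line_tolerance: float = 12.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-particle long axes measured directly from the tomogram density.

    For every picked particle the catalytic head and the rotor ring are
    located by matched filtering (a soft ball and a soft annulus).  The
    first pass finds the head near its expected position above/below the
    pick and takes a provisional axis from pick to head; the second pass
    re-centers the head search and looks for the ring down that axis in
    a deliberately tight window — the cross-membrane partner's ring sits
    only ~30 Å away and a wide window would lock onto it.  The final
    axis is the unit vector from ring to head, a ~150 Å baseline that
    the missing wedge leaves measurable because both features are
    compact.  Returns (axes (N, 3) xyz unit vectors pointing from
    membrane to head, valid mask, head positions (N, 3) in Å).

    This is the re-insertion logic of hybrid crystallographic/tomographic
    packing analysis: orientations are read from where the rigid bodies
    sit in the map, not from per-particle rotational matching, whose spin
    component is ill-determined for a pseudo-symmetric complex in a
    tight lattice.
    """
    vs = tomogram.voxel_size
    nz, ny, nx = tomogram.shape

    def _template_cc(template_fn):
        zc0 = np.fft.fftfreq(nz) * nz * vs
        yc0 = np.fft.fftfreq(ny) * ny * vs
        xc0 = np.fft.fftfreq(nx) * nx * vs
        t = template_fn(zc0[:, None, None], yc0[None, :, None],
                        xc0[None, None, :])
        t = t - t.mean()
        g = tomogram.grid.astype(np.float64)
        return np.fft.ifftn(np.fft.fftn(g - g.mean())
                            * np.conj(np.fft.fftn(t))).real

    def _ball(z, y, x, soft=16.0):
        r = np.sqrt(z**2 + y**2 + x**2)
        return np.clip((head_radius + soft / 2 - r) / soft, 0.0, 1.0)

    def _ring(z, y, x, soft=12.0):
        rl = np.sqrt(y**2 + x**2)
        return (np.clip((ring_radii[1] + soft / 2 - rl) / soft, 0, 1)
                * np.clip((rl - ring_radii[0] + soft / 2) / soft, 0, 1)
                * np.clip((ring_height / 2 + soft / 2 - np.abs(z)) / soft, 0, 1))

    cc_head = _template_cc(_ball)
    cc_ring = _template_cc(_ring)

    def _local_peak(cc, g0, search):
        iz = (g0[2] - tomogram.origin[0]) / vs
        iy, ix = g0[1] / vs, g0[0] / vs
        w = int(np.ceil(search / vs))
        zs = slice(max(0, int(iz) - w), min(nz, int(iz) + w + 1))
        ys = slice(max(0, int(iy) - w), min(ny, int(iy) + w + 1))
        xs = slice(max(0, int(ix) - w), min(nx, int(ix) + w + 1))
        win = cc[zs, ys, xs]
        if win.size == 0:
            return None
        k = np.unravel_index(np.argmax(win), win.shape)
        p = [zs.start + k[0], ys.start + k[1], xs.start + k[2]]
        out = []
        for a, (pp, nn) in enumerate(zip(p, (nz, ny, nx))):
            d = 0.0
            if 0 < pp < nn - 1:
                idx = list(p)
                idx[a] = pp - 1
                ym = cc[tuple(idx)]
                idx[a] = pp + 1
                yp = cc[tuple(idx)]
                den = ym - 2 * cc[tuple(p)] + yp
                if abs(den) > 1e-12:
                    d = np.clip(0.5 * (ym - yp) / den, -1, 1)
            out.append(pp + d)
        return np.array([out[2] * vs, out[1] * vs,
                         tomogram.origin[0] + out[0] * vs])

    n = len(table)
    axes = np.zeros((n, 3))
    heads = np.zeros((n, 3))
    ok = np.zeros(n, dtype=bool)
    faces = table.faces()
    pos = table.positions_xyz() * vs
    pos[:, 2] += tomogram.origin[0]
    for i in range(n):
        sgn = 1.0 if faces[i] == "up" else -1.0
        v = np.array([0.0, 0.0, sgn])
        # pass 1: head only, provisional axis pick -> head
        head = _local_peak(cc_head, pos[i] + head_offset * v, head_search)
        if head is None:
            continue
        d = head - pos[i]
        if np.linalg.norm(d) < 0.4 * head_offset:
            continue
        v = d / np.linalg.norm(d)
        # pass 2: tight searches down the provisional axis
        good = False
        for _ in range(2):
            head = _local_peak(cc_head, pos[i] + head_offset * v,
                               refine_search)
            ring = _local_peak(cc_ring, pos[i] - ring_offset * v, ring_search)
            if head is None or ring is None:
                break
            d = head - ring
            nrm = np.linalg.norm(d)
            if nrm < 0.4 * (head_offset + ring_offset):
                break
            v = d / nrm
            good = True
        if not good:
            continue
        # quality gate: head, pick and ring must be collinear — a capture
        # of a neighbouring head or ring breaks the line through the pick
        off_line = np.linalg.norm(np.cross(pos[i] - ring, v))
        if off_line > line_tolerance:
            continue
        axes[i] = v
        heads[i] = head
        ok[i] = True
    return axes, ok, heads


def axes_to_table(table: ParticleTable, axes: np.ndarray,
                  valid: np.ndarray | None = None) -> ParticleTable:
    """Particle table whose rotations encode the given long axes.

    rot = axis azimuth, tilt = polar angle, psi = 0: the minimal rotation
    convention for axis-level geometry — inclination, pair angles and the
    cross-face interface rotation are all well defined on it (the spin
    about the axis cancels out of each of those quantities).
    """
    df = table.df.copy()
    for i, v in enumerate(axes):
        if valid is not None and not valid[i]:
            continue
        df.loc[df.index[i], "rot"] = float(np.degrees(np.arctan2(v[1], v[0])))
        df.loc[df.index[i], "tilt"] = float(
            np.degrees(np.arccos(np.clip(v[2], -1.0, 1.0))))
        df.loc[df.index[i], "psi"] = 0.0
    out = ParticleTable(df)
    if valid is not None and not np.all(valid):
        out = ParticleTable(out.df[valid].reset_index(drop=True))
    return out


def kink_from_particle_rows(
    table: ParticleTable,
    voxel_size: float,
    center_height: float,
    row_spacing: float,
    direction: np.ndarray | None = None,
    min_row_members: int = 2,
    reference_axis: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Membrane kink from the refined particles' mid-membrane anchor rows.

    In a missing-wedge tomogram the bilayer's own density is unsampled
    where its surface is nearly normal to the beam, but the rotor rings
    are recovered by alignment; their mid-membrane anchor points (one row
    per zigzag vertex) carry the membrane height.  This fits the same
    piecewise-linear zigzag — breakpoints every ``row_spacing`` Å along
    the row normal, one height per row — and reports the angle between
    adjacent segment directions.
    """
    if direction is None:
        direction = np.array([1.0, 0.0])
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    mid = midmembrane_positions(table, voxel_size, center_height, reference_axis)
    u = mid[:, 0] * d[0] + mid[:, 1] * d[1]
    z = mid[:, 2]
    # phase: minimize within-row spread of u
    best = None
    for phase in np.linspace(0.0, row_spacing, 48, endpoint=False):
        resid = np.mod(u - phase + row_spacing / 2, row_spacing) - row_spacing / 2
        r = float((resid**2).sum())
        if best is None or r < best[0]:
            best = (r, phase)
    phase = best[1]
    rows = np.rint((u - phase) / row_spacing).astype(int)
    heights: dict[int, float] = {}
    for r in np.unique(rows):
        sel = rows == r
        if sel.sum() >= min_row_members:
            heights[int(r)] = float(z[sel].mean())
    ks = []
    for r in sorted(heights):
        if r - 1 in heights and r + 1 in heights:
            s1 = (heights[r] - heights[r - 1]) / row_spacing
            s2 = (heights[r + 1] - heights[r]) / row_spacing
            ks.append(abs(np.degrees(np.arctan(s2) - np.arctan(s1))))
    ks = np.array(ks)
    if len(ks) == 0:
        raise ValueError("too few populated particle rows to estimate a kink")
    return ks, float(ks.mean())


def predict_dimer_angle(kink_kappa: float) -> float:
    """Dimer angle implied by two monomers sharing a membrane kink: 2κ."""
    if not (0.0 <= kink_kappa < 90.0):
        raise ValueError("kink must be in [0°, 90°)")
    return 2.0 * kink_kappa


# ---------------------------------------------------------------------------
# Head height
# ---------------------------------------------------------------------------

def measure_head_height(
    tomogram: DensityVolume,
    band: tuple[float, float] = (70.0, 235.0),
    smooth_sigma: float = 1.5,
    membrane_z: float | None = None,
    min_blob_voxels: int | None = None,
) -> tuple[float, np.ndarray]:
    """Mean height (nm) of up-face head centroids above the membrane midplane.

    Segments the density band ``band`` Å above the midplane (threshold at
    mean + 2 sd after Gaussian smoothing), labels connected blobs and
    averages their centroid heights.
    """
    from scipy import ndimage

    vs = tomogram.voxel_size
    if membrane_z is None:
        membrane_z = _estimate_membrane_z(tomogram)
    zc = tomogram.axis_coords(0)
    sel = (zc >= membrane_z + band[0]) & (zc <= membrane_z + band[1])
    if not np.any(sel):
        raise ValueError("head band empty; volume too thin")
    sub = ndimage.gaussian_filter(tomogram.grid[sel].astype(np.float64),
                                  smooth_sigma)
    thresh = 0.5 * sub.max()
    labels, n = ndimage.label(sub > thresh)
    if n == 0:
        raise ValueError("no head densities above threshold")
    sizes = ndimage.sum_labels(np.ones_like(sub), labels, index=np.arange(1, n + 1))
    if min_blob_voxels is None:
        min_blob_voxels = max(int(0.25 * sizes.max()), 8)
    keep = np.where(sizes >= min_blob_voxels)[0] + 1
    if len(keep) == 0:
        raise ValueError("no head densities above the minimum blob size")
    coms = ndimage.center_of_mass(sub, labels, keep)
    z_band = zc[sel]
    heights = np.array([
        z_band[0] + com[0] * vs - membrane_z for com in coms
    ]) / 10.0  # Å -> nm
    # the zigzag membrane places alternate particle rows at two vertex
    # levels; average the two level means so a finite field of view with
    # unequal row counts does not bias the estimate
    mean_h = float(heights.mean())
    if len(heights) >= 4 and (heights.max() - heights.min()) > 1.0:
        mid = 0.5 * (heights.max() + heights.min())
        hi, lo = heights[heights >= mid], heights[heights < mid]
        if len(hi) and len(lo):
            mean_h = float(0.5 * (hi.mean() + lo.mean()))
    return mean_h, heights
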