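"""Synthetic ground truth: phantom complex, 2D crystal, tilt series, WBP.

This module emulates the raw data of the study system: a 2D membrane
crystal of a large rotary ATPase (a ~10 nm catalytic head held ~15 nm
above the bilayer on a central stalk, with a peripheral stalk and a
membrane-embedded rotor ring), packed on an oblique 2D lattice with
complexes on both membrane faces, their long axes inclined to the crystal
normal so that the bilayer adopts a zigzag profile.  The crystal volume is
projected into a single-axis tilt series (tilt axis y) and reconstructed
by ramp-weighted back-projection, which produces the characteristic
missing-wedge anisotropy of electron cryo-tomography.

All densities are rendered as soft-edged solids (erf edge profile): a
smooth contrast model that keeps the phantom's power spectrum decaying
realistically toward high resolution and is friendly to trilinear
resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as _ndrotate
from scipy.special import erf

from .particles import COLUMNS, ParticleTable
from .transforms import RigidTransform, X_FLIP, compose_transforms
from .volume import DensityVolume

__all__ = [
    "PhantomSpec",
    "CrystalSpec",
    "TiltSeries",
    "build_phantom",
    "build_crystal_volume",
    "simulate_tilt_series",
    "default_tilt_angles",
    "reconstruct_wbp",
    "wedge_mask",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometric stand-in for the membrane complex (all lengths in Å).

    z = 0 is the membrane midplane; the long axis is +z.  The default
    geometry places a 100 Å spherical catalytic head 150 Å above the
    membrane, a thin central stalk, an off-axis peripheral stalk and an
    annular rotor ring embedded in the bilayer.
    """

    head_diameter: float = 100.0
    head_height: float = 150.0
    central_stalk_radius: float = 10.0
    central_stalk_length: float = 80.0
    peripheral_stalk_radius: float = 16.0
    peripheral_stalk_offset: float = 40.0
    cring_radius_outer: float = 22.0
    cring_radius_inner: float = 12.0
    membrane_thickness: float = 40.0
    protein_density: float = 1.0
    lipid_density: float = 0.5
    edge_sigma: float = 8.0
    center_height: float = 90.0  # z of the particle reference center

    def __post_init__(self):
        for name in (
            "head_diameter", "head_height", "central_stalk_radius",
            "central_stalk_length", "peripheral_stalk_radius",
            "cring_radius_outer", "membrane_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.head_height <= self.head_diameter / 2:
            raise ValueError("head_height must exceed head_diameter/2")

    @property
    def z_top(self) -> float:
        return self.head_height + self.head_diameter / 2

    @property
    def z_bottom(self) -> float:
        return -self.membrane_thickness / 2

    def bounding_radius(self) -> float:
        """Radius (about the reference center) containing all density."""
        half_span = max(self.z_top - self.center_height,
                        self.center_height - self.z_bottom)
        lateral = self.peripheral_stalk_offset + self.peripheral_stalk_radius
        lateral = max(lateral, self.head_diameter / 2, self.cring_radius_outer)
        return float(np.hypot(half_span, lateral) + 3 * self.edge_sigma)


@dataclass
class CrystalSpec:
    """2D crystal geometry: lattice, motif, inclinations, membrane zigzag."""

    a: float = 179.1
    b: float = 171.4
    gamma: float = 94.9            # degrees
    inclination_theta: float = 16.0
    pair_azimuth_delta: float = 97.93   # gives a 24.0° intra-pair axis angle
    interface_rotation: float = 90.0
    kink_kappa: float = 43.0
    base_azimuth: float = 0.0
    cross_face_offset: float = 30.0     # Å, lateral offset of the down partner
    jitter_sigma_xy: float = 2.0        # Å
    jitter_sigma_angle: float = 1.0     # degrees
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gamma < 180):
            raise ValueError("gamma must be in (0, 180) degrees")
        if not (0 <= self.inclination_theta < 45):
            raise ValueError("inclination_theta must be in [0, 45)")
        if not (0 <= self.kink_kappa < 90):
            raise ValueError("kink_kappa must be in [0, 90)")

    # -- lattice helpers ----------------------------------------------------

    def cell_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        g = np.radians(self.gamma)
        return (np.array([self.a, 0.0]),
                np.array([self.b * np.cos(g), self.b * np.sin(g)]))

    def row_normal(self) -> np.ndarray:
        """In-plane unit vector perpendicular to the particle rows (|| b)."""
        g = np.radians(self.gamma)
        return np.array([np.sin(g), -np.cos(g)])

    def row_spacing(self) -> float:
        """Distance between adjacent zigzag vertex rows (Å)."""
        return self.a * np.sin(np.radians(self.gamma)) / 2.0

    def zigzag_amplitude(self) -> float:
        """Peak height h of the triangle-wave membrane midsurface (Å)."""
        return self.row_spacing() / 2.0 * np.tan(np.radians(self.kink_kappa / 2.0))

    def membrane_height(self, x, y) -> np.ndarray:
        """Membrane midsurface z (Å) at in-plane position (x, y) in Å."""
        nx, ny = self.row_normal()
        u = np.asarray(x) * nx + np.asarray(y) * ny
        h = self.zigzag_amplitude()
        period = 2.0 * self.row_spacing()
        t = np.mod(u, period) / self.row_spacing()  # in [0, 2)
        return np.where(t < 1.0, h * (1.0 - 2.0 * t), h * (2.0 * t - 3.0))


@dataclass
class TiltSeries:
    images: np.ndarray            # (n_angles, ny, nx)
    angles: np.ndarray            # degrees, about the y axis
    pixel_size: float             # Å
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3 or len(self.images) != len(self.angles):
            raise ValueError("one image per tilt angle required")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("tilt angles must be strictly increasing")


# ---------------------------------------------------------------------------
# Density rendering
# ---------------------------------------------------------------------------

def _sstep(t: np.ndarray, sigma: float) -> np.ndarray:
    """Soft unit step: ~1 for t >> 0, ~0 for t << 0, erf edge of width sigma."""
    return 0.5 * (1.0 + erf(t / (np.sqrt(2.0) * sigma)))


def _protein_density(spec: PhantomSpec, x, y, z) -> np.ndarray:
    """Protein density at phantom-frame coordinates (Å, z=0 at membrane)."""
    s = spec.edge_sigma
    p = spec.protein_density
    out = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z)))

    # catalytic head: sphere
    r_head = np.sqrt(x**2 + y**2 + (z - spec.head_height) ** 2)
    out += p * _sstep(spec.head_diameter / 2.0 - r_head, s)

    # central stalk: on-axis cylinder from the rotor ring up to the head
    z1 = spec.membrane_thickness / 2.0 - 5.0
    z2 = z1 + spec.central_stalk_length
    r_ax = np.sqrt(x**2 + y**2)
    out += p * (_sstep(spec.central_stalk_radius - r_ax, s)
                * _sstep(z - z1, s) * _sstep(z2 - z, s))

    # peripheral stalk: off-axis cylinder from membrane surface to head level
    r_ps = np.sqrt((x - spec.peripheral_stalk_offset) ** 2 + y**2)
    out += p * (_sstep(spec.peripheral_stalk_radius - r_ps, s)
                * _sstep(z - z1, s) * _sstep(spec.head_height - z, s))

    # rotor ring: annulus spanning the bilayer
    half = spec.membrane_thickness / 2.0
    ring = (_sstep(spec.cring_radius_outer - r_ax, s)
            * _sstep(r_ax - spec.cring_radius_inner, s)
            * _sstep(z + half, s) * _sstep(half - z, s))
    out += p * ring
    return out


def build_phantom(
    spec: PhantomSpec,
    voxel_size: float,
    box: int | None = None,
    include_membrane: bool = False,
) -> DensityVolume:
    """Render the single-particle phantom into a cubic volume.

    The volume is centered on the particle reference point (``center_height``
    Å up the long axis); the ``origin`` field is set so that physical z = 0
    is the membrane midplane.
    """
    if box is None:
        box = int(np.ceil(2.0 * spec.bounding_radius() / voxel_size)) + 2
    need = 2.0 * max(spec.z_top - spec.center_height,
                     spec.center_height - spec.z_bottom)
    if box * voxel_size < need:
        raise ValueError(
            f"box of {box} voxels ({box * voxel_size:.0f} Å) too small; "
            f"needs at least {need:.0f} Å to contain the phantom"
        )
    c = (box - 1) / 2.0
    idx = np.arange(box)
    zc = (idx - c)[:, None, None] * voxel_size + spec.center_height
    yc = (idx - c)[None, :, None] * voxel_size
    xc = (idx - c)[None, None, :] * voxel_size
    grid = _protein_density(spec, xc, yc, zc)
    if include_membrane:
        half = spec.membrane_thickness / 2.0
        grid = grid + spec.lipid_density * (
            _sstep(zc + half, spec.edge_sigma) * _sstep(half - zc, spec.edge_sigma)
        ) * np.ones_like(grid)
    origin_z = spec.center_height - c * voxel_size
    return DensityVolume(
        grid.astype(np.float32),
        voxel_size,
        origin=np.array([origin_z, -c * voxel_size, -c * voxel_size]),
    )


# ---------------------------------------------------------------------------
# Crystal volume
# ---------------------------------------------------------------------------

class PackingWarning(UserWarning):
    pass


def _motif(crystal: CrystalSpec) -> list[dict]:
    """Per-cell placements: fractional position, face, rotation matrix."""
    theta = crystal.inclination_theta
    half_d = crystal.pair_azimuth_delta / 2.0
    phi0 = crystal.base_azimuth
    up1 = RigidTransform(phi0 - half_d, theta, 0.0)
    up2 = RigidTransform(phi0 + half_d, theta, 0.0)
    flip = X_FLIP
    rho = RigidTransform(crystal.interface_rotation, 0.0, 0.0)
    down1 = compose_transforms(rho, compose_transforms(flip, up1))
    down2 = compose_transforms(rho, compose_transforms(flip, up2))
    return [
        {"frac": np.array([0.0, 0.25]), "face": "up", "t": up1, "partner_shift": False},
        {"frac": np.array([0.5, 0.75]), "face": "up", "t": up2, "partner_shift": False},
        {"frac": np.array([0.0, 0.25]), "face": "down", "t": down1, "partner_shift": True},
        {"frac": np.array([0.5, 0.75]), "face": "down", "t": down2, "partner_shift": True},
    ]


def _random_small_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    if sigma_deg <= 0:
        return np.eye(3)
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, np.radians(sigma_deg))
    return Rotation.from_rotvec(axis * angle).as_matrix()


def build_crystal_volume(
    crystal: CrystalSpec,
    phantom: PhantomSpec,
    box: tuple[int, int, int] = (96, 96, 96),
    voxel_size: float = 6.66,
    table_margin: float = 85.0,
    overlap_tolerance: float = 25.0,
) -> tuple[DensityVolume, ParticleTable]:
    """Render the 2D crystal and return (volume, ground-truth table).

    Per unit cell: two up-face monomers (an in-plane pair, long axes tilted
    ``inclination_theta`` from the normal with azimuths ``pair_azimuth_delta``
    apart) and two down-face monomers (the up rotations composed with a 180°
    x-flip and the cross-membrane ``interface_rotation`` about z), their
    rotor rings apposed across the bilayer.  The membrane is a zigzag slab
    whose vertices coincide with the particle rows.  The table records every
    placement at least ``table_margin`` Å from the volume's xy faces.
    """
    nz, ny, nx = box
    rng = np.random.default_rng(crystal.seed)
    av, bv = crystal.cell_vectors()
    if min(nx, ny) * voxel_size < 3 * max(crystal.a, crystal.b):
        warnings.warn(
            "box spans fewer than 3x3 unit cells in-plane", PackingWarning
        )

    c = np.array([(nz - 1) / 2.0, 0.0, 0.0])  # z centered; xy start at 0
    origin = np.array([-(nz - 1) / 2.0 * voxel_size, 0.0, 0.0])

    # physical coordinate grids (Å)
    zc = (np.arange(nz) * voxel_size + origin[0])[:, None, None]
    yc = (np.arange(ny) * voxel_size)[None, :, None]
    xc = (np.arange(nx) * voxel_size)[None, None, :]

    grid = np.zeros((nz, ny, nx))

    # membrane: zigzag slab
    zm = crystal.membrane_height(xc[0], yc[0])  # (ny, nx)
    half = phantom.membrane_thickness / 2.0
    dz = zc - zm[None, :, :]
    grid += phantom.lipid_density * (
        _sstep(dz + half, phantom.edge_sigma) * _sstep(half - dz, phantom.edge_sigma)
    )

    # particle placements
    motif = _motif(crystal)
    b_hat = bv / np.linalg.norm(bv)
    r_pad = phantom.bounding_radius()
    span_x, span_y = nx * voxel_size, ny * voxel_size
    m_lo = -2
    m_hi = int(np.ceil(span_x / min(abs(av[0]), crystal.a))) + 2
    n_hi = int(np.ceil(span_y / abs(bv[1]))) + 2

    records: list[dict] = []
    placements: list[tuple[np.ndarray, np.ndarray]] = []
    pid = 0
    for m in range(m_lo, m_hi + 1):
        for n in range(m_lo, n_hi + 1):
            for item in motif:
                frac = item["frac"]
                xy = (m + frac[0]) * av + (n + frac[1]) * bv
                if item["partner_shift"]:
                    xy = xy + crystal.cross_face_offset * b_hat
                xy = xy + rng.normal(0.0, crystal.jitter_sigma_xy, size=2)
                r_mat = _random_small_rotation(
                    rng, crystal.jitter_sigma_angle
                ) @ item["t"].matrix
                z_mem = float(crystal.membrane_height(xy[0], xy[1]))
                center = (
                    np.array([xy[0], xy[1], z_mem])
                    + r_mat @ np.array([0.0, 0.0, phantom.center_height])
                )
                # skip particles whose density cannot touch the box
                if (center[0] < -r_pad or center[0] > span_x + r_pad
                        or center[1] < -r_pad or center[1] > span_y + r_pad):
                    continue
                placements.append((center, r_mat))
                _render_particle(grid, phantom, center, r_mat, voxel_size, origin)

                pos_vox = np.array([
                    center[0] / voxel_size,
                    center[1] / voxel_size,
                    (center[2] - origin[0]) / voxel_size,
                ])  # (x, y, z) voxels
                margin_vox = table_margin / voxel_size
                if (margin_vox <= pos_vox[0] < nx - 1 - margin_vox
                        and margin_vox <= pos_vox[1] < ny - 1 - margin_vox
                        and 0 <= pos_vox[2] < nz):
                    t = RigidTransform.from_matrix(r_mat)
                    records.append({
                        "id": pid,
                        "x": pos_vox[0], "y": pos_vox[1], "z": pos_vox[2],
                        "rot": t.rot, "tilt": t.tilt, "psi": t.psi,
                        "face": item["face"], "halfset": "",
                        "score": 0.0,
                    })
                    pid += 1

    n_overlap = _count_overlaps(placements, overlap_tolerance)
    if n_overlap:
        warnings.warn(
            f"{n_overlap} particle placements closer than {overlap_tolerance} Å",
            PackingWarning,
        )

    table = ParticleTable(
        pd.DataFrame(records, columns=COLUMNS)
    ).assign_halfsets(seed=int(rng.integers(2**31 - 1)))
    vol = DensityVolume(grid.astype(np.float32), voxel_size, origin=origin)
    return vol, table


def _count_overlaps(placements, tolerance: float) -> int:
    if len(placements) < 2:
        return 0
    from scipy.spatial import cKDTree

    pts = np.array([p[0] for p in placements])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(tolerance)
    return len(pairs)


def _render_particle(grid, phantom, center, r_mat, voxel_size, origin) -> None:
    """Additively render one particle into the global grid (local subbox)."""
    nz, ny, nx = grid.shape
    r_pad = phantom.bounding_radius()
    # voxel-index center (z, y, x)
    iz = (center[2] - origin[0]) / voxel_size
    iy = center[1] / voxel_size
    ix = center[0] / voxel_size
    w = int(np.ceil(r_pad / voxel_size)) + 1
    z0, z1 = max(0, int(iz) - w), min(nz, int(iz) + w + 1)
    y0, y1 = max(0, int(iy) - w), min(ny, int(iy) + w + 1)
    x0, x1 = max(0, int(ix) - w), min(nx, int(ix) + w + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zc = (np.arange(z0, z1) * voxel_size + origin[0] - center[2])[:, None, None]
    yc = (np.arange(y0, y1) * voxel_size - center[1])[None, :, None]
    xc = (np.arange(x0, x1) * voxel_size - center[0])[None, None, :]
    # rotate global offsets into the phantom frame: p_local = R^T p
    rt = r_mat.T
    lx = rt[0, 0] * xc + rt[0, 1] * yc + rt[0, 2] * zc
    ly = rt[1, 0] * xc + rt[1, 1] * yc + rt[1, 2] * zc
    lz = rt[2, 0] * xc + rt[2, 1] * yc + rt[2, 2] * zc + phantom.center_height
    grid[z0:z1, y0:y1, x0:x1] += _protein_density(phantom, lx, ly, lz)


# ---------------------------------------------------------------------------
# Tilt series and reconstruction
# ---------------------------------------------------------------------------

def default_tilt_angles(
    tilt_min: float = -60.0, tilt_max: float = 60.0, step: float = 1.5
) -> np.ndarray:
    return np.arange(tilt_min, tilt_max + step / 2.0, step)


def simulate_tilt_series(
    volume: DensityVolume,
    angles: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TiltSeries:
    """Project a volume into a single-axis tilt series about the y axis.

    Each image is the line integral along z of the volume rotated by the
    tilt angle (real-space rotation + summation), plus white Gaussian
    noise of the given standard deviation.
    """
    if angles is None:
        angles = default_tilt_angles()
    angles = np.asarray(angles, dtype=float)
    if np.any(np.abs(angles) >= 90.0):
        raise ValueError("tilt angles must lie within (-90°, 90°)")
    imgs = np.empty((len(angles), volume.shape[1], volume.shape[2]), dtype=np.float32)
    for i, ang in enumerate(angles):
        if abs(ang) < 1e-12:
            rot = volume.grid
        else:
            rot = _ndrotate(
                volume.grid, ang, axes=(0, 2), reshape=False, order=1,
                mode="constant", cval=0.0, prefilter=False,
            )
        imgs[i] = rot.sum(axis=0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        imgs = imgs + rng.normal(0.0, noise_sigma, size=imgs.shape).astype(np.float32)
    return TiltSeries(imgs, angles, volume.voxel_size, noise_sigma, seed)


def _ramp_filter(images: np.ndarray, min_weight: float = 0.0) -> np.ndarray:
    """R-weight (ramp filter) each image along the x axis.

    ``min_weight`` floors the radial weight (cycles/pixel) so that slowly
    varying structure — e.g. an extended bilayer seen nearly face-on — is
    not annihilated, mirroring the low-frequency plateau of the radial
    filters used by standard tomography packages.
    """
    n = images.shape[-1]
    freqs = np.fft.rfftfreq(n)
    weight = np.maximum(np.abs(freqs), min_weight)
    f = np.fft.rfft(images, axis=-1)
    return np.fft.irfft(f * weight, n=n, axis=-1).astype(np.float32)


def reconstruct_wbp(
    series: TiltSeries,
    z_size: int | None = None,
    origin_z_centered: bool = True,
    min_filter_weight: float = 0.0,
) -> DensityVolume:
    """Ramp-weighted back-projection of a single-axis tilt series (axis y)."""
    n_ang, ny, nx = series.images.shape
    nz = z_size if z_size is not None else nx
    filtered = _ramp_filter(series.images.astype(np.float64), min_filter_weight)
    zc = np.arange(nz) - (nz - 1) / 2.0
    xc = np.arange(nx) - (nx - 1) / 2.0
    out = np.zeros((nz, ny, nx), dtype=np.float64)
    for ang, img in zip(series.angles, filtered):
        th = np.radians(ang)
        # sample position on the detector for every (z, x) output voxel
        xp = xc[None, :] * np.cos(th) + zc[:, None] * np.sin(th) + (nx - 1) / 2.0
        i0 = np.floor(xp).astype(int)
        w = xp - i0
        valid0 = (i0 >= 0) & (i0 <= nx - 1)
        valid1 = (i0 + 1 >= 0) & (i0 + 1 <= nx - 1)
        j0 = np.clip(i0, 0, nx - 1)
        j1 = np.clip(i0 + 1, 0, nx - 1)
        # gather: img is (ny, nx); broadcast over y
        g0 = img[:, j0.ravel()].reshape(ny, nz, nx)
        g1 = img[:, j1.ravel()].reshape(ny, nz, nx)
        contrib = (g0 * ((1.0 - w) * valid0).ravel().reshape(1, nz, nx)
                   + g1 * (w * valid1).ravel().reshape(1, nz, nx))
        out += np.transpose(contrib, (1, 0, 2))
    dtheta = np.radians(series.angles[-1] - series.angles[0]) / max(n_ang - 1, 1)
    out *= dtheta  # FBP normalization: sum over sampled angles times step
    origin = np.array([-(nz - 1) / 2.0 * series.pixel_size, 0.0, 0.0]) \
        if origin_z_centered else np.zeros(3)
    return DensityVolume(out.astype(np.float32), series.pixel_size, origin=origin)


def wedge_mask(shape: tuple[int, int, int], theta_max: float = 60.0) -> np.ndarray:
    """Binary Fourier-domain missing-wedge mask (tilt axis y, unshifted layout).

    A voxel is included iff |k_z| <= tan(theta_max) * |k_x|; Hermitian
    (Friedel) symmetric by construction.
    """
    if not (0.0 < theta_max <= 90.0):
        raise ValueError("theta_max must be in (0°, 90°]")
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    if theta_max >= 90.0 - 1e-9:
        return np.ones(shape, dtype=np.float32)
    t = np.tan(np.radians(theta_max))
    mask = (np.abs(kz) <= t * np.abs(kx) + 1e-12)
    return np.broadcast_to(mask, shape).astype(np.float32).copy()
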