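"""2D electron crystallography of tomographic z-slices.

The hybrid step of the workflow: z-slices of the tomogram are summed into
projection images and processed crystallographically — lattice detection
from the power spectrum, single-round unbending of smooth lattice
distortions, structure-factor extraction at the reciprocal nodes within a
resolution limit, Fourier synthesis of p1 projection maps, and a p2
phase-residual test with origin refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import DensityVolume

__all__ = [
    "UnitCell2D",
    "ProjectionImage",
    "StructureFactorSet",
    "LatticeNotFoundError",
    "slice_projections",
    "detect_lattice",
    "unbend_image",
    "extract_structure_factors",
    "synthesize_projection_map",
    "plane_group_residual",
    "reflection_quality",
]


class LatticeNotFoundError(ValueError):
    pass


@dataclass
class UnitCell2D:
    a: float
    b: float
    gamma: float   # degrees

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("cell lengths must be positive")
        if not (0.0 < self.gamma < 180.0):
            raise ValueError("gamma must be in (0, 180) degrees")

    def real_vectors(self) -> np.ndarray:
        """Rows are the real-space cell vectors (x, y) in Å."""
        g = np.radians(self.gamma)
        return np.array([
            [self.a, 0.0],
            [self.b * np.cos(g), self.b * np.sin(g)],
        ])

    def reciprocal_vectors(self) -> np.ndarray:
        """Rows are a*, b* in cycles/Å; satisfies a_i . b*_j = delta_ij."""
        return np.linalg.inv(self.real_vectors()).T

    @classmethod
    def from_reciprocal(cls, recip: np.ndarray) -> "UnitCell2D":
        real = np.linalg.inv(np.asarray(recip, dtype=float)).T
        a_vec, b_vec = real
        a = float(np.linalg.norm(a_vec))
        b = float(np.linalg.norm(b_vec))
        cosg = float(a_vec @ b_vec / (a * b))
        gamma = float(np.degrees(np.arccos(np.clip(cosg, -1.0, 1.0))))
        return cls(a, b, gamma)

    def d_spacing(self, h: int, k: int) -> float:
        q = h * self.reciprocal_vectors()[0] + k * self.reciprocal_vectors()[1]
        return float(1.0 / np.linalg.norm(q))


@dataclass
class ProjectionImage:
    data: np.ndarray
    pixel_size: float
    z_range: tuple[float, float] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.data.ndim != 2:
            raise ValueError("projection image must be 2D")


@dataclass
class StructureFactorSet:
    entries: pd.DataFrame    # columns h, k, amplitude, phase, background, snr
    cell: UnitCell2D
    resolution_limit: float

    COLUMNS = ["h", "k", "amplitude", "phase", "background", "snr"]

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"missing structure-factor columns: {missing}")
        if self.entries.duplicated(subset=["h", "k"]).any():
            raise ValueError("duplicate (h, k) entries")

    def __len__(self):
        return len(self.entries)

    def significant(self, snr_min: float = 2.0) -> pd.DataFrame:
        return self.entries[self.entries["snr"] >= snr_min]

    def write_tsv(self, path) -> None:
        df = self.entries.copy()
        for col in ("amplitude", "phase", "background", "snr"):
            df[col] = df[col].map(lambda v: f"{v:.6f}")
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Slicing
# ---------------------------------------------------------------------------

def slice_projections(
    tomogram: DensityVolume,
    z_min: float,
    z_max: float,
    per_slice: bool = False,
):
    """Project a z-range (Å, in the volume's physical frame) of the tomogram.

    ``per_slice=True`` returns one :class:`ProjectionImage` per voxel
    layer — count = round((z_max - z_min)/voxel_size); otherwise their sum
    as a single image.
    """
    if z_max <= z_min:
        raise ValueError("empty z range")
    vs = tomogram.voxel_size
    count = int(round((z_max - z_min) / vs))
    if count < 1:
        raise ValueError("z range narrower than one voxel layer")
    start = int(round((z_min - tomogram.origin[0]) / vs))
    start = max(start, 0)
    stop = min(start + count, tomogram.shape[0])
    if stop <= start:
        raise ValueError("z range outside the volume")
    layers = tomogram.grid[start:stop]
    z0 = tomogram.origin[0] + start * vs
    if per_slice:
        return [
            ProjectionImage(layers[i], vs, (z0 + i * vs, z0 + (i + 1) * vs))
            for i in range(layers.shape[0])
        ]
    return ProjectionImage(layers.sum(axis=0), vs, (z0, z0 + layers.shape[0] * vs))


# ---------------------------------------------------------------------------
# Lattice detection
# ---------------------------------------------------------------------------

def _power_spectrum(image: ProjectionImage, pad_factor: int):
    n_y, n_x = image.data.shape
    win = np.outer(np.hanning(n_y), np.hanning(n_x))
    data = (image.data - image.data.mean()) * win
    f = np.fft.fftshift(np.fft.fft2(data, s=(n_y * pad_factor, n_x * pad_factor)))
    return np.abs(f) ** 2


def _find_peaks(power, pixel_size, shape, pad_factor,
                min_spacing, max_spacing, significance):
    ny, nx = power.shape
    cy, cx = ny // 2, nx // 2
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_size / pad_factor * pad_factor))
    # frequency per padded pixel (cycles/Å)
    dq_y = 1.0 / (ny * pixel_size / pad_factor) / pad_factor
    dq_x = 1.0 / (nx * pixel_size / pad_factor) / pad_factor
    yy, xx = np.mgrid[0:ny, 0:nx]
    qy = (yy - cy) * dq_y
    qx = (xx - cx) * dq_x
    qr = np.hypot(qx, qy)
    band = (qr >= 1.0 / max_spacing) & (qr <= 1.0 / min_spacing)
    if not np.any(band):
        return []
    # radially local significance: compare to the median level in the band
    bg = np.median(power[band])
    mad = np.median(np.abs(power[band] - bg)) + 1e-30
    thresh = bg + significance * 1.4826 * mad
    local_max = power == ndimage.maximum_filter(power, size=2 * pad_factor + 1)
    cand = np.where(band & local_max & (power > thresh))
    peaks = []
    for y, x in zip(*cand):
        # sub-pixel quadratic refinement on the padded grid
        dy = dx = 0.0
        if 0 < y < ny - 1:
            d = power[y - 1, x] - 2 * power[y, x] + power[y + 1, x]
            if abs(d) > 1e-30:
                dy = np.clip(0.5 * (power[y - 1, x] - power[y + 1, x]) / d, -1, 1)
        if 0 < x < nx - 1:
            d = power[y, x - 1] - 2 * power[y, x] + power[y, x + 1]
            if abs(d) > 1e-30:
                dx = np.clip(0.5 * (power[y, x - 1] - power[y, x + 1]) / d, -1, 1)
        q = np.array([(x + dx - cx) * dq_x, (y + dy - cy) * dq_y])
        peaks.append((q, float(power[y, x])))
    # keep one of each Friedel pair (qx > 0 or (qx==0, qy>0))
    uniq = []
    for q, w in peaks:
        if q[0] > 1e-12 or (abs(q[0]) <= 1e-12 and q[1] > 0):
            uniq.append((q, w))
    uniq.sort(key=lambda t: np.linalg.norm(t[0]))
    return uniq


def _reduce_basis(vectors: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Two shortest independent vectors of the lattice generated by input."""
    best = None
    rng = range(-2, 3)
    combos = []
    for m in rng:
        for n in rng:
            for p in rng:
                coeffs = np.array([m, n, p][: len(vectors)])
                if not np.any(coeffs):
                    continue
                v = sum(c * vec for c, vec in zip(coeffs, vectors))
                combos.append(v)
    combos.sort(key=np.linalg.norm)
    v1 = combos[0]
    for v2 in combos[1:]:
        cross = abs(v1[0] * v2[1] - v1[1] * v2[0])
        if cross > 0.15 * np.linalg.norm(v1) * np.linalg.norm(v2):
            return v1, v2
    raise LatticeNotFoundError("could not reduce lattice basis")


def detect_lattice(
    image: ProjectionImage,
    min_spacing: float = 40.0,
    max_spacing: float = 400.0,
    pad_factor: int = 4,
    significance: float = 8.0,
) -> tuple[np.ndarray, UnitCell2D]:
    """Reciprocal basis and unit cell from power-spectrum peaks.

    Picks significant peaks in the resolution band, chooses the two
    shortest independent vectors (tie-break toward the smaller angle with
    +x via the sorted search order), verifies every strong peak indexes
    integrally — extending and re-reducing the basis when a peak reveals
    a finer sublattice (e.g. a centred arrangement of a strong motif) —
    and finally refines the basis by weighted least squares over all
    indexed peaks.  Returns (2x2 reciprocal matrix [a*; b*] in cycles/Å,
    cell), with the cell reported as a >= b and gamma in [90°, 180°).
    """
    power = _power_spectrum(image, pad_factor)
    peaks = _find_peaks(power, image.pixel_size, image.data.shape, pad_factor,
                        min_spacing, max_spacing, significance)
    if len(peaks) < 2:
        raise LatticeNotFoundError(
            f"only {len(peaks)} significant diffraction peaks found"
        )
    qs = [p[0] for p in peaks]
    ws = np.array([p[1] for p in peaks])
    try:
        v1, v2 = _reduce_basis(qs[:2])
    except LatticeNotFoundError:
        # first two peaks collinear: scan for an independent partner
        v1 = qs[0]
        v2 = None
        for q in qs[1:]:
            cross = abs(v1[0] * q[1] - v1[1] * q[0])
            if cross > 0.15 * np.linalg.norm(v1) * np.linalg.norm(q):
                v2 = q
                break
        if v2 is None:
            raise LatticeNotFoundError("all significant peaks are collinear")

    strong = ws >= np.median(ws)
    for _ in range(5):
        m = np.stack([v1, v2])
        fresh = None
        for q, is_strong in zip(qs, strong):
            if not is_strong:
                continue
            idx = np.linalg.solve(m.T, q)
            if np.max(np.abs(idx - np.rint(idx))) > 0.25:
                fresh = q
                break
        if fresh is None:
            break
        v1, v2 = _reduce_basis([v1, v2, fresh])

    # weighted least-squares refinement over integrally indexing peaks
    m = np.stack([v1, v2])
    rows, targets, weights = [], [], []
    for q, w in zip(qs, ws):
        idx = np.linalg.solve(m.T, q)
        if np.max(np.abs(idx - np.rint(idx))) <= 0.2:
            rows.append(np.rint(idx))
            targets.append(q)
            weights.append(np.sqrt(w))
    if len(rows) >= 3:
        a_mat = np.array(rows) * np.array(weights)[:, None]
        b_mat = np.array(targets) * np.array(weights)[:, None]
        m, *_ = np.linalg.lstsq(a_mat, b_mat, rcond=None)
        m = m  # rows are a*, b*

    cell = UnitCell2D.from_reciprocal(m)
    m, cell = _canonicalize(m, cell)
    return m, cell


def _canonicalize(m: np.ndarray, cell: UnitCell2D) -> tuple[np.ndarray, UnitCell2D]:
    """Report a >= b and gamma obtuse (in [90, 180))."""
    real = np.linalg.inv(m).T
    a_vec, b_vec = real
    if np.linalg.norm(a_vec) < np.linalg.norm(b_vec):
        a_vec, b_vec = b_vec, a_vec
    cosg = a_vec @ b_vec / (np.linalg.norm(a_vec) * np.linalg.norm(b_vec))
    if cosg > 0:
        b_vec = -b_vec
    real = np.stack([a_vec, b_vec])
    m_new = np.linalg.inv(real).T
    return m_new, UnitCell2D.from_reciprocal(m_new)


# ---------------------------------------------------------------------------
# Unbending
# ---------------------------------------------------------------------------

def unbend_image(
    image: ProjectionImage,
    lattice: np.ndarray,
    reference_radius: float = 3.0,
    search_radius: float | None = None,
    window_factor: float = 0.45,
) -> tuple[ProjectionImage, np.ndarray, dict]:
    """Single-round lattice unbending.

    A reference is built by Fourier-filtering the image around every
    reciprocal node (radius ``reference_radius`` in Fourier pixels); its
    cross-correlation with the image is peak-searched around every ideal
    lattice node, the displacements are interpolated into a smooth field,
    and the image is resampled against it.  Skipped (with a warning and a
    zero field) when fewer than 4 correlation peaks are found.
    """
    data = image.data.astype(np.float64)
    ny, nx = data.shape
    real = np.linalg.inv(lattice).T / image.pixel_size  # lattice vectors in px
    if search_radius is None:
        search_radius = 0.3 * min(np.linalg.norm(real[0]), np.linalg.norm(real[1]))

    f = np.fft.fft2(data - data.mean())
    mask = _lattice_node_mask((ny, nx), lattice, image.pixel_size,
                              reference_radius)
    ref = np.fft.ifft2(f * mask).real
    # reference patch: the filtered image under a one-cell Gaussian window
    # at the center; linear correlation with local energy normalization
    sigma = max(np.linalg.norm(real[0]), np.linalg.norm(real[1])) * window_factor
    yy0, xx0 = np.mgrid[0:ny, 0:nx]
    win = np.exp(-(((yy0 - ny / 2.0) ** 2 + (xx0 - nx / 2.0) ** 2)
                   / (2.0 * sigma**2)))
    patch = ref * win
    from scipy.signal import fftconvolve

    d0 = data - data.mean()
    cc = fftconvolve(d0, patch[::-1, ::-1], mode="same")
    local_energy = fftconvolve(d0**2, win[::-1, ::-1], mode="same")
    norm = np.sqrt(np.clip(local_energy, 0, None) * (patch**2).sum())
    cc = cc / (norm + 1e-9 * norm.max())

    # ideal nodes inside the image; a peak counts only when its normalized
    # correlation is significant, so noise cannot fake a lattice
    disp_pts, disp_vec = [], []
    lim = int(np.ceil(max(ny, nx) / min(np.linalg.norm(real[0]),
                                        np.linalg.norm(real[1])))) + 1
    origin = np.array([ny / 2.0, nx / 2.0])
    min_peak_cc = 0.3
    for mi in range(-lim, lim + 1):
        for ni in range(-lim, lim + 1):
            node = origin + mi * real[0][::-1] + ni * real[1][::-1]  # (y, x)
            if not (0 <= node[0] < ny and 0 <= node[1] < nx):
                continue
            peak = _local_peak(cc, node, search_radius)
            if peak is None:
                continue
            if cc[int(round(peak[0])) % ny, int(round(peak[1])) % nx] < min_peak_cc:
                continue
            disp_pts.append(node)
            disp_vec.append(peak - node)
    report = {"n_peaks": len(disp_pts)}
    if len(disp_pts) < 4:
        warnings.warn("unbending skipped: fewer than 4 lattice correlation peaks")
        return image, np.zeros((ny, nx, 2)), report

    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

    pts = np.array(disp_pts)
    vec = np.array(disp_vec)
    # the affine component of the measured displacements is a lattice
    # (basis/origin) correction, not a distortion; remove it so only the
    # smooth non-linear field is resampled
    a_design = np.column_stack([pts - pts.mean(axis=0), np.ones(len(pts))])
    for c in range(2):
        coef, *_ = np.linalg.lstsq(a_design, vec[:, c], rcond=None)
        vec[:, c] = vec[:, c] - a_design @ coef
    yy, xx = np.mgrid[0:ny, 0:nx]
    field = np.zeros((ny, nx, 2))
    for c in range(2):
        lin = LinearNDInterpolator(pts, vec[:, c])
        near = NearestNDInterpolator(pts, vec[:, c])
        vals = lin(yy, xx)
        nanmask = np.isnan(vals)
        if np.any(nanmask):
            vals[nanmask] = near(yy[nanmask], xx[nanmask])
        field[:, :, c] = vals
    corrected = ndimage.map_coordinates(
        data, [yy + field[:, :, 0], xx + field[:, :, 1]], order=1, mode="nearest"
    )
    report["rms_displacement_px"] = float(np.sqrt((vec**2).sum(axis=1).mean()))
    out = ProjectionImage(corrected, image.pixel_size, image.z_range)
    # keep the input when resampling does not sharpen the lattice: the
    # correction must improve the diffraction or be a no-op
    try:
        q_in = reflection_quality(image, lattice)
        q_out = reflection_quality(out, lattice)
        report["quality_before"] = q_in
        report["quality_after"] = q_out
        if q_out < q_in:
            report["applied"] = False
            return image, field, report
    except ValueError:
        pass
    report["applied"] = True
    return out, field, report


def _lattice_node_mask(shape, lattice, pixel_size, radius):
    ny, nx = shape
    qy = np.fft.fftfreq(ny, d=pixel_size)[:, None]
    qx = np.fft.fftfreq(nx, d=pixel_size)[None, :]
    # fractional indices of each Fourier pixel
    m = np.stack([lattice[0], lattice[1]])
    inv = np.linalg.inv(m.T)
    hf = inv[0, 0] * qx + inv[0, 1] * qy
    kf = inv[1, 0] * qx + inv[1, 1] * qy
    dh = hf - np.rint(hf)
    dk = kf - np.rint(kf)
    # distance from nearest node in Fourier pixels
    dq = (dh[..., None] * m[0] + dk[..., None] * m[1])
    dist_px = np.hypot(dq[..., 0] * nx * pixel_size, dq[..., 1] * ny * pixel_size)
    mask = dist_px <= radius
    mask[0, 0] = False  # keep DC out of the reference
    return mask.astype(float)


def _norm_xcorr(a, b):
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cc = np.fft.ifft2(fa * np.conj(fb)).real
    cc = np.fft.fftshift(cc)
    denom = np.sqrt((a**2).sum() * (b**2).sum()) + 1e-30
    return cc / denom


def _local_peak(cc, node, radius):
    ny, nx = cc.shape
    y0, x0 = int(round(node[0])), int(round(node[1]))
    r = int(np.ceil(radius))
    ys = slice(max(0, y0 - r), min(ny, y0 + r + 1))
    xs = slice(max(0, x0 - r), min(nx, x0 + r + 1))
    win = cc[ys, xs]
    if win.size == 0:
        return None
    iy, ix = np.unravel_index(np.argmax(win), win.shape)
    py, px = ys.start + iy, xs.start + ix
    if np.hypot(py - node[0], px - node[1]) > radius:
        return None
    # sub-pixel
    dy = dx = 0.0
    if 0 < py < ny - 1:
        d = cc[py - 1, px] - 2 * cc[py, px] + cc[py + 1, px]
        if abs(d) > 1e-30:
            dy = np.clip(0.5 * (cc[py - 1, px] - cc[py + 1, px]) / d, -1, 1)
    if 0 < px < nx - 1:
        d = cc[py, px - 1] - 2 * cc[py, px] + cc[py, px + 1]
        if abs(d) > 1e-30:
            dx = np.clip(0.5 * (cc[py, px - 1] - cc[py, px + 1]) / d, -1, 1)
    return np.array([py + dy, px + dx])


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

def extract_structure_factors(
    image: ProjectionImage,
    lattice: np.ndarray,
    resolution_limit: float = 30.0,
    pad_factor: int = 4,
    core_radius: int = 1,
    annulus: tuple[float, float] = (3.0, 5.0),
) -> StructureFactorSet:
    """Amplitudes and phases at the reciprocal nodes within the limit.

    Phases are referred to the image center.  The background is the mean
    amplitude in an off-peak annulus (radii in unpadded Fourier pixels,
    excluding the peak core); snr = amplitude/background.
    """
    data = image.data.astype(np.float64)
    ny, nx = data.shape
    f = np.fft.fft2(data - data.mean(), s=(ny * pad_factor, nx * pad_factor))
    f = np.fft.fftshift(f)
    npy, npx = f.shape
    cy, cx = npy // 2, npx // 2
    dq_y = 1.0 / (ny * image.pixel_size) / pad_factor
    dq_x = 1.0 / (nx * image.pixel_size) / pad_factor
    cell = UnitCell2D.from_reciprocal(lattice)
    hmax = int(np.ceil(cell.a / resolution_limit)) + 1
    kmax = int(np.ceil(cell.b / resolution_limit)) + 1

    # exact DTFT sampling at each node (phases referred to image center);
    # the padded spectrum serves only for the background annulus
    d0 = data - data.mean()
    x_A = (np.arange(nx) - nx / 2.0) * image.pixel_size
    y_A = (np.arange(ny) - ny / 2.0) * image.pixel_size

    amp_map = np.abs(f)
    entries = []
    for h in range(0, hmax + 1):
        krange = range(-kmax, kmax + 1) if h > 0 else range(1, kmax + 1)
        for k in krange:
            q = h * lattice[0] + k * lattice[1]
            if np.linalg.norm(q) > 1.0 / resolution_limit:
                continue
            px = q[0] / dq_x + cx
            py = q[1] / dq_y + cy
            if not (1 <= px < npx - 2 and 1 <= py < npy - 2):
                continue
            wave_x = np.exp(-2j * np.pi * q[0] * x_A)
            wave_y = np.exp(-2j * np.pi * q[1] * y_A)
            val = wave_y @ d0 @ wave_x
            amp, phase = float(np.abs(val)), float(np.angle(val))
            bg = _annulus_background(amp_map, py, px, pad_factor, core_radius,
                                     annulus)
            entries.append({
                "h": h, "k": k,
                "amplitude": amp,
                "phase": float(np.degrees(phase) % 360.0),
                "background": bg,
                "snr": amp / bg if bg > 0 else np.inf,
            })
    df = pd.DataFrame(entries, columns=StructureFactorSet.COLUMNS)
    return StructureFactorSet(df, cell, resolution_limit)


def _sample_complex(f, py, px):
    """Bilinear interpolation of the complex spectrum at (py, px)."""
    y0, x0 = int(np.floor(py)), int(np.floor(px))
    wy, wx = py - y0, px - x0
    val = (f[y0, x0] * (1 - wy) * (1 - wx) + f[y0, x0 + 1] * (1 - wy) * wx
           + f[y0 + 1, x0] * wy * (1 - wx) + f[y0 + 1, x0 + 1] * wy * wx)
    return float(np.abs(val)), float(np.angle(val))


def _annulus_background(amp_map, py, px, pad_factor, core_radius, annulus):
    npy, npx = amp_map.shape
    r_in = annulus[0] * pad_factor
    r_out = annulus[1] * pad_factor
    r = int(np.ceil(r_out))
    y0, x0 = int(round(py)), int(round(px))
    ys = slice(max(0, y0 - r), min(npy, y0 + r + 1))
    xs = slice(max(0, x0 - r), min(npx, x0 + r + 1))
    yy, xx = np.mgrid[ys, xs]
    dist = np.hypot(yy - py, xx - px)
    core = core_radius * pad_factor
    sel = (dist >= max(r_in, core + pad_factor)) & (dist <= r_out)
    if not np.any(sel):
        return float(np.median(amp_map))
    return float(amp_map[ys, xs][sel].mean())


def reflection_quality(image: ProjectionImage, lattice: np.ndarray,
                       hk: tuple[int, int] = (1, 0)) -> float:
    """Peak/background amplitude ratio of one reflection.

    A Hann window suppresses the finite-field sinc skirts so the
    background annulus reflects diffuse (disorder) scattering.
    """
    ny, nx = image.data.shape
    win = np.outer(np.hanning(ny), np.hanning(nx))
    windowed = ProjectionImage(image.data * win, image.pixel_size)
    sf = extract_structure_factors(windowed, lattice, resolution_limit=1.0
                                   / (np.linalg.norm(
                                       hk[0] * lattice[0] + hk[1] * lattice[1]
                                   ) + 1e-12))
    row = sf.entries[(sf.entries.h == hk[0]) & (sf.entries.k == hk[1])]
    if len(row) == 0:
        raise ValueError(f"reflection {hk} not extractable")
    return float(row.iloc[0]["snr"])


# ---------------------------------------------------------------------------
# Map synthesis and symmetry
# ---------------------------------------------------------------------------

def synthesize_projection_map(
    sfset: StructureFactorSet,
    cell: UnitCell2D | None = None,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float | None = None,
    lattice: np.ndarray | None = None,
) -> ProjectionImage:
    """Real-valued p1 Fourier synthesis over the stored reflections.

    map(r) = sum 2 A cos(2π (h x* + k y*) . r + phase), including Friedel
    mates implicitly; the origin is the image center, matching the phase
    convention of :func:`extract_structure_factors`.  Pass the detected
    reciprocal ``lattice`` matrix to reconstruct in the source image
    frame; otherwise the cell's standard orientation (a along +x) is used.
    """
    if len(sfset) == 0:
        raise ValueError("empty structure-factor set")
    cell = cell or sfset.cell
    ny, nx = shape
    if pixel_size is None:
        pixel_size = 2.0 * max(cell.a, cell.b) / min(shape)
    recip = cell.reciprocal_vectors() if lattice is None else np.asarray(lattice)
    yy, xx = np.mgrid[0:ny, 0:nx]
    x = (xx - nx / 2.0) * pixel_size
    y = (yy - ny / 2.0) * pixel_size
    out = np.zeros((ny, nx))
    for _, row in sfset.entries.iterrows():
        q = row["h"] * recip[0] + row["k"] * recip[1]
        arg = 2.0 * np.pi * (q[0] * x + q[1] * y) + np.radians(row["phase"])
        out += 2.0 * row["amplitude"] * np.cos(arg)
    return ProjectionImage(out, pixel_size)


def plane_group_residual(
    sfset: StructureFactorSet,
    group: str = "p2",
    snr_min: float = 2.0,
    grid: int = 60,
) -> tuple[float, tuple[float, float]]:
    """Phase residual against a plane group after origin refinement.

    p1 is 0° by convention.  For p2, phases at the correct origin must be
    0° or 180°; the origin (tx, ty in cell fractions) is grid-searched
    and locally refined to minimise the snr-weighted mean deviation from
    centrosymmetric phases.
    """
    if group == "p1":
        return 0.0, (0.0, 0.0)
    if group != "p2":
        raise ValueError("only p1 and p2 are supported")
    sig = sfset.significant(snr_min)
    if len(sig) < 3:
        raise ValueError(
            f"only {len(sig)} reflections with snr >= {snr_min}; need >= 3"
        )
    h = sig["h"].to_numpy()
    k = sig["k"].to_numpy()
    phase = np.radians(sig["phase"].to_numpy())
    w = sig["snr"].to_numpy()

    def residual(t):
        tx, ty = t
        ph = np.degrees(phase - 2.0 * np.pi * (h * tx + k * ty))
        dev = np.abs((ph + 90.0) % 180.0 - 90.0)
        return float((w * dev).sum() / w.sum())

    ts = np.linspace(0.0, 1.0, grid, endpoint=False)
    best = min(((residual((tx, ty)), (tx, ty)) for tx in ts for ty in ts),
               key=lambda p: p[0])
    from scipy.optimize import minimize

    res = minimize(residual, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8})
    t = tuple(float(v % 1.0) for v in res.x)
    return float(res.fun), t
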