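"""Resolution estimation and overfitting control.

Implements the gold-standard validation toolkit: Fourier shell
correlation between independently refined half-maps with the 0.5
threshold criterion, high-resolution phase randomization to expose
alignment overfitting, and the Fermi lowpass used to filter final
averages for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .volume import DensityVolume

__all__ = [
    "FSCCurve",
    "ResolutionEstimate",
    "compute_fsc",
    "resolution_at_threshold",
    "phase_randomize_beyond",
    "fermi_filter",
    "overfitting_check",
    "overfit_verdict",
    "OverfitResult",
]


@dataclass
class FSCCurve:
    shell_frequencies: np.ndarray   # 1/Å, strictly increasing
    correlations: np.ndarray        # in [-1, 1]; NaN for empty shells
    shell_voxel_counts: np.ndarray

    def __post_init__(self):
        self.shell_frequencies = np.asarray(self.shell_frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        self.shell_voxel_counts = np.asarray(self.shell_voxel_counts, dtype=int)
        if np.any(np.diff(self.shell_frequencies) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")

    def noise_threshold(self) -> np.ndarray:
        """Significance level 3/sqrt(n) per shell."""
        with np.errstate(divide="ignore"):
            return 3.0 / np.sqrt(np.maximum(self.shell_voxel_counts, 1))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frequency_invA\tfsc\tn_voxels\n")
            for f, c, n in zip(self.shell_frequencies, self.correlations,
                               self.shell_voxel_counts):
                fh.write(f"{f:.8f}\t{c if np.isfinite(c) else 'nan'}\t{n}\n")

    def plot(self, path, extra: "FSCCurve | None" = None,
             labels=("half-maps", "phase-randomized")) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.shell_frequencies, self.correlations, "k-", label=labels[0])
        if extra is not None:
            ax.plot(extra.shell_frequencies, extra.correlations, "-",
                    color="grey", label=labels[1])
        ax.axhline(0.5, ls=":", color="crimson", lw=0.8)
        ax.set_xlabel("spatial frequency (1/Å)")
        ax.set_ylabel("FSC")
        ax.set_ylim(-0.1, 1.05)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


class ResolutionEstimate(NamedTuple):
    resolution_A: float
    crossed: bool   # False if the curve never drops below the threshold


def _shell_indices(shape) -> tuple[np.ndarray, int]:
    axes = [np.fft.fftfreq(n) * n for n in shape]  # index units
    kz = axes[0][:, None, None]
    ky = axes[1][None, :, None]
    kx = axes[2][None, None, :]
    r = np.sqrt(kz**2 + ky**2 + kx**2)
    shells = np.rint(r).astype(int)
    n_shell = min(shape) // 2 + 1
    return shells, n_shell


def compute_fsc(map_a: DensityVolume, map_b: DensityVolume,
                shell_width: float = 1.0,
                voxel_mask: np.ndarray | None = None) -> FSCCurve:
    """Per-shell Re(sum F_A conj(F_B)) / sqrt(sum|F_A|^2 sum|F_B|^2).

    ``voxel_mask`` (Fourier layout) restricts the sums to a subset of
    voxels, e.g. the jointly wedge-covered region of two compensated
    averages.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must have the same shape")
    if not map_a.is_cubic():
        raise ValueError("FSC requires cubic maps")
    fa = np.fft.fftn(map_a.grid.astype(np.float64))
    fb = np.fft.fftn(map_b.grid.astype(np.float64))
    shells, n_shell = _shell_indices(map_a.shape)
    if shell_width != 1.0:
        shells = (shells / shell_width).astype(int)
        n_shell = int(np.ceil(n_shell / shell_width))
    flat = shells.ravel()
    sel = flat < n_shell
    if voxel_mask is not None:
        sel = sel & voxel_mask.ravel().astype(bool)
    cross = np.bincount(flat[sel], weights=(fa * np.conj(fb)).real.ravel()[sel],
                        minlength=n_shell)
    pa = np.bincount(flat[sel], weights=(np.abs(fa) ** 2).ravel()[sel],
                     minlength=n_shell)
    pb = np.bincount(flat[sel], weights=(np.abs(fb) ** 2).ravel()[sel],
                     minlength=n_shell)
    counts = np.bincount(flat[sel], minlength=n_shell)
    with np.errstate(invalid="ignore", divide="ignore"):
        fsc = cross / np.sqrt(pa * pb)
    fsc[counts == 0] = np.nan
    n = map_a.shape[0]
    freqs = (np.arange(n_shell) * shell_width) / (n * map_a.voxel_size)
    return FSCCurve(freqs, fsc, counts)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.5
                            ) -> ResolutionEstimate:
    """Linear interpolation of the first downward crossing of the threshold.

    Never-crossing curves report the Nyquist wavelength with crossed=False.
    Non-monotone noise spikes after the first crossing are ignored by the
    first-crossing rule.
    """
    f = curve.shell_frequencies
    c = curve.correlations
    valid = np.isfinite(c)
    fi, ci = f[valid], c[valid]
    for i in range(1, len(ci)):
        if ci[i - 1] >= threshold > ci[i]:
            frac = (ci[i - 1] - threshold) / (ci[i - 1] - ci[i])
            fc = fi[i - 1] + frac * (fi[i] - fi[i - 1])
            return ResolutionEstimate(float(1.0 / fc), True)
    return ResolutionEstimate(float(1.0 / fi[-1]), False)


def phase_randomize_beyond(volume: DensityVolume, cutoff: float = 40.0,
                           seed: int = 0) -> DensityVolume:
    """Randomize Fourier phases beyond the cutoff (Å), keeping amplitudes.

    Hermitian symmetry is guaranteed by drawing the random phases from the
    Fourier transform of a real white-noise field, so the output is real.
    """
    if cutoff < 2.0 * volume.voxel_size:
        raise ValueError("cutoff must be coarser than the Nyquist wavelength")
    f = np.fft.fftn(volume.grid.astype(np.float64))
    rng = np.random.default_rng(seed)
    g = np.fft.fftn(rng.normal(size=volume.shape))
    k = _freq_radius_invA(volume.shape, volume.voxel_size)
    beyond = k > 1.0 / cutoff
    randomized = np.abs(f) * np.exp(1j * np.angle(g))
    out = np.where(beyond, randomized, f)
    grid = np.fft.ifftn(out).real.astype(np.float32)
    return DensityVolume(grid, volume.voxel_size, volume.origin.copy())


def _freq_radius_invA(shape, voxel_size) -> np.ndarray:
    axes = [np.fft.fftfreq(n, d=voxel_size) for n in shape]
    kz = axes[0][:, None, None]
    ky = axes[1][None, :, None]
    kx = axes[2][None, None, :]
    return np.sqrt(kz**2 + ky**2 + kx**2)


def fermi_filter(volume: DensityVolume, cutoff: float = 18.0,
                 temperature: float = 0.002) -> DensityVolume:
    """Fermi lowpass: transfer 1 / (1 + exp((k - k_c)/T)), k in 1/pixel.

    ``cutoff`` is in Å; ``temperature`` in reciprocal pixels, matching the
    conventional per-pixel temperature factor.
    """
    k = _freq_radius_invA(volume.shape, volume.voxel_size) * volume.voxel_size
    kc = volume.voxel_size / cutoff
    arg = np.clip((k - kc) / temperature, -700, 700)
    transfer = 1.0 / (1.0 + np.exp(arg))
    f = np.fft.fftn(volume.grid.astype(np.float64))
    grid = np.fft.ifftn(f * transfer).real.astype(np.float32)
    return DensityVolume(grid, volume.voxel_size, volume.origin.copy())


class OverfitResult(NamedTuple):
    fsc_true: FSCCurve
    fsc_randomized: FSCCurve
    verdict: str   # "clean" or "overfit"


def overfitting_check(
    stack: np.ndarray,
    table,
    half_maps: tuple[DensityVolume, DensityVolume],
    constraints,
    voxel_size: float,
    cutoff: float = 40.0,
    angular_step: float = 2.0,
    resolution_limit: float = 30.0,
    wedge_theta: float | None = 60.0,
    seed: int = 0,
    frozen: bool = False,
    spin_step: float | None = None,
) -> OverfitResult:
    """Phase-randomization overfitting test.

    Phases of every subvolume are randomized beyond the cutoff, the final
    alignment iteration is repeated per half-set (unless ``frozen``, which
    keeps the input transforms), and the FSC of the resulting half maps is
    compared against the half-map FSC.  Verdict is "overfit" when the
    randomized FSC exceeds the 3/sqrt(n) noise significance level beyond
    the cutoff on average.
    """
    from .average import (
        align_subvolume,
        fourier_lowpass,
        wedge_compensated_average,
    )
    from .synthetic import wedge_mask
    from .transforms import RigidTransform, X_FLIP, compose_transforms, invert_transform
    from .volume import flip_x180

    df = table.df
    faces = table.faces()
    box = stack.shape[1]
    wedge = None if wedge_theta is None else wedge_mask((box,) * 3, wedge_theta)

    rng = np.random.default_rng(seed)
    rand_stack = np.stack([
        phase_randomize_beyond(
            DensityVolume(s, voxel_size), cutoff, seed=int(rng.integers(2**31 - 1))
        ).grid
        for s in stack
    ])
    work = np.stack([
        flip_x180(s) if f == "down" else s for s, f in zip(rand_stack, faces)
    ])

    halves = {}
    coverages = {}
    for label in ("A", "B"):
        members = np.where(df["halfset"].to_numpy() == label)[0]
        subs = work[members]
        transforms = []
        for idx in members:
            row = df.iloc[idx]
            t_full = RigidTransform(row["rot"], row["tilt"], row["psi"])
            # alignment-frame transform: undo the x-flip for down particles
            t_align = (compose_transforms(invert_transform(X_FLIP), t_full)
                       if faces[idx] == "down" else t_full)
            transforms.append(t_align)
        if not frozen:
            ref = wedge_compensated_average(subs, transforms, wedge)
            ref_lp = fourier_lowpass(ref, voxel_size, resolution_limit)
            new = []
            for sub, t0 in zip(subs, transforms):
                sub_lp = fourier_lowpass(sub, voxel_size, resolution_limit)
                orientations = None
                if spin_step is not None:
                    # repeat a spin-exhaustive final iteration
                    from .average import psi_global_grid

                    orientations = psi_global_grid(t0, spin_step)
                t, _ = align_subvolume(sub_lp, ref_lp, constraints, wedge=wedge,
                                       angular_step=angular_step, center=t0,
                                       orientations=orientations)
                new.append(t)
            transforms = new
        avg, cov = wedge_compensated_average(subs, transforms, wedge,
                                             return_coverage=True)
        halves[label] = DensityVolume(avg, voxel_size)
        coverages[label] = cov

    fsc_true = compute_fsc(*half_maps)
    # Fourier voxels with no wedge coverage are identically zero in both
    # halves and would fake correlation; restrict the randomized FSC to
    # the jointly covered region
    joint = (coverages["A"] > 0.5) & (coverages["B"] > 0.5)
    fsc_rand = compute_fsc(halves["A"], halves["B"], voxel_mask=joint)
    return OverfitResult(fsc_true, fsc_rand, overfit_verdict(fsc_rand, cutoff))


def overfit_verdict(fsc_rand: FSCCurve, cutoff: float = 40.0) -> str:
    """'overfit' when the randomized FSC exceeds 3/sqrt(n) beyond cutoff
    on average, else 'clean'."""
    beyond = fsc_rand.shell_frequencies > 1.0 / cutoff
    beyond &= np.isfinite(fsc_rand.correlations)
    if not np.any(beyond):
        return "clean"
    mean_rand = float(np.mean(fsc_rand.correlations[beyond]))
    mean_thresh = float(np.mean(fsc_rand.noise_threshold()[beyond]))
    return "overfit" if mean_rand > mean_thresh else "clean"
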