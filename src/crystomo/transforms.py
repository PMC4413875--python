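"""Rigid-transform algebra for subtomogram alignment.

Euler convention: intrinsic ZYZ (rot, tilt, psi) in degrees, matching the
common single-particle convention — R = Rz(rot) · Ry(tilt) · Rz(psi).
A transform maps the reference frame to the particle frame; shifts are in
voxels, (z, y, x) order to match array indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "compose_transforms",
    "invert_transform",
    "rotation_angle_deg",
]

_J = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


@dataclass(frozen=True)
class RigidTransform:
    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(
            self, "shift", np.asarray(self.shift, dtype=float).reshape(3)
        )

    # -- conversions --------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (x, y, z) column vectors."""
        return Rotation.from_euler(
            "ZYZ", [self.rot, self.tilt, self.psi], degrees=True
        ).as_matrix()

    @property
    def matrix_zyx(self) -> np.ndarray:
        """Same rotation expressed for (z, y, x)-ordered vectors."""
        return _J @ self.matrix @ _J

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, shift=(0.0, 0.0, 0.0)) -> "RigidTransform":
        import warnings as _warnings

        with _warnings.catch_warnings():
            # tilt ~ 0/180 makes rot+psi degenerate; any split is valid
            _warnings.filterwarnings("ignore", message="Gimbal lock")
            rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
        return cls(float(rot), float(tilt), float(psi), np.asarray(shift, dtype=float))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def axis(self) -> np.ndarray:
        """Unit vector (x, y, z) of the reference +z axis mapped through R."""
        return self.matrix @ np.array([0.0, 0.0, 1.0])

    def __repr__(self) -> str:  # compact, 4-decimal angles
        s = self.shift
        return (
            f"RigidTransform(rot={self.rot:.4f}, tilt={self.tilt:.4f}, "
            f"psi={self.psi:.4f}, shift=({s[0]:.3f}, {s[1]:.3f}, {s[2]:.3f}))"
        )


def compose_transforms(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Composition t1 ∘ t2 — t2 is applied first."""
    r = t1.matrix @ t2.matrix
    shift = t1.matrix_zyx @ t2.shift + t1.shift
    return RigidTransform.from_matrix(r, shift)


def invert_transform(t: RigidTransform) -> RigidTransform:
    r_inv = t.matrix.T
    shift = -(_J @ r_inv @ _J) @ t.shift
    return RigidTransform.from_matrix(r_inv, shift)


def rotation_angle_deg(t: RigidTransform, other: RigidTransform | None = None) -> float:
    """Geodesic rotation angle of t (or between t and other) in degrees."""
    r = t.matrix if other is None else t.matrix @ other.matrix.T
    return float(np.degrees(Rotation.from_matrix(r).magnitude()))


# 180° rotation about the x axis: the convention used to bring particles on
# the opposite membrane face into the reference hemisphere before alignment.
X_FLIP = RigidTransform(rot=0.0, tilt=180.0, psi=180.0)
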