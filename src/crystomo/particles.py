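"""Particle tables: per-particle position, orientation, face, half-set, score.

Positions are voxel coordinates in the tomogram (x, y, z columns, 0-based,
may be fractional); orientations are ZYZ Euler angles in degrees mapping
the reference frame to the particle frame.  Ground-truth tables written by
the simulator and refined tables written by the averaging stage share this
schema, which makes parameter-recovery comparisons one merge away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transforms import RigidTransform

__all__ = ["ParticleTable", "ParticleTableError", "COLUMNS"]

COLUMNS = ["id", "x", "y", "z", "rot", "tilt", "psi", "face", "halfset", "score"]
_FACES = {"up", "down"}
_ANGLE_FMT = "%.6f"


class ParticleTableError(ValueError):
    pass


@dataclass
class ParticleTable:
    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ParticleTableError(f"missing columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        if len(self.df):
            if self.df["id"].duplicated().any():
                raise ParticleTableError("particle ids are not unique")
            bad = set(self.df["face"]) - _FACES
            if bad:
                raise ParticleTableError(f"invalid face values: {sorted(bad)}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: list[dict]) -> "ParticleTable":
        df = pd.DataFrame(records, columns=COLUMNS)
        return cls(df)

    @classmethod
    def empty(cls) -> "ParticleTable":
        return cls(pd.DataFrame(columns=COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy())

    # -- accessors ----------------------------------------------------------

    def positions_zyx(self) -> np.ndarray:
        """(N, 3) voxel coordinates in (z, y, x) order."""
        return self.df[["z", "y", "x"]].to_numpy(dtype=float)

    def positions_xyz(self) -> np.ndarray:
        return self.df[["x", "y", "z"]].to_numpy(dtype=float)

    def transforms(self) -> list[RigidTransform]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                RigidTransform(float(row["rot"]), float(row["tilt"]), float(row["psi"]))
            )
        return out

    def faces(self) -> np.ndarray:
        return self.df["face"].to_numpy()

    def check_bounds(self, shape: tuple[int, int, int]) -> None:
        pos = self.positions_zyx()
        if len(pos) == 0:
            return
        upper = np.array(shape, dtype=float)
        if np.any(pos < 0) or np.any(pos >= upper):
            raise ParticleTableError("particle positions outside tomogram bounds")

    def assign_halfsets(self, seed: int) -> "ParticleTable":
        """Random balanced A/B split (gold-standard refinement contract)."""
        rng = np.random.default_rng(seed)
        n = len(self.df)
        labels = np.array(["A", "B"])[np.arange(n) % 2]
        df = self.df.copy()
        df["halfset"] = labels[rng.permutation(n)]
        return ParticleTable(df)

    # -- I/O -----------------------------------------------------------------

    def write_tsv(self, path) -> None:
        df = self.df.copy()
        for col in ("x", "y", "z", "rot", "tilt", "psi", "score"):
            df[col] = df[col].map(lambda v: _ANGLE_FMT % float(v))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ParticleTable":
        df = pd.read_csv(path, sep="\t", dtype={"id": int, "face": str, "halfset": str})
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ParticleTableError(f"missing columns: {missing}")
        return cls(df)

    def write_star(self, path, block: str = "particles") -> None:
        """Minimal STAR-dialect writer (one loop block, crystomo column names)."""
        with open(path, "w") as fh:
            fh.write(f"\ndata_{block}\n\nloop_\n")
            for i, col in enumerate(COLUMNS, start=1):
                fh.write(f"_crystomo_{col} #{i}\n")
            for _, row in self.df.iterrows():
                vals = []
                for col in COLUMNS:
                    v = row[col]
                    vals.append(
                        _ANGLE_FMT % float(v) if isinstance(v, (int, float, np.floating)) and col not in ("id",) else str(v)
                    )
                fh.write(" ".join(vals) + "\n")
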