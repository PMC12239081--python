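"""Core in-memory containers shared by every analysis stage.

``ForceTimeSeries`` carries one window's constraint-force record,
``Snapshot``/``Trajectory`` carry labeled coordinates.  All quantities use the
internal unit system (nm, ps, kJ/mol).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["ForceTimeSeries", "Snapshot", "Trajectory", "guess_masses"]

#: Standard atomic masses (amu) keyed by leading element letter of the atom
#: name; the convention the toy membranes and density metrics share.
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


def guess_masses(names: Sequence[str]) -> np.ndarray:
    """Guess atomic masses (amu) from the first letter of each atom name.

    Atom names starting with an unknown letter are treated as carbon-like
    beads (12.011 amu), which keeps coarse-grained fixtures well-defined.
    """
    return np.array(
        [_ELEMENT_MASSES.get(str(n)[:1].upper(), 12.011) for n in names], dtype=float
    )


@dataclass
class ForceTimeSeries:
    """Constraint-force record of a single window.

    Parameters
    ----------
    window_id:
        Index of the window on the reaction-coordinate grid.
    z0:
        Signed distance of the window from the bilayer center (nm).
    times:
        Strictly increasing, uniformly spaced sample times (ps).
    forces:
        z-component of the constraint force acting on the tracer's
        center of mass (kJ mol^-1 nm^-1), one value per time.
    config_id, replicate:
        Which multi-tracer configuration and which coverage repeat the
        series came from.
    """

    window_id: int
    z0: float
    times: np.ndarray
    forces: np.ndarray
    config_id: int = 0
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.times.ndim != 1 or self.forces.ndim != 1:
            raise ValueError("times and forces must be 1-D arrays")
        if len(self.times) != len(self.forces):
            raise ValueError(
                f"length mismatch: {len(self.times)} times vs {len(self.forces)} forces"
            )
        if len(self.times) == 0:
            raise ValueError("empty force series")
        if not (np.isfinite(self.times).all() and np.isfinite(self.forces).all()):
            raise ValueError("non-finite values in force series")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            dt = steps[0]
            if dt <= 0:
                raise ValueError("times must be strictly increasing")
            if np.abs(steps - dt).max() > 1e-9 * max(abs(dt), 1.0):
                raise ValueError("time grid is not uniform to 1e-9 relative")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Sampling interval (ps); 0 for a single-sample series."""
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class Snapshot:
    """One frame of labeled atom coordinates in an orthorhombic box."""

    resids: np.ndarray
    resnames: np.ndarray
    names: np.ndarray
    positions: np.ndarray  # (N, 3), nm
    box: np.ndarray  # (3,) orthorhombic lengths, nm
    time: float = 0.0

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype="U5")
        self.names = np.asarray(self.names, dtype="U5")
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.resids)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")
        if len(self.resnames) != n or len(self.names) != n:
            raise ValueError("label arrays must match the atom count")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite positions")
        if self.box.shape != (3,) or not (self.box > 0).all():
            raise ValueError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.resids)

    def masses(self) -> np.ndarray:
        return guess_masses(self.names)

    def translated(self, shift) -> "Snapshot":
        """Rigidly translated copy (used by invariance checks)."""
        return Snapshot(
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            names=self.names.copy(),
            positions=self.positions + np.asarray(shift, dtype=float),
            box=self.box.copy(),
            time=self.time,
        )


@dataclass
class Trajectory:
    """Ordered snapshots with identical atom ordering."""

    frames: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.frames[0].n_atoms
        t_prev = -np.inf
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(f"frame {i} has {fr.n_atoms} atoms, expected {n}")
            if fr.time < t_prev:
                raise ValueError("frame times must be non-decreasing")
            t_prev = fr.time

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def translated(self, shift) -> "Trajectory":
        return Trajectory([fr.translated(shift) for fr in self.frames])
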