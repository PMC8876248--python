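"""In-memory trajectory container and named atom selections.

A deliberately small container: atom metadata (names, masses, residue
grouping) plus per-frame orthorhombic boxes and coordinates, all in nm.
Real trajectories enter through :mod:`memprobe.gmxio` (GRO/XTC/TRR via
MDAnalysis); synthetic ones through :mod:`memprobe.toybilayer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np

__all__ = ["Trajectory", "SelectionSpec"]


@dataclass
class Trajectory:
    """Frames (orthorhombic box + coordinates, nm) over a fixed atom set."""

    names: np.ndarray      # (n_atoms,) str
    masses: np.ndarray     # (n_atoms,) amu
    resids: np.ndarray     # (n_atoms,) int, molecule/residue id
    resnames: np.ndarray   # (n_atoms,) str
    boxes: np.ndarray      # (n_frames, 3) nm
    coords: np.ndarray     # (n_frames, n_atoms, 3) nm

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=str)
        self.masses = np.asarray(self.masses, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=str)
        self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 3)
        n = self.names.size
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, n, 3)
        if not (self.masses.size == self.resids.size == self.resnames.size == n):
            raise ValueError("atom metadata arrays must have equal length")
        if self.coords.shape[0] != self.boxes.shape[0]:
            raise ValueError("boxes and coords must have one entry per frame")
        if self.n_frames and np.any(self.boxes <= 0):
            raise ValueError("box edges must be positive (orthorhombic)")

    @property
    def n_atoms(self) -> int:
        return self.names.size

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, name: str | None = None, resname: str | None = None) -> np.ndarray:
        """Atom indices matching an atom name and/or residue name."""
        m = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            m &= self.names == name
        if resname is not None:
            m &= self.resnames == resname
        return np.flatnonzero(m)

    def molecules(self, indices: np.ndarray) -> list[np.ndarray]:
        """Split an index set by residue id (one array per molecule)."""
        indices = np.asarray(indices)
        order = np.argsort(self.resids[indices], kind="stable")
        sorted_idx = indices[order]
        groups = np.split(
            sorted_idx,
            np.flatnonzero(np.diff(self.resids[sorted_idx]) != 0) + 1,
        )
        return [g for g in groups if g.size]


@dataclass
class SelectionSpec:
    """Named atom groups as index arrays into a trajectory's atom list."""

    groups: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=int) for k, v in self.groups.items()}
        for k, v in self.groups.items():
            if v.size == 0:
                raise ValueError(f"selection group {k!r} is empty")
            if np.any(v < 0):
                raise ValueError(f"selection group {k!r} has negative indices")

    def __getitem__(self, key: str) -> np.ndarray:
        try:
            return self.groups[key]
        except KeyError:
            raise KeyError(
                f"unknown selection group {key!r}; available: "
                f"{sorted(self.groups)}"
            ) from None

    def __contains__(self, key: str) -> bool:
        return key in self.groups

    def names(self) -> list[str]:
        return sorted(self.groups)

    def validate(self, n_atoms: int):
        for k, v in self.groups.items():
            if v.max() >= n_atoms:
                raise ValueError(
                    f"selection group {k!r} references atom {int(v.max())} "
                    f"but the trajectory has {n_atoms} atoms"
                )

    @classmethod
    def from_rules(cls, traj: Trajectory, rules: Mapping[str, Mapping[str, str]]
                   ) -> "SelectionSpec":
        """Build groups from {group: {"name": ..., "resname": ...}} rules."""
        groups = {}
        for gname, rule in rules.items():
            idx = traj.select(name=rule.get("name"), resname=rule.get("resname"))
            if idx.size == 0:
                raise ValueError(f"selection rule for {gname!r} matched no atoms")
            groups[gname] = idx
        return cls(groups)
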