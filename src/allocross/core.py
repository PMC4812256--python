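"""Core in-memory containers for structures, trajectories and selections.

Conventions used throughout the package:

* lengths are stored in **nanometres**, times in **picoseconds**;
* residue numbering is **1-based inclusive**, taken from the PDB residue
  sequence numbers, so literature residue intervals can be used verbatim;
* frames are assumed whole (no periodic wrapping) — analyses never apply a
  minimum-image correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "ProvenanceLabel",
    "Trajectory",
    "Selection",
    "MetaTrajectory",
    "select",
    "build_meta",
]


@dataclass(frozen=True)
class Atom:
    """One atom row: name, element symbol, mass (amu), 1-based residue id."""

    name: str
    element: str
    mass: float
    resid: int
    resname: str
    chain: str = "A"

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


class Topology:
    """Ordered atom list plus derived residue index ranges.

    Residue ids must be non-decreasing along the atom list and every atom
    must carry a positive mass.  A residue whose Cα is missing or duplicated
    is recorded in :attr:`flagged_residues` (Cα lookups on it fail).
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("topology needs at least one atom")
        resids = [a.resid for a in atoms]
        if any(b < a for a, b in zip(resids, resids[1:])):
            raise ValueError("residue ids must be non-decreasing along the atom list")
        if any(a.mass <= 0 for a in atoms):
            raise ValueError("every atom must have mass > 0")
        self.atoms: list[Atom] = atoms
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.resids = np.array(resids, dtype=int)

        self._res_atoms: dict[int, list[int]] = {}
        for i, a in enumerate(atoms):
            self._res_atoms.setdefault(a.resid, []).append(i)

        self._ca: dict[int, int] = {}
        self.flagged_residues: set[int] = set()
        for rid, idxs in self._res_atoms.items():
            cas = [i for i in idxs if atoms[i].name == "CA"]
            if len(cas) == 1:
                self._ca[rid] = cas[0]
            else:
                self.flagged_residues.add(rid)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_ids(self) -> list[int]:
        return sorted(self._res_atoms)

    @property
    def n_residues(self) -> int:
        return len(self._res_atoms)

    @property
    def residue_span(self) -> tuple[int, int]:
        ids = self.residue_ids
        return ids[0], ids[-1]

    def residue_atoms(self, resid: int) -> list[int]:
        return list(self._res_atoms[resid])

    def residue_name(self, resid: int) -> str:
        return self.atoms[self._res_atoms[resid][0]].resname

    def ca_index(self, resid: int) -> int:
        """Index of the unique Cα of ``resid``; KeyError if absent/ambiguous."""
        return self._ca[resid]

    def has_ca(self, resid: int) -> bool:
        return resid in self._ca


@dataclass
class Frame:
    """A single conformation: per-atom coordinates (nm) and a time stamp (ps)."""

    coords: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ProvenanceLabel:
    """Where a trajectory came from: system id, per-site ligand tags, replica.

    ``ligands`` maps a binding site to the ligand occupying it, e.g.
    ``{"NBD": "ATP", "SBD": "NR"}``.
    """

    system: str
    ligands: Mapping[str, str] = field(default_factory=dict)
    replica: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligands", dict(self.ligands))

    def __hash__(self) -> int:
        return hash((self.system, tuple(sorted(self.ligands.items())), self.replica))

    @property
    def state_key(self) -> str:
        """Ligand-state key (replica-independent), e.g. ``NBD(ATP)-SBD(NR)``."""
        if not self.ligands:
            return self.system
        return "-".join(f"{site}({lig})" for site, lig in sorted(self.ligands.items()))

    def validate(self, vocabulary: Mapping[str, Sequence[str]]) -> None:
        for site, lig in self.ligands.items():
            if site not in vocabulary or lig not in vocabulary[site]:
                raise ValueError(f"ligand tag {site}={lig!r} not in declared vocabulary")


class Trajectory:
    """Ordered frames over one topology, with a provenance label.

    Coordinates are held as one ``(n_frames, n_atoms, 3)`` array; times must
    be strictly increasing.
    """

    def __init__(
        self,
        topology: Topology,
        xyz: np.ndarray,
        times: np.ndarray | None = None,
        label: ProvenanceLabel | None = None,
    ):
        xyz = np.asarray(xyz, dtype=float)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise ValueError("xyz must be (n_frames, n_atoms, 3)")
        if xyz.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate count {xyz.shape[1]} != topology atom count {topology.n_atoms}"
            )
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        if times is None:
            times = np.arange(xyz.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (xyz.shape[0],):
            raise ValueError("times must have one entry per frame")
        if xyz.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.xyz = xyz
        self.times = times
        self.label = label

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.xyz[i], time=float(self.times[i]))

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @property
    def dt(self) -> float:
        """Median frame spacing in ps (0 for a single frame)."""
        if self.n_frames < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        """Trajectory duration in ps, counting one ``dt`` per frame."""
        return self.n_frames * self.dt

    def slice(self, frames: slice | np.ndarray) -> "Trajectory":
        idx = np.arange(self.n_frames)[frames]
        return Trajectory(self.topology, self.xyz[idx], self.times[idx], self.label)


@dataclass(frozen=True)
class Selection:
    """Sorted, deduplicated atom indices plus the expression that produced them."""

    indices: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, topology: Topology) -> None:
        if len(self.indices) and (
            self.indices[0] < 0 or self.indices[-1] >= topology.n_atoms
        ):
            raise IndexError("selection indices out of range for topology")


def select(
    topology: Topology,
    residue_range: tuple[int, int],
    atom_filter: Iterable[str] | str = "all",
) -> Selection:
    """Select atoms of a 1-based inclusive residue interval, optionally by name.

    ``atom_filter`` is either the string ``"all"`` or a set of atom names
    (e.g. ``{"CA"}``).  An empty result is allowed but triggers a warning.
    """
    lo, hi = residue_range
    if lo > hi:
        raise ValueError(f"reversed residue range {lo}–{hi}")
    span = topology.residue_span
    if lo < span[0] or hi > span[1]:
        raise ValueError(
            f"residue range {lo}–{hi} outside topology span {span[0]}–{span[1]}"
        )
    if atom_filter == "all":
        names = None
        prov = f"resid {lo}-{hi} and all atoms"
    else:
        names = set(atom_filter)
        prov = f"resid {lo}-{hi} and name {sorted(names)}"
    idx = [
        i
        for i, a in enumerate(topology.atoms)
        if lo <= a.resid <= hi and (names is None or a.name in names)
    ]
    if not idx:
        warnings.warn(f"selection '{prov}' matched no atoms", stacklevel=2)
    return Selection(np.array(idx, dtype=int), provenance=prov)


class MetaTrajectory:
    """Concatenated tail windows of several runs, with per-frame source labels.

    Frames are stored in segment order; every frame maps to exactly one
    :class:`ProvenanceLabel`.  All segments must share the topology atom
    count so a single selection resolves on every frame.
    """

    def __init__(self, segments: Sequence[tuple[Trajectory, slice]]):
        if not segments:
            raise ValueError("meta-trajectory needs at least one segment")
        n_atoms = segments[0][0].n_atoms
        for traj, _ in segments:
            if traj.n_atoms != n_atoms:
                raise ValueError(
                    f"segment atom count {traj.n_atoms} != {n_atoms}; "
                    "all runs must share one atom count"
                )
        self.segments = list(segments)
        self.topology = segments[0][0].topology
        parts, labels, times = [], [], []
        for traj, window in self.segments:
            sub = traj.xyz[window]
            parts.append(sub)
            labels.extend([traj.label] * sub.shape[0])
            times.append(traj.times[window])
        self.xyz = np.concatenate(parts, axis=0)
        self.labels: list[ProvenanceLabel | None] = labels
        self.segment_times = times

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.xyz[i])

    def label_histogram(self) -> dict[ProvenanceLabel | None, int]:
        hist: dict[ProvenanceLabel | None, int] = {}
        for lab in self.labels:
            hist[lab] = hist.get(lab, 0) + 1
        return hist

    def state_keys(self) -> list[str]:
        """Per-frame replica-independent ligand-state keys."""
        return [lab.state_key if lab is not None else "?" for lab in self.labels]


def build_meta(trajectories: Sequence[Trajectory], tail_ns: float) -> MetaTrajectory:
    """Concatenate the final ``tail_ns`` nanoseconds of each run.

    The tail of a run of ``n`` frames with spacing ``dt`` covers
    ``round(tail_ps / dt)`` frames (each frame owning one ``dt`` of time), so
    a tail equal to the full duration keeps every frame.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    tail_ps = tail_ns * 1000.0
    segments = []
    for traj in trajectories:
        if traj.n_frames == 1:
            segments.append((traj, slice(0, 1)))
            continue
        dt = traj.dt
        if tail_ps > traj.duration + 1e-9:
            raise ValueError(
                f"tail {tail_ns} ns exceeds duration of run "
                f"{traj.label.system if traj.label else '?'} "
                f"({traj.duration / 1000.0:g} ns)"
            )
        k = int(round(tail_ps / dt))
        k = max(1, min(traj.n_frames, k))
        segments.append((traj, slice(traj.n_frames - k, traj.n_frames)))
    return MetaTrajectory(segments)
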