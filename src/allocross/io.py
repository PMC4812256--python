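"""Reading and writing structures and trajectories.

Format handling (PDB, XTC, DCD) is delegated to :mod:`mdtraj`; this module
converts between mdtraj objects and the package's own containers, applies
the package conventions (nm/ps units, 1-based PDB residue numbering) and
adds the validation the analyses rely on (atom-count checks, insertion-code
policy, Cα flagging).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import mdtraj as md
import numpy as np
import yaml
from mdtraj.core import element as md_element

from .core import Atom, Frame, ProvenanceLabel, Topology, Trajectory

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "write_pdb",
    "to_mdtraj",
    "from_mdtraj",
    "RunSpec",
    "SystemSpec",
    "RunSet",
    "load_manifest",
]

_FALLBACK_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def _atom_mass(a: md.core.topology.Atom) -> float:
    if a.element is not None and a.element.mass > 0:
        return float(a.element.mass)
    return _FALLBACK_MASS.get(a.name[:1].upper(), 12.011)


def from_mdtraj(top: md.Topology) -> Topology:
    """Convert an mdtraj topology, keeping PDB residue sequence numbers."""
    atoms = []
    for chain in top.chains:
        chain_id = getattr(chain, "chain_id", None) or chr(ord("A") + chain.index % 26)
        for res in chain.residues:
            for a in res.atoms:
                symbol = a.element.symbol if a.element is not None else a.name[:1]
                atoms.append(
                    Atom(
                        name=a.name,
                        element=symbol,
                        mass=_atom_mass(a),
                        resid=int(res.resSeq),
                        resname=res.name,
                        chain=str(chain_id),
                    )
                )
    return Topology(atoms)


def to_mdtraj(topology: Topology) -> md.Topology:
    top = md.Topology()
    chain_map: dict[str, md.core.topology.Chain] = {}
    res_map: dict[tuple[str, int], md.core.topology.Residue] = {}
    for a in topology.atoms:
        if a.chain not in chain_map:
            chain_map[a.chain] = top.add_chain()
        chain = chain_map[a.chain]
        key = (a.chain, a.resid)
        if key not in res_map:
            res_map[key] = top.add_residue(a.resname, chain, resSeq=a.resid)
        try:
            elem = md_element.get_by_symbol(a.element)
        except KeyError:
            elem = md_element.virtual
        top.add_atom(a.name, elem, res_map[key])
    return top


_PROTEIN_BACKBONE_HINT = {"N", "CA", "C", "O"}


def _check_pdb_text(path: str | Path, insertion_codes: str) -> None:
    """Pre-validate ATOM/HETATM records: parseable coordinates, icode policy."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            icode = line[26:27] if len(line) > 26 else " "
            if icode.strip() and insertion_codes == "reject":
                raise ValueError(
                    f"{path}: insertion code {icode!r} at line {lineno}; "
                    "pass insertion_codes='renumber' to accept"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: unparseable coordinate record at line {lineno}"
                ) from None


def _flag_missing_ca(topology: Topology) -> None:
    missing = [
        rid
        for rid in topology.residue_ids
        if rid not in topology.flagged_residues
        and not topology.has_ca(rid)
        and _PROTEIN_BACKBONE_HINT
        & {topology.atoms[i].name for i in topology.residue_atoms(rid)}
    ]
    flagged = sorted(set(missing) | topology.flagged_residues)
    if flagged:
        warnings.warn(
            f"residues without a unique CA atom: {flagged}", stacklevel=3
        )
        topology.flagged_residues.update(flagged)


def read_structure(
    path: str | Path, insertion_codes: str = "reject"
) -> tuple[Topology, Frame]:
    """Read a PDB file; return its topology and the first model's coordinates.

    Coordinates are converted Å→nm.  ``insertion_codes`` is ``"reject"``
    (default, raises on any insertion code) or ``"renumber"`` (mdtraj's
    sequential residue handling is accepted as-is).
    """
    _check_pdb_text(path, insertion_codes)
    t = md.load_pdb(str(path), standard_names=False)
    topology = from_mdtraj(t.topology)
    _flag_missing_ca(topology)
    return topology, Frame(np.asarray(t.xyz[0], dtype=float), time=0.0)


def read_trajectory(
    path: str | Path,
    topology: Topology,
    dt: float | None = None,
    label: ProvenanceLabel | None = None,
) -> Trajectory:
    """Read an XTC/DCD/multi-model-PDB trajectory against a known topology.

    ``dt`` (ps) overrides or supplies frame times when the format carries
    none (DCD) or when the manifest declares the output frequency.
    """
    path = Path(path)
    ext = path.suffix.lower()
    mdtop = to_mdtraj(topology)
    if ext == ".pdb":
        _check_pdb_text(path, insertion_codes="reject")
        t = md.load_pdb(str(path), standard_names=False)
        if t.n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: file has {t.n_atoms} atoms, topology has {topology.n_atoms}"
            )
    else:
        n_file = _file_atom_count(path, ext)
        if n_file is not None and n_file != topology.n_atoms:
            raise ValueError(
                f"{path}: file has {n_file} atoms, topology has {topology.n_atoms}"
            )
        t = md.load(str(path), top=mdtop)
        if ext == ".dcd":
            expected = _dcd_header_frames(path)
            if expected is not None and t.n_frames != expected:
                raise ValueError(
                    f"{path}: truncated DCD — header declares {expected} frames, "
                    f"read {t.n_frames}"
                )
    if t.n_frames == 0:
        raise ValueError(f"{path}: no frames read")
    if dt is not None:
        times = np.arange(t.n_frames, dtype=float) * dt
    else:
        times = np.asarray(t.time, dtype=float)
        if t.n_frames > 1 and not np.all(np.diff(times) > 0):
            times = np.arange(t.n_frames, dtype=float)
    return Trajectory(topology, np.asarray(t.xyz, dtype=float), times, label=label)


def _file_atom_count(path: Path, ext: str) -> int | None:
    if ext == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as fh:
            xyz, _, _, _ = fh.read(n_frames=1)
            return int(xyz.shape[1]) if len(xyz) else None
    if ext == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _, _ = fh.read(n_frames=1)
            return int(xyz.shape[1]) if len(xyz) else None
    return None


def _dcd_header_frames(path: Path) -> int | None:
    """Frame count declared in a DCD header (NSET field), if parseable."""
    import struct

    with open(path, "rb") as fh:
        head = fh.read(12)
    if len(head) < 12 or head[4:8] != b"CORD":
        return None
    return struct.unpack("<i", head[8:12])[0]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write XTC/DCD/multi-model PDB by extension (nm internally, Å in PDB/DCD)."""
    t = md.Trajectory(
        xyz=trajectory.xyz.astype(np.float32),
        topology=to_mdtraj(trajectory.topology),
        time=trajectory.times,
    )
    t.save(str(Path(path)))


def write_pdb(topology: Topology, frame: Frame, path: str | Path) -> None:
    t = md.Trajectory(
        xyz=frame.coords[np.newaxis].astype(np.float32), topology=to_mdtraj(topology)
    )
    t.save_pdb(str(Path(path)))


# ---------------------------------------------------------------------------
# Run-set manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunSpec:
    path: str
    replica: int = 1
    dt: float | None = None  # ps; overrides the run-set default


@dataclass(frozen=True)
class SystemSpec:
    system_id: str
    ligands: Mapping[str, str]
    runs: tuple[RunSpec, ...]

    def label_for(self, run: RunSpec) -> ProvenanceLabel:
        return ProvenanceLabel(self.system_id, dict(self.ligands), run.replica)


@dataclass(frozen=True)
class RunSet:
    """Parsed run-set manifest: reference structure plus labelled run files."""

    reference: str
    dt: float
    systems: tuple[SystemSpec, ...]
    vocabulary: Mapping[str, Sequence[str]] = field(default_factory=dict)
    root: str = "."

    def system(self, system_id: str) -> SystemSpec:
        for s in self.systems:
            if s.system_id == system_id:
                return s
        raise KeyError(f"system {system_id!r} not in manifest")

    def load_reference(self) -> tuple[Topology, Frame]:
        return read_structure(os.path.join(self.root, self.reference))

    def load_runs(self, system_id: str, topology: Topology) -> list[Trajectory]:
        spec = self.system(system_id)
        out = []
        for run in spec.runs:
            out.append(
                read_trajectory(
                    os.path.join(self.root, run.path),
                    topology,
                    dt=run.dt if run.dt is not None else self.dt,
                    label=spec.label_for(run),
                )
            )
        return out


def load_manifest(path: str | Path) -> RunSet:
    """Load a YAML run-set manifest.

    Schema::

        reference: ref.pdb          # starting structure, path relative to manifest
        dt_ps: 100.0                # trajectory output spacing (must be explicit)
        vocabulary: {NBD: [ADP, ATP], SBD: [free, NR, Api88]}
        systems:
          - id: ADP-free
            ligands: {NBD: ADP, SBD: free}
            runs:
              - {path: runs/adp_free_r1.xtc, replica: 1}
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "dt_ps" not in raw:
        raise ValueError("manifest must declare dt_ps (frame spacing in ps)")
    vocabulary = raw.get("vocabulary", {})
    systems = []
    for s in raw["systems"]:
        runs = tuple(
            RunSpec(path=r["path"], replica=int(r.get("replica", 1)), dt=r.get("dt_ps"))
            for r in s["runs"]
        )
        spec = SystemSpec(
            system_id=str(s["id"]), ligands=dict(s.get("ligands", {})), runs=runs
        )
        for run in runs:
            if vocabulary:
                spec.label_for(run).validate(vocabulary)
        systems.append(spec)
    return RunSet(
        reference=raw["reference"],
        dt=float(raw["dt_ps"]),
        systems=tuple(systems),
        vocabulary=vocabulary,
        root=str(path.parent),
    )
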