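"""Contacts, hydrogen bonds, persistence filtering, interface maps and
β-strand content.

Criteria (all configurable):

* **contact** — minimum heavy-atom distance between two residues
  ≤ 0.45 nm (a standard residue-contact convention);
* **hydrogen bond** — donor–acceptor (N···O) distance ≤ 0.35 nm and
  hydrogen–donor–acceptor angle ≤ 30°; when the model carries no
  hydrogens the angle term is skipped (distance-only fallback, flagged);
* **persistence** — an interaction is kept if present in at least a
  threshold fraction of the analysed frames (default 30%), the occupancy
  being reported exactly;
* **interface** — residues whose *time-averaged* minimum heavy-atom
  distance to the partner group falls below a threshold (default 6 Å);
* **strand** — a minimal ladder criterion: a residue is β-strand in a
  frame if it forms an inter-strand bridge (two reciprocal backbone
  N···O bonds in antiparallel register, or the offset pair in parallel
  register, sequence separation ≥ 3) and an adjacent residue continues
  the ladder.  This is deliberately lighter than full DSSP: only strand
  content is needed, not 8-state assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import MetaTrajectory, Topology, Trajectory

__all__ = [
    "InteractionRecord",
    "InterfaceMap",
    "StrandContent",
    "contact_series",
    "hbond_series",
    "persistence_filter",
    "interface_map",
    "strand_content",
]

CONTACT_CUTOFF = 0.45  # nm
HBOND_DISTANCE_CUTOFF = 0.35  # nm donor–acceptor
HBOND_ANGLE_CUTOFF = 30.0  # degrees H–D–A
INTERFACE_THRESHOLD = 6.0  # Å
PERSISTENCE_THRESHOLD = 0.30


def _heavy_atoms(top: Topology, resid: int) -> list[int]:
    return [i for i in top.residue_atoms(resid) if not top.atoms[i].is_hydrogen]


def _named(top: Topology, resid: int, prefix: str) -> list[int]:
    return [
        i
        for i in top.residue_atoms(resid)
        if top.atoms[i].name.startswith(prefix) and not top.atoms[i].is_hydrogen
    ]


def _min_dist_series(
    traj: Trajectory | MetaTrajectory, atoms_a: Sequence[int], atoms_b: Sequence[int]
) -> np.ndarray:
    diff = traj.xyz[:, list(atoms_a), None, :] - traj.xyz[:, None, list(atoms_b), :]
    return np.sqrt((diff**2).sum(-1)).min(axis=(1, 2))


def contact_series(
    trajectory: Trajectory | MetaTrajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    cutoff: float = CONTACT_CUTOFF,
) -> dict[tuple[int, int], np.ndarray]:
    """Per-residue-pair boolean contact series.

    A pair is in contact in a frame iff its minimum heavy-atom distance is
    ≤ ``cutoff`` (nm).  Keys are ``(residue of group A, residue of group B)``.
    """
    if not group_a or not group_b:
        raise ValueError("residue groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("residue groups must be disjoint")
    top = trajectory.topology
    out: dict[tuple[int, int], np.ndarray] = {}
    for ra in group_a:
        ha = _heavy_atoms(top, ra)
        for rb in group_b:
            hb = _heavy_atoms(top, rb)
            out[(ra, rb)] = _min_dist_series(trajectory, ha, hb) <= cutoff
    return out


def hbond_series(
    trajectory: Trajectory | MetaTrajectory,
    donor_residues: Sequence[int],
    acceptor_residues: Sequence[int],
    distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> dict[tuple[int, int], np.ndarray]:
    """Per-residue-pair boolean H-bond series (donor residue, acceptor residue).

    Donors are nitrogen atoms (names starting ``N``), acceptors oxygens
    (names starting ``O``).  When a donor has attached hydrogens (same
    residue, within 0.15 nm) the H–donor–acceptor angle must be
    ≤ ``angle_cutoff``; otherwise detection falls back to the donor
    heavy-atom distance alone, with a warning.
    """
    top = trajectory.topology
    donors = {r: _named(top, r, "N") for r in donor_residues}
    acceptors = {r: _named(top, r, "O") for r in acceptor_residues}
    if not any(donors.values()):
        raise ValueError("no donor (N) atoms found in donor residues")
    if not any(acceptors.values()):
        raise ValueError("no acceptor (O) atoms found in acceptor residues")
    hydrogens = {
        r: [i for i in top.residue_atoms(r) if top.atoms[i].is_hydrogen]
        for r in donor_residues
    }
    if not any(hydrogens.values()):
        warnings.warn(
            "no hydrogens on donors; H-bond detection uses the donor–acceptor "
            "distance criterion only",
            stacklevel=2,
        )
    n = trajectory.n_frames
    out: dict[tuple[int, int], np.ndarray] = {}
    for rd, datoms in donors.items():
        if not datoms:
            continue
        for ra, aatoms in acceptors.items():
            if not aatoms or rd == ra:
                continue
            series = np.zeros(n, dtype=bool)
            for f in range(n):
                hit = False
                for d in datoms:
                    dp = trajectory.xyz[f, d]
                    for a in aatoms:
                        ap = trajectory.xyz[f, a]
                        if np.linalg.norm(ap - dp) > distance_cutoff:
                            continue
                        hs = [
                            h
                            for h in hydrogens.get(rd, [])
                            if np.linalg.norm(trajectory.xyz[f, h] - dp) <= 0.15
                        ]
                        if not hs:
                            hit = True
                            break
                        for h in hs:
                            v1 = trajectory.xyz[f, h] - dp
                            v2 = ap - dp
                            cosang = np.dot(v1, v2) / (
                                np.linalg.norm(v1) * np.linalg.norm(v2)
                            )
                            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                            if ang <= angle_cutoff:
                                hit = True
                                break
                        if hit:
                            break
                    if hit:
                        break
                series[f] = hit
            out[(rd, ra)] = series
    return out


@dataclass(frozen=True)
class InteractionRecord:
    """A persistent contact or H-bond between an ordered residue pair."""

    kind: str  # "contact" | "hbond"
    residue_a: int
    residue_b: int
    occupancy: float

    def __post_init__(self) -> None:
        if self.kind not in ("contact", "hbond"):
            raise ValueError("kind must be 'contact' or 'hbond'")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


def persistence_filter(
    series: Mapping[tuple[int, int], np.ndarray],
    threshold: float = PERSISTENCE_THRESHOLD,
    kind: str = "contact",
) -> list[InteractionRecord]:
    """Keep interactions present in at least ``threshold`` of the frames.

    Occupancy is the exact frame fraction.  At ``threshold == 0`` a pair is
    still only retained if it occurs in at least one frame.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    records = []
    for (ra, rb), s in series.items():
        occ = float(np.mean(np.asarray(s, dtype=bool)))
        if occ >= threshold and occ > 0.0:
            records.append(InteractionRecord(kind, ra, rb, occ))
    records.sort(key=lambda r: (-r.occupancy, r.residue_a, r.residue_b))
    return records


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "residue_a": r.residue_a,
                "residue_b": r.residue_b,
                "occupancy": r.occupancy,
            }
            for r in records
        ]
    )


@dataclass
class InterfaceMap:
    """Time-averaged minimum-distance matrix (Å) with derived residue lists.

    ``side_a``/``side_b`` list the residues having at least one partner
    whose *average* distance is below the threshold (averaged-matrix
    semantics, not any-frame membership).
    """

    residues_a: list[int]
    residues_b: list[int]
    matrix: np.ndarray  # Å, shape (len_a, len_b)
    threshold: float  # Å
    side_a: list[int] = field(default_factory=list)
    side_b: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residues_a, columns=self.residues_b)


def interface_map(
    trajectory: Trajectory | MetaTrajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    threshold: float = INTERFACE_THRESHOLD,
    mode: str = "average",
) -> InterfaceMap:
    """Residue-level interface between two groups.

    ``mode="average"`` (default) lists a residue pair when its
    time-averaged minimum heavy-atom distance is below ``threshold`` (Å);
    ``mode="fraction"`` applies the threshold per frame and lists pairs
    below it in a majority of frames (sensitivity check).
    """
    if not group_a or not group_b:
        raise ValueError("residue groups must be nonempty")
    top = trajectory.topology
    mat = np.empty((len(group_a), len(group_b)))
    below = np.zeros_like(mat)
    for i, ra in enumerate(group_a):
        ha = _heavy_atoms(top, ra)
        for j, rb in enumerate(group_b):
            hb = _heavy_atoms(top, rb)
            d = _min_dist_series(trajectory, ha, hb) * 10.0  # nm → Å
            mat[i, j] = d.mean()
            below[i, j] = np.mean(d < threshold)
    if mode == "average":
        hit = mat < threshold
    elif mode == "fraction":
        hit = below > 0.5
    else:
        raise ValueError("mode must be 'average' or 'fraction'")
    side_a = [ra for i, ra in enumerate(group_a) if hit[i].any()]
    side_b = [rb for j, rb in enumerate(group_b) if hit[:, j].any()]
    return InterfaceMap(
        residues_a=list(group_a),
        residues_b=list(group_b),
        matrix=mat,
        threshold=threshold,
        side_a=side_a,
        side_b=side_b,
    )


# ---------------------------------------------------------------------------
# β-strand content
# ---------------------------------------------------------------------------


@dataclass
class StrandContent:
    """Per-frame strand flags for a residue range and the overall content."""

    residue_range: tuple[int, int]
    flags: np.ndarray  # (n_frames, n_residues_in_range) bool

    @property
    def content(self) -> float:
        """Fraction of (residue, frame) pairs assigned strand."""
        return float(self.flags.mean())

    @property
    def per_frame(self) -> np.ndarray:
        return self.flags.mean(axis=1)


def strand_content(
    trajectory: Trajectory | MetaTrajectory,
    residue_range: tuple[int, int],
    hbond_cutoff: float = HBOND_DISTANCE_CUTOFF,
    min_separation: int = 3,
) -> StrandContent:
    """β-strand content of a residue stretch by the minimal ladder criterion.

    Per frame, residue *i* is strand if it forms a bridge with some residue
    *j* (``|i−j| ≥ min_separation``) and residue *i±1* continues the ladder
    with *j∓1* (antiparallel) or *j±1* (parallel).  Bridges use backbone
    N···O distances ≤ ``hbond_cutoff`` (nm).
    """
    top = trajectory.topology
    lo, hi = residue_range
    # residues (anywhere in the chain) with full backbone serve as partners
    bb = [
        r
        for r in top.residue_ids
        if {"N", "O"} <= {top.atoms[i].name for i in top.residue_atoms(r)}
    ]
    for r in range(lo, hi + 1):
        if r not in bb:
            raise ValueError(f"residue {r} lacks backbone N/O atoms")
    ridx = {r: k for k, r in enumerate(bb)}
    n_idx = np.array([next(i for i in top.residue_atoms(r) if top.atoms[i].name == "N") for r in bb])
    o_idx = np.array([next(i for i in top.residue_atoms(r) if top.atoms[i].name == "O") for r in bb])
    m = len(bb)
    seq = np.array(bb)
    sep_ok = np.abs(seq[:, None] - seq[None, :]) >= min_separation

    range_pos = [ridx[r] for r in range(lo, hi + 1)]
    n_frames = trajectory.n_frames
    flags = np.zeros((n_frames, len(range_pos)), dtype=bool)

    # neighbour-in-chain lookup (positions, -1 when absent)
    nxt = np.full(m, -1, dtype=int)
    prv = np.full(m, -1, dtype=int)
    for k, r in enumerate(bb):
        if r + 1 in ridx:
            nxt[k] = ridx[r + 1]
        if r - 1 in ridx:
            prv[k] = ridx[r - 1]

    def shifted(bridge: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """bridge[rows[i], cols[j]] with -1 mapping to False."""
        ok = (rows[:, None] >= 0) & (cols[None, :] >= 0)
        out = np.zeros((m, m), dtype=bool)
        rr = np.clip(rows, 0, m - 1)
        cc = np.clip(cols, 0, m - 1)
        out = bridge[rr[:, None], cc[None, :]] & ok
        return out

    for f in range(n_frames):
        npos = trajectory.xyz[f][n_idx]
        opos = trajectory.xyz[f][o_idx]
        hb = cdist(npos, opos) <= hbond_cutoff  # hb[i, j]: N_i···O_j
        anti = hb & hb.T & sep_ok
        # parallel bridge (i, j): N_i···O_{j-1} and N_{j+1}···O_i
        valid = (prv >= 0)[None, :] & (nxt >= 0)[None, :]
        jprv = np.clip(prv, 0, m - 1)
        jnxt = np.clip(nxt, 0, m - 1)
        par = hb[:, jprv] & hb.T[:, jnxt] & valid & sep_ok
        bridge = anti | par
        ladder_anti = anti & shifted(anti, nxt, prv)
        ladder_anti |= anti & shifted(anti, prv, nxt)
        ladder_par = par & shifted(par, nxt, nxt)
        ladder_par |= par & shifted(par, prv, prv)
        strand = (ladder_anti | ladder_par).any(axis=1)
        flags[f] = strand[range_pos]
    return StrandContent(residue_range=(lo, hi), flags=flags)
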