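"""Synthetic two-domain trajectories with known, programmable structure.

Real Hsp70-type trajectories come from μs-scale MD; for testing the
analysis stages this module generates *toy* two-lobe + appended-domain
chains joined by a flexible linker, with

* multimodal interdomain arrangements (a weighted mixture of rigid
  placements of the appended domain, i.i.d. or Markov over frames),
* differential internal rigidity (per-region Gaussian noise σ),
* planted residue–residue H-bond/contact events with exact occupancy,
* planted β-strand segments with exact per-frame strand fractions.

Every generator is a pure function of its parameters and seed, and each
emits its ground truth (per-frame state, planted frame indices) alongside
the trajectory, so analyses can be validated against construction rather
than against another estimator.  No force field or thermodynamic realism
is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Atom, Frame, Topology, Trajectory, ProvenanceLabel

__all__ = [
    "ToyArchitecture",
    "ToyStructure",
    "Placement",
    "StateMixture",
    "NoiseModel",
    "make_toy_structure",
    "simulate_hinge_trajectory",
    "HingeSimulation",
    "plant_interaction",
    "plant_strand_segment",
]

CA_SPACING = 0.38  # nm, ideal consecutive Cα spacing

# backbone offsets relative to CA (nm); deliberately non-physical but fixed
_N_OFF = np.array([-0.12, 0.09, 0.04])
_C_OFF = np.array([0.12, 0.09, -0.04])
_O_OFF = np.array([0.12, 0.21, -0.04])

_MASS = {"N": 14.007, "C": 12.011, "O": 15.999}


@dataclass(frozen=True)
class ToyArchitecture:
    """Residue counts of the toy chain: lobe A + lobe B (the two-lobe
    nucleotide-binding-like domain), linker, and the appended
    substrate-binding-like domain, numbered contiguously from 1."""

    lobe_a: int = 40
    lobe_b: int = 40
    linker: int = 14
    appended: int = 60
    backbone: bool = False
    spacing: float = CA_SPACING

    def __post_init__(self) -> None:
        if min(self.lobe_a, self.lobe_b, self.linker, self.appended) < 1:
            raise ValueError("all residue counts must be >= 1")

    @property
    def n_residues(self) -> int:
        return self.lobe_a + self.lobe_b + self.linker + self.appended

    @property
    def lobe_a_range(self) -> tuple[int, int]:
        return 1, self.lobe_a

    @property
    def lobe_b_range(self) -> tuple[int, int]:
        return self.lobe_a + 1, self.lobe_a + self.lobe_b

    @property
    def core_range(self) -> tuple[int, int]:
        """Both lobes together — the anchor (NBD-like) domain."""
        return 1, self.lobe_a + self.lobe_b

    @property
    def linker_range(self) -> tuple[int, int]:
        start = self.lobe_a + self.lobe_b + 1
        return start, start + self.linker - 1

    @property
    def appended_range(self) -> tuple[int, int]:
        start = self.lobe_a + self.lobe_b + self.linker + 1
        return start, self.n_residues


def _serpentine(n: int, step: float) -> np.ndarray:
    """n points on a boustrophedon lattice path in a near-cubic box.

    Consecutive points are exactly one lattice step apart, giving a
    compact, fully deterministic globule.
    """
    side = max(1, math.ceil(n ** (1.0 / 3.0)))
    pts = []
    row = 0
    for k in range(side + 2):
        js = range(side) if k % 2 == 0 else range(side - 1, -1, -1)
        for j in js:
            is_ = range(side) if row % 2 == 0 else range(side - 1, -1, -1)
            for i in is_:
                pts.append((i, j, k))
                if len(pts) == n:
                    return np.array(pts, dtype=float) * step
            row += 1
    return np.array(pts[:n], dtype=float) * step


@dataclass
class ToyStructure:
    """A built toy chain: topology, reference frame, architecture and pivot."""

    topology: Topology
    frame: Frame
    arch: ToyArchitecture
    pivot: np.ndarray  # hinge point (last linker Cα), nm

    @classmethod
    def build(cls, arch: ToyArchitecture) -> "ToyStructure":
        step = arch.spacing
        ca = np.zeros((arch.n_residues, 3))
        cursor = 0

        def place(block: np.ndarray, origin: np.ndarray) -> None:
            nonlocal cursor
            ca[cursor : cursor + len(block)] = block + origin
            cursor += len(block)

        a = _serpentine(arch.lobe_a, step)
        place(a, np.zeros(3))
        last = ca[cursor - 1]
        b = _serpentine(arch.lobe_b, step)
        place(b, last + np.array([0.0, 0.0, step]))
        last = ca[cursor - 1]
        for i in range(arch.linker):
            ca[cursor] = last + np.array([0.0, 0.0, step * (i + 1)])
            cursor += 1
        pivot = ca[cursor - 1].copy()
        s = _serpentine(arch.appended, step)
        place(s, pivot + np.array([0.0, 0.0, step]))

        atoms: list[Atom] = []
        coords: list[np.ndarray] = []
        for r in range(arch.n_residues):
            rid = r + 1
            if arch.backbone:
                atoms.append(Atom("N", "N", _MASS["N"], rid, "ALA"))
                coords.append(ca[r] + _N_OFF)
            atoms.append(Atom("CA", "C", _MASS["C"], rid, "ALA"))
            coords.append(ca[r])
            if arch.backbone:
                atoms.append(Atom("C", "C", _MASS["C"], rid, "ALA"))
                coords.append(ca[r] + _C_OFF)
                atoms.append(Atom("O", "O", _MASS["O"], rid, "ALA"))
                coords.append(ca[r] + _O_OFF)
        top = Topology(atoms)
        return cls(top, Frame(np.array(coords)), arch, pivot)

    def region_sigma_per_atom(self, noise: "NoiseModel") -> np.ndarray:
        lo, hi = self.arch.linker_range
        sig = np.full(self.topology.n_atoms, noise.domain_sigma)
        in_linker = (self.topology.resids >= lo) & (self.topology.resids <= hi)
        sig[in_linker] = noise.linker_sigma
        return sig

    def appended_atom_mask(self) -> np.ndarray:
        lo, hi = self.arch.appended_range
        return (self.topology.resids >= lo) & (self.topology.resids <= hi)


def make_toy_structure(arch: ToyArchitecture) -> tuple[Topology, Frame]:
    """Build the toy chain; see :class:`ToyStructure.build` for the rich form."""
    s = ToyStructure.build(arch)
    return s.topology, s.frame


def _rotation_matrix(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    ax = np.asarray(axis, dtype=float)
    n = np.linalg.norm(ax)
    if n < 1e-12:
        return np.eye(3)
    ax = ax / n
    th = math.radians(angle_deg)
    K = np.array(
        [[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]]
    )
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


@dataclass(frozen=True)
class Placement:
    """Rigid placement of the appended domain about the hinge pivot."""

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        return _rotation_matrix(self.axis, self.angle_deg)


@dataclass(frozen=True)
class StateMixture:
    """Weighted mixture of interdomain placements.

    ``transition``: ``"iid"`` draws the state independently per frame;
    ``"markov"`` runs a stationary chain that switches to a fresh
    weight-proportional draw with probability ``switch_probability``.
    """

    states: tuple[Placement, ...]
    weights: tuple[float, ...]
    transition: str = "iid"
    switch_probability: float = 0.1

    def __post_init__(self) -> None:
        if len(self.states) != len(self.weights) or not self.states:
            raise ValueError("states and weights must be matched and nonempty")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("weights must be >= 0 and sum to 1")
        if self.transition not in ("iid", "markov"):
            raise ValueError("transition must be 'iid' or 'markov'")


@dataclass(frozen=True)
class NoiseModel:
    """Isotropic per-atom Gaussian noise: one σ for the domains (internal
    rigidity), one for the linker residues (flexibility), both in nm."""

    domain_sigma: float = 0.02
    linker_sigma: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_sigma < 0 or self.linker_sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class HingeSimulation:
    """A generated trajectory plus its ground truth."""

    trajectory: Trajectory
    states: np.ndarray  # per-frame mixture-state index
    mixture: StateMixture
    noise: NoiseModel

    def truth_dict(self) -> dict:
        return {
            "states": self.states.tolist(),
            "weights": list(self.mixture.weights),
            "transition": self.mixture.transition,
            "domain_sigma": self.noise.domain_sigma,
            "linker_sigma": self.noise.linker_sigma,
            "seed": self.noise.seed,
        }


def simulate_hinge_trajectory(
    structure: ToyStructure,
    mixture: StateMixture,
    noise: NoiseModel,
    n_frames: int,
    dt: float = 100.0,
    label: ProvenanceLabel | None = None,
) -> HingeSimulation:
    """Draw a mixture state per frame, place the appended domain, add noise.

    Deterministic for fixed parameters and seed; the per-frame state
    sequence is returned as ground truth.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(noise.seed)
    w = np.asarray(mixture.weights, dtype=float)
    n_states = len(mixture.states)

    if mixture.transition == "iid":
        states = rng.choice(n_states, size=n_frames, p=w)
    else:
        states = np.empty(n_frames, dtype=int)
        states[0] = rng.choice(n_states, p=w)
        for f in range(1, n_frames):
            if rng.random() < mixture.switch_probability:
                states[f] = rng.choice(n_states, p=w)
            else:
                states[f] = states[f - 1]

    ref = structure.frame.coords
    mask = structure.appended_atom_mask()
    pivot = structure.pivot
    sigma = structure.region_sigma_per_atom(noise)

    placed = []
    for p in mixture.states:
        coords = ref.copy()
        R = p.matrix()
        coords[mask] = (coords[mask] - pivot) @ R.T + pivot + np.asarray(p.translation)
        placed.append(coords)
    placed = np.array(placed)

    xyz = placed[states]
    if sigma.max() > 0:
        xyz = xyz + rng.standard_normal(xyz.shape) * sigma[None, :, None]
    times = np.arange(n_frames, dtype=float) * dt
    traj = Trajectory(structure.topology, xyz, times, label=label)
    return HingeSimulation(traj, states, mixture, noise)


# ---------------------------------------------------------------------------
# Planted interactions
# ---------------------------------------------------------------------------


def _residue_atom(top: Topology, resid: int, name: str) -> int:
    for i in top.residue_atoms(resid):
        if top.atoms[i].name == name:
            return i
    return top.residue_atoms(resid)[0]


def _planted_frames(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    k = math.ceil(fraction * n)
    if k == 0:
        return np.array([], dtype=int)
    return np.sort(rng.choice(n, size=k, replace=False))


def plant_interaction(
    trajectory: Trajectory,
    donor_residue: int,
    acceptor_residue: int,
    occupancy: float,
    seed: int = 0,
    bonded_distance: float = 0.28,
    broken_distance: float = 0.50,
) -> tuple[Trajectory, np.ndarray]:
    """Plant a donor–acceptor H-bond/contact with exact frame occupancy.

    In a seeded uniform ⌈occupancy·n⌉-frame subset the acceptor residue is
    translated rigidly so the donor-N/acceptor-O distance equals
    ``bonded_distance`` (satisfying the heavy-atom H-bond criterion); in
    every other frame the distance is ``broken_distance``, at least 0.1 nm
    beyond the criterion.  Returns the new trajectory and the planted frame
    indices (the ground truth).
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    top = trajectory.topology
    span = top.residue_span
    for rid in (donor_residue, acceptor_residue):
        if not span[0] <= rid <= span[1]:
            raise ValueError(f"residue {rid} out of topology span {span}")
    rng = np.random.default_rng(seed)
    planted = _planted_frames(trajectory.n_frames, occupancy, rng)
    planted_set = set(planted.tolist())

    d_idx = _residue_atom(top, donor_residue, "N")
    a_idx = _residue_atom(top, acceptor_residue, "O")
    acc_atoms = np.array(top.residue_atoms(acceptor_residue))

    xyz = trajectory.xyz.copy()
    for f in range(trajectory.n_frames):
        dpos = xyz[f, d_idx]
        apos = xyz[f, a_idx]
        direction = apos - dpos
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        target = bonded_distance if f in planted_set else broken_distance
        shift = (dpos + direction * target) - apos
        xyz[f, acc_atoms] += shift
    out = Trajectory(top, xyz, trajectory.times, trajectory.label)
    return out, planted


# ---------------------------------------------------------------------------
# Planted strand segments
# ---------------------------------------------------------------------------

_STRAND_RISE = 0.35  # nm per residue along an extended strand
_STRAND_SEP = 0.60  # nm between paired Cα traces
_HELIX_RADIUS = 0.23
_HELIX_RISE = 0.15
_HELIX_TURN = 100.0  # degrees per residue


def _rewrite_residue(
    top: Topology, xyz: np.ndarray, frame: int, resid: int, ca: np.ndarray, flip: bool
) -> None:
    sgn = -1.0 if flip else 1.0
    for i in top.residue_atoms(resid):
        name = top.atoms[i].name
        if name == "CA":
            xyz[frame, i] = ca
        elif name == "N":
            xyz[frame, i] = ca + sgn * np.array([-0.08, 0.18, 0.0])
        elif name == "O":
            xyz[frame, i] = ca + sgn * np.array([0.08, 0.18, 0.0])
        elif name == "C":
            xyz[frame, i] = ca + sgn * np.array([0.10, 0.05, 0.0])
        else:
            xyz[frame, i] = ca


def plant_strand_segment(
    trajectory: Trajectory,
    residue_range: tuple[int, int],
    fraction: float,
    partner_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Plant antiparallel β geometry on a segment with exact frame fraction.

    In a seeded ⌈fraction·n⌉-frame subset the segment and a partner
    segment adopt an ideal antiparallel ladder (every backbone N···O rung
    within H-bond range); in every other frame the segment is rewritten as
    an ideal α-helix (no inter-strand rungs).  The partner defaults to the
    equally long stretch starting three residues past the segment.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    top = trajectory.topology
    lo, hi = residue_range
    n_res = hi - lo + 1
    if partner_range is None:
        partner_range = (hi + 3, hi + 2 + n_res)
    plo, phi = partner_range
    if phi - plo + 1 != n_res:
        raise ValueError("partner range must match segment length")
    span = top.residue_span
    if lo < span[0] or phi > span[1]:
        raise ValueError("segment/partner outside topology span")
    for rid in list(range(lo, hi + 1)) + list(range(plo, phi + 1)):
        names = {top.atoms[i].name for i in top.residue_atoms(rid)}
        if not {"N", "CA", "C", "O"} <= names:
            raise ValueError(f"residue {rid} lacks backbone atoms N/CA/C/O")

    rng = np.random.default_rng(seed)
    planted = _planted_frames(trajectory.n_frames, fraction, rng)
    planted_set = set(planted.tolist())

    base = trajectory.xyz[:, :, :].min(axis=(0, 1)) - np.array([0.0, 5.0, 5.0])
    xyz = trajectory.xyz.copy()
    helix_start = trajectory.xyz[0, top.ca_index(lo)].copy()

    for f in range(trajectory.n_frames):
        if f in planted_set:
            for k, rid in enumerate(range(lo, hi + 1)):
                ca = base + np.array([_STRAND_RISE * k, 0.0, 0.0])
                _rewrite_residue(top, xyz, f, rid, ca, flip=False)
            for k, rid in enumerate(range(phi, plo - 1, -1)):
                ca = base + np.array([_STRAND_RISE * k, _STRAND_SEP, 0.0])
                _rewrite_residue(top, xyz, f, rid, ca, flip=True)
        else:
            for k, rid in enumerate(range(lo, hi + 1)):
                th = math.radians(_HELIX_TURN * k)
                ca = helix_start + np.array(
                    [
                        _HELIX_RADIUS * math.cos(th),
                        _HELIX_RADIUS * math.sin(th),
                        _HELIX_RISE * k,
                    ]
                )
                for i in top.residue_atoms(rid):
                    name = top.atoms[i].name
                    if name == "N":
                        xyz[f, i] = ca + np.array([0.0, 0.0, 0.05])
                    elif name == "O":
                        xyz[f, i] = ca + np.array([0.0, 0.0, -0.05])
                    elif name == "C":
                        xyz[f, i] = ca + np.array([0.0, 0.0, -0.02])
                    else:
                        xyz[f, i] = ca
    out = Trajectory(top, xyz, trajectory.times, trajectory.label)
    return out, planted
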