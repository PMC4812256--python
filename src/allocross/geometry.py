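"""Superposition, RMSD, centre-of-mass clouds, pair distances and dihedrals.

The central object here is the :class:`COMCloud`: after least-squares
fitting every frame on a fixed anchor domain (for DnaK, the NBD Cα atoms),
the centre of mass of the mobile domain (the SBD) traces a point cloud
whose spread quantifies the flexibility of the interdomain arrangement.
Two summaries of that cloud are used: the distribution of distances from
the starting position, and the distribution of all point-pair distances.

Internal units are nm; distance *distributions* are reported in Å because
that is how interdomain distances are quoted in the structural literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Frame, MetaTrajectory, ProvenanceLabel, Selection, Topology, Trajectory

__all__ = [
    "kabsch_fit",
    "apply_transform",
    "com",
    "com_cloud",
    "COMCloud",
    "DistanceDistribution",
    "distance_from_start",
    "pair_distance_distribution",
    "residue_pair_distance_series",
    "dihedral",
    "dihedral_series",
    "DihedralSeries",
    "circular_mean",
    "rmsd_series",
]

NM_TO_ANGSTROM = 10.0


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of two matched point sets.

    Returns ``(R, t, rmsd)`` such that ``x @ R.T + t`` maps mobile points
    onto the reference with minimal (weighted) RMSD.  ``R`` is always a
    proper rotation (det +1).  Degenerate point sets (fewer than 3 points,
    all collinear or coincident) are rejected.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points to define a superposition")
    if weights is None:
        w = np.ones(P.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    P0 = P - cp
    Q0 = Q - cq
    # collinearity/coincidence check on the mobile set
    sv = np.linalg.svd(P0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-30) or sv[0] < 1e-12:
        raise ValueError("degenerate (collinear or coincident) point set")
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ np.asarray(R).T + np.asarray(t)


# ---------------------------------------------------------------------------
# Centre of mass
# ---------------------------------------------------------------------------


def com(
    frame: Frame | np.ndarray,
    selection: Selection,
    topology: Topology | None = None,
    weighting: str = "mass",
) -> np.ndarray:
    """Centre of mass (default) or geometric centre of a selection, in nm."""
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame)
    idx = selection.indices
    if len(idx) == 0:
        raise ValueError("empty selection")
    if weighting == "mass":
        if topology is None:
            raise ValueError("mass weighting needs a topology")
        w = topology.masses[idx]
        total = w.sum()
        if total <= 0:
            raise ValueError("zero total mass in selection")
        return (w[:, None] * coords[idx]).sum(axis=0) / total
    if weighting == "geometric":
        return coords[idx].mean(axis=0)
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class COMCloud:
    """Mobile-domain COM positions (nm) after fitting each frame on the anchor.

    ``reference`` is the COM of the same selection in the starting
    structure; ``labels`` carries one provenance label per point.
    """

    points: np.ndarray
    reference: np.ndarray
    labels: list[ProvenanceLabel | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.reference = np.asarray(self.reference, dtype=float).reshape(3)
        if not self.labels:
            self.labels = [None] * len(self.points)
        if len(self.labels) != len(self.points):
            raise ValueError("one label per point required")

    def __len__(self) -> int:
        return len(self.points)

    def distances_from_start(self) -> np.ndarray:
        """Per-point distance from the starting COM, in Å."""
        return (
            np.linalg.norm(self.points - self.reference, axis=1) * NM_TO_ANGSTROM
        )

    def subset(self, mask: np.ndarray) -> "COMCloud":
        mask = np.asarray(mask, dtype=bool)
        return COMCloud(
            self.points[mask],
            self.reference,
            [l for l, m in zip(self.labels, mask) if m],
        )


def com_cloud(
    runs: Sequence[Trajectory],
    fit_selection: Selection,
    com_selection: Selection,
    reference: tuple[Topology, Frame],
) -> COMCloud:
    """Fit every frame of every run on the anchor selection, then track the COM.

    Runs are merged in order; each point keeps its run's provenance label.
    """
    if not runs:
        raise ValueError("no runs given (empty retained window)")
    ref_top, ref_frame = reference
    fit_selection.validate(ref_top)
    com_selection.validate(ref_top)
    ref_fit = ref_frame.coords[fit_selection.indices]
    ref_point = com(ref_frame, com_selection, ref_top)
    points, labels = [], []
    for traj in runs:
        if traj.n_frames == 0:
            raise ValueError("empty retained window in one run")
        for i in range(traj.n_frames):
            xyz = traj.xyz[i]
            R, t, _ = kabsch_fit(xyz[fit_selection.indices], ref_fit)
            fitted = apply_transform(xyz, R, t)
            points.append(com(fitted, com_selection, traj.topology))
            labels.append(traj.label)
    return COMCloud(np.array(points), ref_point, labels)


# ---------------------------------------------------------------------------
# Distance distributions
# ---------------------------------------------------------------------------


@dataclass
class DistanceDistribution:
    """Histogram of distances in Å, with the mean and the modal-bin centre.

    Bin edges are aligned so that bin centres fall on integer multiples of
    the bin width (the first bin is centred on 0); ties between equally
    populated bins resolve toward the smaller distance.
    """

    edges: np.ndarray
    counts: np.ndarray
    mean: float
    peak: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def modes(self, min_separation: float = 0.0) -> list[float]:
        """Bin centres of local maxima, by decreasing count then distance."""
        c = self.counts
        idx = [
            i
            for i in range(len(c))
            if c[i] > 0
            and (i == 0 or c[i] >= c[i - 1])
            and (i == len(c) - 1 or c[i] >= c[i + 1])
        ]
        idx.sort(key=lambda i: (-c[i], self.centers[i]))
        out: list[float] = []
        for i in idx:
            center = float(self.centers[i])
            if all(abs(center - o) > min_separation for o in out):
                out.append(center)
        return out


def _histogram(distances: np.ndarray, bin_width: float) -> DistanceDistribution:
    d = np.asarray(distances, dtype=float)
    hi = float(d.max()) if len(d) else 0.0
    n_bins = int(np.floor(hi / bin_width + 0.5)) + 1
    edges = (np.arange(n_bins + 1) - 0.5) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    peak_bin = int(np.argmax(counts))  # argmax takes the first == smaller distance
    peak = float((edges[peak_bin] + edges[peak_bin + 1]) / 2.0)
    return DistanceDistribution(
        edges=edges, counts=counts, mean=float(d.mean()), peak=peak
    )


def distance_from_start(cloud: COMCloud, bin_width: float = 1.0) -> DistanceDistribution:
    """Histogram of COM distances from the starting position (Å)."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    return _histogram(cloud.distances_from_start(), bin_width)


def pair_distance_distribution(
    cloud: COMCloud,
    bin_width: float = 1.0,
    max_points: int = 50_000,
    seed: int = 0,
) -> DistanceDistribution:
    """Histogram of all unordered point-pair distances of the cloud (Å).

    Above ``max_points`` points a seeded uniform subsample is used, since
    exhaustive pairs grow quadratically.
    """
    pts = cloud.points
    if len(pts) < 2:
        raise ValueError("need at least 2 points for pair distances")
    if len(pts) > max_points:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=max_points, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(pts) * NM_TO_ANGSTROM
    return _histogram(d, bin_width)


# ---------------------------------------------------------------------------
# Residue-pair distances
# ---------------------------------------------------------------------------


def residue_pair_distance_series(
    trajectory: Trajectory,
    residue_i: int,
    residue_j: int,
    atom_rule: str = "ca",
) -> tuple[np.ndarray, float]:
    """Per-frame distance (Å) between two residues, plus its time average.

    ``atom_rule``: ``"ca"`` measures Cα–Cα; ``"closest-heavy"`` the minimum
    distance over heavy-atom pairs in each frame.
    """
    top = trajectory.topology
    if atom_rule == "ca":
        try:
            ai = top.ca_index(residue_i)
            aj = top.ca_index(residue_j)
        except KeyError as exc:
            raise ValueError(f"missing CA atom for residue {exc}") from None
        d = np.linalg.norm(
            trajectory.xyz[:, ai] - trajectory.xyz[:, aj], axis=1
        )
    elif atom_rule == "closest-heavy":
        hi = [i for i in top.residue_atoms(residue_i) if not top.atoms[i].is_hydrogen]
        hj = [j for j in top.residue_atoms(residue_j) if not top.atoms[j].is_hydrogen]
        if not hi or not hj:
            raise ValueError("no heavy atoms under closest-heavy rule")
        diff = trajectory.xyz[:, hi, None, :] - trajectory.xyz[:, None, hj, :]
        d = np.sqrt((diff**2).sum(-1)).min(axis=(1, 2))
    else:
        raise ValueError(f"unknown atom rule {atom_rule!r}")
    d = d * NM_TO_ANGSTROM
    return d, float(d.mean())


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (−180, 180].

    Returns NaN (with a warning) when three consecutive atoms are collinear.
    """
    b0 = np.asarray(p0) - np.asarray(p1)  # points back along the first bond
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        warnings.warn("collinear atoms in dihedral; returning NaN", stacklevel=2)
        return float("nan")
    b1u = b1 / nb1
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(w) < 1e-12:
        warnings.warn("collinear atoms in dihedral; returning NaN", stacklevel=2)
        return float("nan")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def circular_mean(angles_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean (deg, in (−180, 180]) and circular variance 1−R.

    Computed from the mean resultant vector, so {+170°, −170°} averages to
    180°, not 0°.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    a = a[np.isfinite(a)]
    if len(a) == 0:
        return float("nan"), float("nan")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    R = float(np.hypot(s, c))
    mean = float(np.degrees(np.arctan2(s, c)))
    if mean <= -180.0:
        mean += 360.0
    if mean == -0.0:
        mean = 0.0
    # map atan2(0, -1) → +180 explicitly
    if abs(mean + 180.0) < 1e-12:
        mean = 180.0
    return mean, 1.0 - R


@dataclass
class DihedralSeries:
    """Per-frame dihedral angles (deg) with circular mean and variance."""

    angles: np.ndarray
    circ_mean: float
    circ_variance: float

    def __len__(self) -> int:
        return len(self.angles)


def dihedral_series(
    trajectory: Trajectory, atom_indices: Sequence[int]
) -> DihedralSeries:
    """Dihedral over four atoms for every frame of a trajectory."""
    idx = list(atom_indices)
    if len(idx) != 4 or len(set(idx)) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    angles = np.array(
        [
            dihedral(
                trajectory.xyz[f, idx[0]],
                trajectory.xyz[f, idx[1]],
                trajectory.xyz[f, idx[2]],
                trajectory.xyz[f, idx[3]],
            )
            for f in range(trajectory.n_frames)
        ]
    )
    m, v = circular_mean(angles)
    return DihedralSeries(angles=angles, circ_mean=m, circ_variance=v)


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------


def rmsd_series(
    traj_a: Trajectory,
    reference: Trajectory | Frame,
    selection: Selection,
    fit_selection: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (nm) over ``selection`` after fitting on ``fit_selection``.

    Against a single reference :class:`Frame`, every frame of ``traj_a`` is
    compared to it; against a matched-length :class:`Trajectory`, frames are
    compared pairwise (frame i vs frame i).
    """
    fit_sel = fit_selection if fit_selection is not None else selection
    sel = selection.indices
    fidx = fit_sel.indices

    def one(xa: np.ndarray, xb: np.ndarray) -> float:
        R, t, _ = kabsch_fit(xa[fidx], xb[fidx])
        moved = apply_transform(xa[sel], R, t)
        diff = moved - xb[sel]
        return float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))

    if isinstance(reference, Frame):
        return np.array(
            [one(traj_a.xyz[i], reference.coords) for i in range(traj_a.n_frames)]
        )
    if reference.n_frames != traj_a.n_frames:
        raise ValueError(
            f"pairwise mode needs matched lengths ({traj_a.n_frames} vs "
            f"{reference.n_frames})"
        )
    return np.array(
        [one(traj_a.xyz[i], reference.xyz[i]) for i in range(traj_a.n_frames)]
    )
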