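"""Conformational clustering: RMSD matrices, the gromos algorithm, and
decomposition of cluster populations by ligand-state label.

The gromos method (Daura-style greedy neighbour counting) is the classic
conformational clustering used on MD ensembles: among unassigned frames,
the one with most neighbours within an RMSD cutoff becomes a cluster
centre, it and its neighbours are removed, and the step repeats.  Applied
to a *meta-trajectory* (concatenated tails of runs from different ligand
states) it yields clusters that can then be decomposed back into per-state
population fractions — the statistic used to read off which ligand drives
which conformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Frame, MetaTrajectory, Selection, Trajectory

__all__ = [
    "RMSDMatrix",
    "ClusterResult",
    "DecompositionTable",
    "rmsd_matrix",
    "gromos_cluster",
    "decompose_by_label",
    "representative",
    "SUBSET_PRESETS",
]

#: Named residue-subset presets for cluster analyses of a DnaK-numbered
#: topology: the NBD-side linker stretch, the linker-βSBD stretch (with the
#: shorter alternative interval), the β-sandwich subdomain, and the whole
#: chain.  Values are ((first, last) or None for all residues, cutoff nm).
SUBSET_PRESETS: dict[str, tuple[tuple[int, int] | None, float]] = {
    "linker-nbd": ((373, 393), 0.35),
    "linker-bsbd": ((393, 433), 0.35),
    "linker-bsbd-short": ((393, 413), 0.35),
    "bsbd": ((393, 503), 0.15),
    "whole": (None, 0.35),
}


@dataclass
class RMSDMatrix:
    """Symmetric frame×frame RMSD matrix in nm."""

    values: np.ndarray
    provenance: str = ""
    fitted: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump({"provenance": self.provenance, "fitted": self.fitted}, fh)


def rmsd_matrix(
    meta: MetaTrajectory | Trajectory,
    selection: Selection,
    fit: bool = True,
) -> RMSDMatrix:
    """All-against-all RMSD over a selection, Kabsch-fitted on it by default.

    With ``fit=False`` no superposition is applied (raw coordinate RMSD),
    so a rigidly rotated copy of a frame scores nonzero.
    """
    selection.validate(meta.topology)
    sel = selection.indices
    if len(sel) < 3:
        raise ValueError("selection too small for superposition")
    xyz = meta.xyz[:, sel, :]
    n = xyz.shape[0]
    if fit:
        # batched Kabsch: centre each frame, then per reference frame solve
        # all 3×3 covariance SVDs at once (proper-rotation sign correction)
        X = xyz - xyz.mean(axis=1, keepdims=True)
        g = np.einsum("fni,fni->f", X, X)
        n_sel = X.shape[1]
        M = np.zeros((n, n), dtype=float)
        for i in range(n):
            H = np.einsum("ni,fnj->fij", X[i], X[i:])
            U, S, Vt = np.linalg.svd(H)
            sign = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
            trace = S[:, 0] + S[:, 1] + sign * S[:, 2]
            msd = (g[i] + g[i:] - 2.0 * trace) / n_sel
            M[i, i:] = np.sqrt(np.clip(msd, 0.0, None))
        M = M + M.T
    else:
        X = xyz.reshape(n, -1)
        g = np.einsum("ij,ij->i", X, X)
        G = X @ X.T
        D2 = (g[:, None] + g[None, :] - 2.0 * G) / len(sel)
        M = np.sqrt(np.clip(D2, 0.0, None))
    np.fill_diagonal(M, 0.0)
    return RMSDMatrix(M, provenance=selection.provenance, fitted=fit)


@dataclass
class ClusterResult:
    """Partition of frames: 1-based cluster ids ordered by decreasing size."""

    assignment: np.ndarray  # frame -> cluster id, 1-based
    centers: list[int]  # medoid frame index per cluster (index 0 = cluster 1)
    populations: np.ndarray  # fraction per cluster, sums to 1
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.where(self.assignment == cluster_id)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": np.arange(1, self.n_clusters + 1),
                "center_frame": self.centers,
                "population": self.populations,
            }
        )


def gromos_cluster(matrix: RMSDMatrix, cutoff: float) -> ClusterResult:
    """Greedy neighbour-counting clustering at an RMSD cutoff.

    Iteratively, every unassigned frame counts its unassigned neighbours
    within ``cutoff`` (itself included); the frame with most neighbours —
    ties broken by lowest frame index — seeds a cluster consisting of
    itself and those neighbours, which are then removed.  Clusters are
    renumbered by decreasing size (ties: earlier formation first).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    M = matrix.values
    n = M.shape[0]
    adj = M <= cutoff
    np.fill_diagonal(adj, True)
    unassigned = np.ones(n, dtype=bool)
    raw: list[tuple[int, np.ndarray]] = []
    while unassigned.any():
        idxs = np.where(unassigned)[0]
        counts = adj[np.ix_(idxs, idxs)].sum(axis=1)
        best = idxs[int(np.argmax(counts))]  # argmax → lowest index on ties
        members = idxs[adj[best, idxs]]
        raw.append((int(best), members))
        unassigned[members] = False
    order = sorted(range(len(raw)), key=lambda k: (-len(raw[k][1]), k))
    assignment = np.zeros(n, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    for new_id, k in enumerate(order, start=1):
        center, members = raw[k]
        assignment[members] = new_id
        centers.append(center)
        sizes.append(len(members))
    populations = np.array(sizes, dtype=float) / n
    return ClusterResult(assignment, centers, populations, cutoff)


@dataclass
class DecompositionTable:
    """Cluster populations split by source label, normalised per label.

    Rows are ligand-state keys, columns ``cluster_1..k`` plus ``rest``;
    each row sums to 1 over its label's frames.
    """

    table: pd.DataFrame
    top_k: int

    def row(self, label_key: str) -> pd.Series:
        return self.table.loc[label_key]


def decompose_by_label(
    result: ClusterResult, meta: MetaTrajectory, top_k: int = 3
) -> DecompositionTable:
    """Per-label fractions of frames in each of the top-k clusters + remainder."""
    if len(result.assignment) != meta.n_frames:
        raise ValueError("assignment does not cover the meta-trajectory")
    if top_k > result.n_clusters:
        import warnings

        warnings.warn(
            f"top_k={top_k} exceeds cluster count {result.n_clusters}; clamping",
            stacklevel=2,
        )
        top_k = result.n_clusters
    keys = meta.state_keys()
    df = pd.DataFrame({"label": keys, "cluster": result.assignment})
    rows = {}
    for key, sub in df.groupby("label", sort=True):
        n = len(sub)
        frac = {
            f"cluster_{c}": float((sub["cluster"] == c).sum()) / n
            for c in range(1, top_k + 1)
        }
        frac["rest"] = 1.0 - sum(frac.values())
        rows[key] = frac
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "label"
    return DecompositionTable(table=table, top_k=top_k)


def medoid_frame(
    result: ClusterResult, cluster_id: int, matrix: RMSDMatrix
) -> int:
    """Cluster member minimising summed RMSD to all members (ties: lowest index)."""
    members = result.members(cluster_id)
    sums = matrix.values[np.ix_(members, members)].sum(axis=1)
    return int(members[int(np.argmin(sums))])


def representative(
    result: ClusterResult,
    cluster_id: int,
    meta: MetaTrajectory | Trajectory,
    matrix: RMSDMatrix | None = None,
) -> Frame:
    """The representative conformation of a cluster.

    With the RMSD matrix available this is the medoid (the member with
    minimal summed RMSD to all members); otherwise the stored gromos
    seeding centre is returned.  The two coincide on well-separated
    clusters but can differ on adversarial matrices.
    """
    if not 1 <= cluster_id <= result.n_clusters:
        raise ValueError(f"no cluster {cluster_id} (have {result.n_clusters})")
    if matrix is not None:
        idx = medoid_frame(result, cluster_id, matrix)
    else:
        idx = result.centers[cluster_id - 1]
    return Frame(meta.xyz[idx].copy())
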