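"""Independent reference implementations used only to check the package.

These deliberately share no code with ``allocross``: the clustering oracle
is plain-Python greedy neighbour counting, the superposition oracle
minimises RMSD numerically over rotations, and the dihedral oracle uses
the two-plane-normal formula.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def gromos_brute(matrix: np.ndarray, cutoff: float):
    """Greedy neighbour-counting clustering, written with plain loops.

    Returns (assignment 1-based by decreasing size, centers, populations).
    """
    n = matrix.shape[0]
    unassigned = set(range(n))
    raw = []
    while unassigned:
        best, best_neighbors = None, None
        for i in sorted(unassigned):
            neigh = [j for j in sorted(unassigned) if matrix[i, j] <= cutoff or i == j]
            if best is None or len(neigh) > len(best_neighbors):
                best, best_neighbors = i, neigh
        raw.append((best, best_neighbors))
        unassigned -= set(best_neighbors)
    order = sorted(range(len(raw)), key=lambda k: (-len(raw[k][1]), k))
    assignment = [0] * n
    centers, pops = [], []
    for new_id, k in enumerate(order, start=1):
        center, members = raw[k]
        for m in members:
            assignment[m] = new_id
        centers.append(center)
        pops.append(len(members) / n)
    return np.array(assignment), centers, np.array(pops)


def rmsd_at_rotation(P: np.ndarray, Q: np.ndarray, R: np.ndarray) -> float:
    """RMSD of centred P rotated by R against centred Q."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    d = P0 @ R.T - Q0
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def grid_rmsd_oracle(P: np.ndarray, Q: np.ndarray, coarse: int = 16) -> float:
    """Minimum RMSD over rotations: coarse grid over rotation vectors,
    then Nelder–Mead refinement from the best grid points."""
    candidates = [(rmsd_at_rotation(P, Q, np.eye(3)), np.zeros(3))]
    angles = np.linspace(-np.pi, np.pi, coarse, endpoint=False)
    mags = np.linspace(0.1, np.pi, 8)
    for th in angles:
        for ph in np.linspace(0, np.pi, coarse // 2):
            axis = np.array(
                [np.sin(ph) * np.cos(th), np.sin(ph) * np.sin(th), np.cos(ph)]
            )
            for m in mags:
                v = axis * m
                r = rmsd_at_rotation(P, Q, Rotation.from_rotvec(v).as_matrix())
                candidates.append((r, v))
    candidates.sort(key=lambda c: c[0])

    def f(v):
        return rmsd_at_rotation(P, Q, Rotation.from_rotvec(v).as_matrix())

    best = candidates[0][0]
    for _, v0 in candidates[:8]:
        res = minimize(f, v0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 10000})
        best = min(best, float(res.fun))
    return best


def dihedral_cross_oracle(p0, p1, p2, p3) -> float:
    """Signed dihedral via plane normals n1 = b0×b1, n2 = b1×b2."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang
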