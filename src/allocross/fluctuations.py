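"""Distance-fluctuation (coordination) maps.

For residues *i*, *j* with Cα–Cα distance :math:`d_{ij}(t)`, the map entry
is the temporal fluctuation of that distance,

.. math:: A_{ij} = \\langle d_{ij}^2 \\rangle - \\langle d_{ij} \\rangle^2 ,

i.e. the variance of the inter-residue distance over the trajectory (a
standard-deviation variant is available via ``statistic="std"``).  Low
values mark residue pairs that move in coordination — rigid blocks — so
*decreases* in a difference map signal ligand-induced rigidification.
Being built from internal distances, the map is exactly invariant under
global rigid motion of every frame.

Accumulation is streaming (sums of d and d² per pair, shifted by the
first-frame distances for numerical stability), so memory scales with the
selection squared, not with trajectory length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import MetaTrajectory, Trajectory

__all__ = [
    "DFMap",
    "distance_fluctuation_map",
    "df_difference",
    "coordination_score",
]


@dataclass
class DFMap:
    """Symmetric residue×residue distance-fluctuation matrix (nm²)."""

    values: np.ndarray
    residues: list[int]
    statistic: str = "variance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.residues):
            raise ValueError("matrix must be square over the residue list")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.residues, columns=self.residues)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="residue")

    def _pos(self, residues: Sequence[int]) -> np.ndarray:
        lookup = {r: k for k, r in enumerate(self.residues)}
        try:
            return np.array([lookup[r] for r in residues], dtype=int)
        except KeyError as exc:
            raise ValueError(f"residue {exc} not in map selection") from None


def distance_fluctuation_map(
    trajectory: Trajectory | MetaTrajectory,
    residues: Sequence[int] | None = None,
    statistic: str = "variance",
) -> DFMap:
    """Distance-fluctuation map over the Cα atoms of ``residues``.

    ``statistic`` is ``"variance"`` (default, nm²) or ``"std"`` (nm).
    Requires at least two frames and a Cα for every selected residue.
    """
    if statistic not in ("variance", "std"):
        raise ValueError("statistic must be 'variance' or 'std'")
    top = trajectory.topology
    if residues is None:
        residues = top.residue_ids
    residues = list(residues)
    missing = [r for r in residues if not top.has_ca(r)]
    if missing:
        raise ValueError(f"residues without a unique CA atom: {missing}")
    n_frames = trajectory.n_frames
    if n_frames < 2:
        raise ValueError("need at least two frames")
    ca = np.array([top.ca_index(r) for r in residues])

    d0 = pdist(trajectory.xyz[0][ca])
    s1 = np.zeros_like(d0)
    s2 = np.zeros_like(d0)
    for f in range(n_frames):
        delta = pdist(trajectory.xyz[f][ca]) - d0
        s1 += delta
        s2 += delta * delta
    var = s2 / n_frames - (s1 / n_frames) ** 2
    var = np.clip(var, 0.0, None)
    values = squareform(var if statistic == "variance" else np.sqrt(var))
    return DFMap(values, residues, statistic=statistic)


def df_difference(map_a: DFMap, map_b: DFMap) -> np.ndarray:
    """Elementwise A − B; negative entries mean higher coordination in A."""
    if map_a.residues != map_b.residues:
        raise ValueError("maps cover different residue selections")
    if map_a.statistic != map_b.statistic:
        raise ValueError("maps use different statistics")
    return map_a.values - map_b.values


def coordination_score(
    dfmap: DFMap, block_a: Sequence[int], block_b: Sequence[int]
) -> float:
    """Mean fluctuation over the inter-block rectangle (lower = coordinated)."""
    ia = dfmap._pos(block_a)
    ib = dfmap._pos(block_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("blocks must be nonempty")
    rect = dfmap.values[np.ix_(ia, ib)]
    same = np.isin(ia, ib)
    if same.any():
        # exclude the zero diagonal cells shared by overlapping blocks
        mask = np.ones_like(rect, dtype=bool)
        for x, r in enumerate(ia):
            for y, s in enumerate(ib):
                if r == s:
                    mask[x, y] = False
        return float(rect[mask].mean())
    return float(rect.mean())
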