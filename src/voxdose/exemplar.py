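"""Exemplar / anti-exemplar selection via NCC similarity and affinity propagation.

The registration template for a cohort is chosen as the most representative
image: pairwise normalized cross-correlation (Pearson correlation of voxel
values, optionally within a crop mask) fills a similarity matrix, affinity
propagation clusters it, and the exemplar is the cluster center with the
largest net similarity to all items.  The anti-exemplar — the item least
similar to the exemplar — serves as a template for testing sensitivity to
reference geometry.  Externally computed similarity matrices (e.g. from a
registration pipeline) can be supplied as CSV in place of image NCC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation

from .grid_io import GridError, VoxelGrid, flatten_masked


class ConvergenceFailure(RuntimeError):
    """Affinity propagation failed to converge (oscillation diagnostic)."""


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    item_ids: list[str]
    kind: str = "ncc"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric within 1e-9")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids, columns=self.item_ids)


def ncc(a: VoxelGrid, b: VoxelGrid, crop: VoxelGrid | None = None) -> float:
    """Normalized cross-correlation: Pearson r of voxel values (within crop)."""
    if not a.is_compatible(b):
        raise GridError("grids incompatible for NCC")
    if crop is not None:
        va, _ = flatten_masked(a, crop)
        vb, _ = flatten_masked(b, crop)
    else:
        va = a.data.ravel(order="F").astype(float)
        vb = b.data.ravel(order="F").astype(float)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero-variance input to NCC")
    return float(np.corrcoef(va, vb)[0, 1])


def similarity_matrix(
    grids: Sequence[VoxelGrid],
    item_ids: Sequence[str] | None = None,
    crop: VoxelGrid | None = None,
) -> SimilarityMatrix:
    n = len(grids)
    ids = list(item_ids) if item_ids is not None else [f"item{i}" for i in range(n)]
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = ncc(grids[i], grids[j], crop)
    return SimilarityMatrix(S, ids)


def brute_force_medoid(sim: SimilarityMatrix) -> int:
    """Oracle: argmax of similarity column sums (the net-similarity medoid)."""
    return int(np.argmax(sim.values.sum(axis=0)))


def affinity_propagation_exemplar(
    sim: SimilarityMatrix,
    preference: float | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 50,
) -> tuple[int, np.ndarray]:
    """Exemplar index and full cluster assignment.

    Preference defaults to the median off-diagonal similarity.  When several
    exemplars emerge, the one with the largest net similarity to all items is
    returned.  Deterministic given the inputs.
    """
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must lie in [0.5, 1)")
    n = sim.n
    if n == 1:
        return 0, np.zeros(1, dtype=int)
    if preference is None:
        off = sim.values[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    ap = AffinityPropagation(affinity="precomputed", damping=damping,
                             max_iter=max_iter, convergence_iter=convergence_window,
                             preference=preference, random_state=0)
    labels = ap.fit_predict(sim.values)
    centers = np.asarray(ap.cluster_centers_indices_)
    if centers is None or centers.size == 0 or np.any(labels < 0):
        raise ConvergenceFailure(
            f"affinity propagation did not converge in {max_iter} iterations "
            f"(damping={damping}); messages may be oscillating")
    net = sim.values.sum(axis=0)
    exemplar = int(centers[np.argmax(net[centers])])
    return exemplar, labels


def select_anti_exemplar(sim: SimilarityMatrix, exemplar_index: int) -> int:
    """The item least similar to the exemplar (ties to lowest index)."""
    if sim.n < 2:
        raise ValueError("anti-exemplar requires >= 2 items")
    row = sim.values[exemplar_index].copy()
    row[exemplar_index] = np.inf
    return int(np.argmin(row))
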