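"""Voxel-based dose-difference max-statistic permutation test.

Patients are split into with- and without-toxicity groups; at every masked
voxel the mean dose difference is locally normalized by the pooled
two-sample standard error (a pooled-variance t-type statistic).  Group
labels are randomly permuted (n_perm times, group sizes preserved) and the
maximum statistic over the mask is recorded for each permutation, giving a
null distribution of the max that controls the family-wise error rate over
voxels.  The critical value T_alpha is the (1 - alpha) percentile of that
null distribution (ceiling-rank order statistic); voxels whose observed
statistic strictly exceeds T_alpha are significant at level alpha.  The
observed-max permutation p uses the add-one estimator (1 + b) / (n_perm + 1).

The default statistic is two-sided (max of |stat|); ``sidedness="greater"``
tests for higher dose in the with-toxicity group only.  Zero-pooled-variance
voxels carry no contrast and get statistic 0.  An exhaustive enumeration
mode provides the exact null on small cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np

from .grid_io import VoxelGrid, cohort_matrix, scatter_to_grid

DEFAULT_ALPHAS = (0.05, 0.1, 0.2, 0.3)
DEFAULT_N_PERM = 1000

Sidedness = Literal["two-sided", "greater"]


@dataclass
class PermutationResult:
    diff_map: VoxelGrid
    stat_map: VoxelGrid
    null_max_stats: np.ndarray
    critical_values: dict[float, float]
    significance_masks: dict[float, VoxelGrid]
    global_p: float
    observed_max: float
    sidedness: Sidedness
    n_perm: int

    def n_significant(self, alpha: float) -> int:
        return int(self.significance_masks[alpha].data.sum())


def _group_stats(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed diff and pooled-t stat per column of X (n_patients x n_voxels)."""
    g1, g0 = X[labels], X[~labels]
    n1, n0 = len(g1), len(g0)
    diff = g1.mean(axis=0) - g0.mean(axis=0)
    sp2 = ((n1 - 1) * g1.var(axis=0, ddof=1) + (n0 - 1) * g0.var(axis=0, ddof=1)) / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return diff, _normalized(diff, se)


def _normalized(diff: np.ndarray, se: np.ndarray) -> np.ndarray:
    """diff/se; fully separated groups (se=0, diff!=0) give +/-inf, and
    voxels with no contrast at all (se=0, diff=0) give 0."""
    stat = np.zeros_like(diff)
    np.divide(diff, se, out=stat, where=se > 0)
    degenerate = (se == 0) & (diff != 0)
    if np.any(degenerate):
        stat = np.where(degenerate, np.sign(diff) * np.inf, stat)
    return stat


def _perm_max_stats(X: np.ndarray, label_matrix: np.ndarray, sidedness: Sidedness) -> np.ndarray:
    """Max statistic per permutation, vectorized over permutations.

    ``label_matrix`` is (n_perm, n_patients) boolean with fixed row sums n1.
    Group means/variances come from two matmuls (sums and sums of squares),
    so the whole null distribution costs two (n_perm x n) @ (n x V) products.
    """
    n = X.shape[0]
    n1 = int(label_matrix[0].sum())
    n0 = n - n1
    L = label_matrix.astype(float)
    tot = X.sum(axis=0)
    tot2 = (X * X).sum(axis=0)
    s1 = L @ X                       # per-perm group-1 sums
    q1 = L @ (X * X)
    s0, q0 = tot - s1, tot2 - q1
    m1, m0 = s1 / n1, s0 / n0
    # unbiased variances from sums/sums-of-squares
    v1 = np.maximum(q1 - n1 * m1 * m1, 0.0) / (n1 - 1)
    v0 = np.maximum(q0 - n0 * m0 * m0, 0.0) / (n0 - 1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    stat = _normalized(diff, se)
    if sidedness == "two-sided":
        stat = np.abs(stat)
    return stat.max(axis=1)


def _check_groups(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each group needs >= 2 patients (got {n1} with, {n0} without)")
    return n1, n0


def voxel_dose_difference(
    doses: Sequence[VoxelGrid], labels: Sequence[bool], mask: VoxelGrid
) -> tuple[VoxelGrid, VoxelGrid]:
    """Observed mean-difference map (Gy) and locally normalized stat map."""
    labels = np.asarray(labels, dtype=bool)
    _check_groups(labels)
    X, index_map = cohort_matrix(doses, mask)
    diff, stat = _group_stats(X, labels)
    tpl = doses[0]
    return (scatter_to_grid(diff, index_map, tpl, "stat"),
            scatter_to_grid(stat, index_map, tpl, "stat"))


def critical_value(null_max: np.ndarray, alpha: float) -> float:
    """(1 - alpha) percentile by the ceiling-rank convention (conservative)."""
    srt = np.sort(null_max)
    k = int(np.ceil((1.0 - alpha) * len(srt)))
    k = min(max(k, 1), len(srt))
    return float(srt[k - 1])


def max_stat_permutation(
    doses: Sequence[VoxelGrid],
    labels: Sequence[bool],
    mask: VoxelGrid,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    sidedness: Sidedness = "two-sided",
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> PermutationResult:
    """Monte-Carlo max-statistic permutation test with FWER control.

    Permutations are uniform random relabelings preserving group sizes,
    sampled with replacement; the test is deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=bool)
    n1, _ = _check_groups(labels)
    X, index_map = cohort_matrix(doses, mask)
    n = X.shape[0]

    diff, stat = _group_stats(X, labels)
    obs_stat = np.abs(stat) if sidedness == "two-sided" else stat
    observed_max = float(obs_stat.max())

    rng = np.random.default_rng(seed)
    label_matrix = np.zeros((n_perm, n), dtype=bool)
    for r in range(n_perm):
        label_matrix[r, rng.choice(n, size=n1, replace=False)] = True
    null_max = _perm_max_stats(X, label_matrix, sidedness)

    tpl = doses[0]
    crits: dict[float, float] = {}
    sig_masks: dict[float, VoxelGrid] = {}
    for a in sorted(alphas):
        T = critical_value(null_max, a)
        crits[a] = T
        sig = (obs_stat > T).astype(np.uint8)
        sig_masks[a] = scatter_to_grid(sig, index_map, tpl, "mask")
    global_p = float((1 + np.sum(null_max >= observed_max)) / (n_perm + 1))

    return PermutationResult(
        diff_map=scatter_to_grid(diff, index_map, tpl, "stat"),
        stat_map=scatter_to_grid(stat, index_map, tpl, "stat"),
        null_max_stats=null_max, critical_values=crits,
        significance_masks=sig_masks, global_p=global_p,
        observed_max=observed_max, sidedness=sidedness, n_perm=n_perm)


def exhaustive_null(
    doses: Sequence[VoxelGrid],
    labels: Sequence[bool],
    mask: VoxelGrid,
    sidedness: Sidedness = "two-sided",
    cap: int = 10_000,
) -> tuple[np.ndarray, float]:
    """Exact null max distribution by enumerating every relabeling.

    Returns ``(null_max_stats, exact_p)`` where the p-value is the fraction
    of relabelings whose max statistic is >= the observed one (the observed
    labeling is itself a member of the enumeration, so p > 0).
    """
    labels = np.asarray(labels, dtype=bool)
    n1, _ = _check_groups(labels)
    X, _ = cohort_matrix(doses, mask)
    n = X.shape[0]
    total = comb(n, n1)
    if total > cap:
        raise ValueError(f"C({n},{n1}) = {total} exceeds enumeration cap {cap}")

    _, stat = _group_stats(X, labels)
    obs = float((np.abs(stat) if sidedness == "two-sided" else stat).max())

    label_matrix = np.zeros((total, n), dtype=bool)
    for r, idx in enumerate(combinations(range(n), n1)):
        label_matrix[r, list(idx)] = True
    null_max = _perm_max_stats(X, label_matrix, sidedness)
    exact_p = float(np.sum(null_max >= obs - 1e-12) / total)
    return null_max, exact_p
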