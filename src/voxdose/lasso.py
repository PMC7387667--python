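"""Multi-voxel L1-penalized Cox regression with cross-validated selection.

All voxel dose variables enter one Cox model as binary median-split
indicators (the same cut-point rule as the per-voxel maps; indicators share
a scale, so columns are not standardized).  An L1 penalty traces a path of
100 penalty values, equally spaced on a linear scale from lambda_max (the
smallest penalty at which no voxel is selected, computed in closed form from
the Breslow score at the null model) down to lambda_max * 1e-3 — selecting
every voxel exactly is unattainable when voxels outnumber events, so the
small-fraction floor stands in for the all-selected end of the path.

Ten-fold cross-validation (folds stratified by event status, seeded) scores
each penalty by the Verweij-van Houwelingen partial-likelihood deviance:
each fold contributes -2 * [loglik(all data) - loglik(training data)]
evaluated at the fold-trained coefficients.  Both the deviance-minimizing
penalty (lambda_star) and the largest penalty within one standard error of
that minimum (lambda_1se) are reported; the default *selection* uses the
one-standard-error convention because the raw CV minimum systematically
overselects noise voxels in this regime (its deviance curve is flat and its
argmin noisy — the behaviour is identical in glmnet), whereas the 1-SE rule
yields the sparse selections, including empty ones, that voxel maps of this
kind actually exhibit.  The model is refit on all data and the non-zero
voxels at the chosen penalty are reported with their HR direction.  An
empty selection is a legitimate outcome.

The coordinate-descent path solver is scikit-survival's Coxnet; the
closed-form lambda_max and the deviance evaluations here are computed
independently of it (both use Breslow tie handling, Coxnet's convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .grid_io import VoxelGrid, cohort_matrix
from .univoxel import NonInformativeVoxel, median_dichotomize

DEFAULT_N_LAMBDA = 100
DEFAULT_N_FOLDS = 10
DEFAULT_MIN_RATIO = 1e-3
COXNET_TOL = 1e-5


@dataclass
class LassoPathResult:
    lambda_grid: np.ndarray
    cv_deviance_mean: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_star: float                    # argmin of mean CV deviance
    lambda_star_index: int
    lambda_1se: float                     # largest penalty within 1 SE of the min
    lambda_1se_index: int
    selection_rule: str                   # "1se" (default) or "min"
    lambda_selected: float                # the penalty the selection used
    coef_path: np.ndarray                 # (n_columns, n_lambda), full-data fit
    selected_columns: np.ndarray          # design-column indices at lambda_selected
    selected_voxel_indices: np.ndarray    # canonical flat voxel indices
    selected_coefs: np.ndarray
    fold_assignment: np.ndarray
    active_counts: np.ndarray
    log: dict = field(default_factory=dict)

    @property
    def selected_hrs(self) -> np.ndarray:
        return np.exp(self.selected_coefs)


def build_design(
    doses: list[VoxelGrid], mask: VoxelGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Patient x voxel matrix of high/low indicators.

    Returns ``(design, kept_voxel_indices, dropped_voxel_indices)`` where the
    indices are canonical flat indices into the template grid.  Constant
    (non-informative) columns are dropped.
    """
    X, index_map = cohort_matrix(doses, mask)
    cols, kept, dropped = [], [], []
    for v in range(X.shape[1]):
        try:
            cols.append(median_dichotomize(X[:, v]))
            kept.append(index_map[v])
        except NonInformativeVoxel:
            dropped.append(index_map[v])
    if not cols:
        raise ValueError("all design columns are constant")
    design = np.column_stack(cols).astype(float)
    return design, np.asarray(kept), np.asarray(dropped)


def _breslow_risk_groups(times: np.ndarray):
    order = np.argsort(times, kind="stable")
    ts = times[order]
    # first index of each tie group, per observation
    first_idx = np.searchsorted(ts, ts, side="left")
    return order, first_idx


def cox_lasso_lambda_max(design: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Smallest penalty with an empty active set (max null-score bound).

    lambda_max = max_j |U_j(0)| / n with U the Breslow partial-likelihood
    score at beta = 0 (matches the glmnet/Coxnet convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() == 0:
        raise ValueError("zero events")
    n = len(times)
    order, first_idx = _breslow_risk_groups(times)
    Xs, es = design[order], events[order]
    risk_sums = np.cumsum(Xs[::-1], axis=0)[::-1]        # sum over {k: t_k >= t_i}
    risk_counts = (n - np.arange(n)).astype(float)
    score = np.sum(Xs[es] - risk_sums[first_idx[es]] / risk_counts[first_idx[es], None],
                   axis=0)
    return float(np.max(np.abs(score)) / n)


def lambda_grid(
    design: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_MIN_RATIO,
    scale: str = "linear",
) -> np.ndarray:
    """Strictly decreasing penalty grid from lambda_max to lambda_max*min_ratio."""
    lmax = cox_lasso_lambda_max(design, np.asarray(times, float), np.asarray(events, bool))
    if scale == "linear":
        return np.linspace(lmax, lmax * min_ratio, n_lambda)
    if scale == "log":
        return np.geomspace(lmax, lmax * min_ratio, n_lambda)
    raise ValueError(f"unknown grid scale {scale!r}")


def cox_partial_loglik(beta: np.ndarray, design: np.ndarray,
                       times: np.ndarray, events: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood at fixed coefficients."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    eta = design @ beta
    order, first_idx = _breslow_risk_groups(times)
    eta_s, es = eta[order], events[order]
    # stable log of risk-set sums: running logsumexp from the latest time back
    rev_log_cum = np.logaddexp.accumulate(eta_s[::-1])[::-1]
    return float(np.sum(eta_s[es] - rev_log_cum[first_idx[es]]))


def _stratified_folds(events: np.ndarray, n_folds: int, seed: int,
                      max_retry: int = 20) -> np.ndarray:
    """Event-stratified fold ids such that every training set has >= 1 event."""
    events = np.asarray(events, dtype=bool)
    n = len(events)
    rng = np.random.default_rng(seed)
    for _ in range(max_retry):
        folds = np.empty(n, dtype=int)
        for cls in (True, False):
            idx = np.flatnonzero(events == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
        ok = all(events[folds != k].sum() >= 1 for k in range(n_folds))
        if ok:
            return folds
    raise ValueError("could not build folds with events in every training set")


def _fit_path(design: np.ndarray, times: np.ndarray, events: np.ndarray,
              grid: np.ndarray, tol: float) -> np.ndarray:
    y = Surv.from_arrays(event=np.asarray(events, bool), time=np.asarray(times, float))
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=grid, tol=tol,
                                   fit_baseline_model=False)
    with warnings.catch_warnings():
        # saturated fits at the smallest penalties may stop at max_iter;
        # the CV deviance discards those grid points on its own
        warnings.simplefilter("ignore")
        model.fit(design, y)
    coefs = np.asarray(model.coef_)
    if coefs.shape[1] != len(grid):     # solver dropped tail alphas
        full = np.zeros((design.shape[1], len(grid)))
        full[:, :coefs.shape[1]] = coefs
        full[:, coefs.shape[1]:] = coefs[:, -1:]
        coefs = full
    return coefs


def cv_cox_lasso(
    design: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    grid: np.ndarray | None = None,
    kept_voxel_indices: np.ndarray | None = None,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    tol: float = COXNET_TOL,
    selection_rule: str = "1se",
) -> LassoPathResult:
    """Cross-validated L1 Cox path; see the module docstring for the method."""
    if selection_rule not in ("1se", "min"):
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if events.sum() == 0:
        raise ValueError("zero events")
    if grid is None:
        grid = lambda_grid(design, times, events)
    grid = np.asarray(grid, dtype=float)

    folds = _stratified_folds(events, n_folds, seed)
    n_lambda = len(grid)
    dev = np.zeros((n_folds, n_lambda))
    for k in range(n_folds):
        tr = folds != k
        coefs = _fit_path(design[tr], times[tr], events[tr], grid, tol)
        for j in range(n_lambda):
            ll_all = cox_partial_loglik(coefs[:, j], design, times, events)
            ll_tr = cox_partial_loglik(coefs[:, j], design[tr], times[tr], events[tr])
            dev[k, j] = -2.0 * (ll_all - ll_tr)

    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    star = int(np.argmin(mean_dev))
    # largest penalty (grid is decreasing, so smallest index) within 1 SE
    one_se = int(np.argmax(mean_dev <= mean_dev[star] + se_dev[star]))

    coef_path = _fit_path(design, times, events, grid, tol)
    active_counts = (coef_path != 0).sum(axis=0)
    pick = one_se if selection_rule == "1se" else star
    sel = np.flatnonzero(coef_path[:, pick])
    kept = kept_voxel_indices if kept_voxel_indices is not None else np.arange(design.shape[1])
    return LassoPathResult(
        lambda_grid=grid, cv_deviance_mean=mean_dev, cv_deviance_se=se_dev,
        lambda_star=float(grid[star]), lambda_star_index=star,
        lambda_1se=float(grid[one_se]), lambda_1se_index=one_se,
        selection_rule=selection_rule, lambda_selected=float(grid[pick]),
        coef_path=coef_path, selected_columns=sel,
        selected_voxel_indices=np.asarray(kept)[sel],
        selected_coefs=coef_path[sel, pick], fold_assignment=folds,
        active_counts=active_counts,
        log={"n_events": int(events.sum()), "n_columns": int(design.shape[1])})


def path_table(result: LassoPathResult) -> pd.DataFrame:
    """Path summary: penalty, active count, CV deviance mean and SE."""
    return pd.DataFrame({
        "lambda": result.lambda_grid,
        "active_count": result.active_counts,
        "cv_deviance_mean": result.cv_deviance_mean,
        "cv_deviance_se": result.cv_deviance_se,
    })
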