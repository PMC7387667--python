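"""Per-voxel Cox proportional-hazards mapping.

At each masked voxel, patients are dichotomized at the voxel-wise median of
the cohort dose distribution (ties to the low group); a Cox model with the
high-dose indicator plus the endpoint's selected baseline covariates yields
a hazard ratio (high vs low dose) and a two-sided Wald p-value.  Repeating
over all voxels produces a 3D HR map and p-value map, with an overlay of
p < 0.05 voxels split by HR direction.

Fits use partial-likelihood maximization with the Efron approximation for
tied event times (visit-grid follow-up guarantees heavy ties).  Voxels where
the dose is constant across patients, or where the fit fails to converge
(e.g. monotone likelihood with all events in one group), are flagged
non-informative and excluded from the maps rather than aborting the run.

No multiplicity correction is applied to the per-voxel p-map: these are raw
Wald p-values for display, and family-wise error control is the role of the
max-statistic permutation test.

Candidate baseline covariates (age, prescribed dose group, disease risk,
cancer stage, baseline PSA, number of beams) are screened once per endpoint
by univariable Cox fits, retaining those with Wald p < 0.157 (the
AIC-equivalent level); the retained set adjusts every voxel model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .endpoints import CANDIDATE_COVARIATES
from .grid_io import VoxelGrid, cohort_matrix, scatter_to_grid

SCREEN_P_THRESHOLD = 0.157


class NonInformativeVoxel(ValueError):
    """Raised when a voxel carries no usable dose contrast or fit."""


@dataclass
class CoxMapResult:
    hr_map: VoxelGrid
    p_map: VoxelGrid
    covariates_used: list[str]
    noninformative_mask: VoxelGrid
    n_events: int
    overlay_hr_gt1: VoxelGrid = None
    overlay_hr_lt1: VoxelGrid = None
    log: dict = field(default_factory=dict)


def median_dichotomize(values: Sequence[float]) -> np.ndarray:
    """High/low split about the median of the combined distribution.

    High group = strictly above the median; ties go low.  Raises
    :class:`NonInformativeVoxel` when all values are identical or the split
    leaves a group empty.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.all(values == values[0]):
        raise NonInformativeVoxel("all dose values identical at this voxel")
    high = values > np.median(values)
    if high.all() or not high.any():
        raise NonInformativeVoxel("median split produced an empty group")
    return high.astype(int)


def _fit(df: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time_months", event_col="event")
    return cph


def fit_cox_voxel(
    groups: Sequence[int],
    covariates: pd.DataFrame | None,
    times: Sequence[float],
    events: Sequence[int],
) -> tuple[float, float]:
    """Cox fit of the high-dose indicator; returns (HR, two-sided Wald p).

    ``covariates`` (optional) are entered unpenalized alongside the
    indicator.  Efron tie handling throughout.  Non-convergence or a
    degenerate Wald standard error flags the voxel non-informative.
    """
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("zero events in the analysis set")
    df = pd.DataFrame({"high_dose": np.asarray(groups, dtype=float),
                       "time_months": np.asarray(times, dtype=float),
                       "event": events})
    if covariates is not None and len(covariates.columns):
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy(dtype=float)
    try:
        cph = _fit(df)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise NonInformativeVoxel(f"Cox fit failed: {exc}") from exc
    coef = float(cph.params_["high_dose"])
    se = float(cph.standard_errors_["high_dose"])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 50 or abs(coef) > 50:
        raise NonInformativeVoxel("monotone likelihood / degenerate Wald SE")
    p = float(cph.summary.loc["high_dose", "p"])
    return float(np.exp(coef)), p


def select_covariates(
    candidates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    threshold: float = SCREEN_P_THRESHOLD,
) -> list[str]:
    """Univariable screen: keep candidates with Wald p below ``threshold``.

    Non-convergent candidate fits are dropped with a warning.  An empty
    candidate frame yields unadjusted voxel models.
    """
    chosen: list[str] = []
    for name in candidates.columns:
        v = candidates[name].to_numpy(dtype=float)
        if np.all(v == v[0]):
            continue
        df = pd.DataFrame({name: v, "time_months": np.asarray(times, dtype=float),
                           "event": np.asarray(events, dtype=int)})
        try:
            cph = _fit(df)
            p = float(cph.summary.loc[name, "p"])
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"covariate {name} dropped (fit failed: {exc})")
            continue
        if p < threshold:
            chosen.append(name)
    return chosen


def cox_map(
    doses: Sequence[VoxelGrid],
    outcome_table: pd.DataFrame,
    mask: VoxelGrid,
    covariates: Sequence[str] | None = None,
    screen_threshold: float = SCREEN_P_THRESHOLD,
) -> CoxMapResult:
    """HR and p-value maps over all masked voxels.

    ``outcome_table`` must carry ``time_months``, ``event`` and the candidate
    covariate columns (one row per patient, aligned with ``doses``).
    ``covariates=None`` triggers the automated univariable screen;
    pass an explicit list (possibly empty) to override.
    """
    times = outcome_table["time_months"].to_numpy(dtype=float)
    events = outcome_table["event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("zero events in the analysis set")
    if len(doses) != len(outcome_table):
        raise ValueError("doses and outcome table lengths differ")

    candidates = outcome_table[[c for c in CANDIDATE_COVARIATES
                                if c in outcome_table.columns]]
    if covariates is None:
        chosen = select_covariates(candidates, times, events, screen_threshold)
    else:
        chosen = list(covariates)
    cov_df = outcome_table[chosen] if chosen else None

    X, index_map = cohort_matrix(doses, mask)
    n_vox = X.shape[1]
    hrs = np.full(n_vox, np.nan)
    ps = np.full(n_vox, np.nan)
    noninf = np.zeros(n_vox, dtype=np.uint8)
    for v in range(n_vox):
        try:
            groups = median_dichotomize(X[:, v])
            hrs[v], ps[v] = fit_cox_voxel(groups, cov_df, times, events)
        except NonInformativeVoxel:
            noninf[v] = 1

    tpl = doses[0]
    finite = np.isfinite(ps)
    sig_hi = (finite & (ps < 0.05) & (hrs > 1)).astype(np.uint8)
    sig_lo = (finite & (ps < 0.05) & (hrs < 1)).astype(np.uint8)
    return CoxMapResult(
        hr_map=scatter_to_grid(np.where(np.isfinite(hrs), hrs, 0.0), index_map, tpl, "hr"),
        p_map=scatter_to_grid(np.where(finite, ps, 1.0), index_map, tpl, "pvalue"),
        covariates_used=chosen,
        noninformative_mask=scatter_to_grid(noninf, index_map, tpl, "mask"),
        n_events=int(events.sum()),
        overlay_hr_gt1=scatter_to_grid(sig_hi, index_map, tpl, "mask"),
        overlay_hr_lt1=scatter_to_grid(sig_lo, index_map, tpl, "mask"),
        log={"n_noninformative": int(noninf.sum()), "n_voxels": int(n_vox)})
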