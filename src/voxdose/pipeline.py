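"""End-to-end orchestration: cohort -> endpoint tables -> the three tests.

A :class:`RunConfig` (YAML on disk) names the cohort source (a synthetic
generator config or an existing cohort manifest), the endpoints to analyse,
and the test parameters.  :func:`run_endpoint` executes the permutation
test, the per-voxel Cox map and the LASSO selection on the same analysis
set, writing a result bundle per endpoint; a failure of one test is recorded
in the bundle's status ledger without aborting the others.  Pooled
multi-trial analyses are plain concatenations of member cohorts
(:func:`combine_cohorts`) and flow through the identical code path, with an
optional balanced subsample so no single cohort dominates.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .endpoints import DEFAULT_ENDPOINTS, ClinicalRecord, ToxicityEndpoint, apply_exclusions, outcome_table
from .grid_io import GridError, VoxelGrid, read_grid, require_compatible, subsample_grid, write_grid
from .lasso import build_design, cv_cox_lasso, lambda_grid, path_table
from .perm_test import DEFAULT_ALPHAS, DEFAULT_N_PERM, max_stat_permutation
from .synthetic import (CohortConfig, SimulationTruth, default_effect_region,
                        default_template, generate_cohort, load_cohort)
from .univoxel import cox_map


@dataclass
class RunConfig:
    cohort_manifest: str | None = None
    synthetic: dict | None = None            # kwargs for the default generator
    endpoints: Sequence[str] = ("dysuria",)
    n_perm: int = DEFAULT_N_PERM
    alphas: Sequence[float] = DEFAULT_ALPHAS
    n_lambda: int = 100
    folds: int = 10
    subsample_factor: Sequence[int] = (1, 1, 1)
    seed: int = 0
    out_dir: str = "voxdose_results"
    mask_name: str = "analysis_region"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    def validate(self) -> None:
        if (self.cohort_manifest is None) == (self.synthetic is None):
            raise ValueError("exactly one of cohort_manifest / synthetic is required")
        if self.cohort_manifest is not None and not Path(self.cohort_manifest).exists():
            raise FileNotFoundError(f"cohort manifest not found: {self.cohort_manifest}")
        for ep in self.endpoints:
            if ep not in DEFAULT_ENDPOINTS:
                raise ValueError(f"unknown endpoint {ep!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _materialize_cohort(config: RunConfig, work_dir: Path):
    """Return (dose grids, clinical records, analysis mask)."""
    if config.cohort_manifest is not None:
        grids, records = load_cohort(config.cohort_manifest)
        root = Path(config.cohort_manifest).parent
        mask_path = root / f"{config.mask_name}.nii.gz"
        if mask_path.exists():
            mask = read_grid(mask_path, payload_kind="mask")
        else:
            mask = grids[0].with_payload(np.ones(grids[0].dims, dtype=np.uint8), "mask")
    else:
        kwargs = dict(config.synthetic or {})
        template = default_template(**kwargs.pop("template", {}))
        truth_kwargs = kwargs.pop("truth", {})
        truth = SimulationTruth(effect_region=default_effect_region(template), **truth_kwargs)
        cohort_cfg = CohortConfig(template=template, seed=config.seed, **kwargs)
        cohort_dir = work_dir / "cohort"
        manifest = generate_cohort(cohort_cfg, truth, cohort_dir,
                                   endpoints=[DEFAULT_ENDPOINTS[e] for e in config.endpoints])
        grids, records = load_cohort(manifest)
        mask = template.mask(config.mask_name)
    return grids, records, mask


def _subsampled(grids: list[VoxelGrid], mask: VoxelGrid, factor: Sequence[int]):
    if tuple(factor) == (1, 1, 1):
        return grids, mask
    return [subsample_grid(g, factor) for g in grids], subsample_grid(mask, factor)


def run_endpoint(
    config: RunConfig,
    endpoint_name: str,
    grids: list[VoxelGrid] | None = None,
    records: list[ClinicalRecord] | None = None,
    mask: VoxelGrid | None = None,
) -> dict:
    """Execute all three voxel-based tests for one endpoint; write a bundle.

    Returns the bundle status ledger (also written as ``status.json``).
    Pre-loaded cohort objects may be supplied to share them across endpoints.
    """
    config.validate()
    endpoint = DEFAULT_ENDPOINTS[endpoint_name]
    out = Path(config.out_dir) / endpoint_name
    out.mkdir(parents=True, exist_ok=True)

    if grids is None or records is None or mask is None:
        grids, records, mask = _materialize_cohort(config, Path(config.out_dir))
    grids_s, mask_s = _subsampled(grids, mask, config.subsample_factor)

    id_to_idx = {r.patient_id: i for i, r in enumerate(records)}
    included, excl_log = apply_exclusions(records, endpoint)
    table = outcome_table(records, endpoint)
    ep_grids = [grids_s[id_to_idx[pid]] for pid in table["patient_id"]]
    excl_log.to_csv(out / "exclusions.csv", index=False)
    table.to_csv(out / "outcomes.csv", index=False)

    status: dict = {"endpoint": endpoint_name, "n_included": len(included),
                    "n_events": int(table["event"].sum()), "stages": {}}

    labels = table["event"].to_numpy(dtype=bool)
    times = table["time_months"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)

    try:
        perm = max_stat_permutation(ep_grids, labels, mask_s, n_perm=config.n_perm,
                                    seed=config.seed, alphas=config.alphas)
        write_grid(perm.diff_map, out / "diff_map.nii.gz")
        write_grid(perm.stat_map, out / "stat_map.nii.gz")
        for a, m in perm.significance_masks.items():
            write_grid(m, out / f"sig_alpha_{a:g}.nii.gz")
        np.savetxt(out / "null_max_stats.csv", perm.null_max_stats, delimiter=",")
        (out / "permtest.json").write_text(json.dumps({
            "critical_values": {str(a): t for a, t in perm.critical_values.items()},
            "global_p": perm.global_p, "observed_max": perm.observed_max,
            "n_significant": {str(a): perm.n_significant(a) for a in perm.critical_values},
        }, indent=2))
        status["stages"]["perm_test"] = {"ok": True, "global_p": perm.global_p}
    except Exception as exc:                                    # noqa: BLE001
        status["stages"]["perm_test"] = {"ok": False, "error": str(exc),
                                         "trace": traceback.format_exc(limit=3)}

    try:
        cmap = cox_map(ep_grids, table, mask_s)
        write_grid(cmap.hr_map, out / "hr_map.nii.gz")
        write_grid(cmap.p_map, out / "p_map.nii.gz")
        write_grid(cmap.overlay_hr_gt1, out / "overlay_hr_gt1.nii.gz")
        write_grid(cmap.overlay_hr_lt1, out / "overlay_hr_lt1.nii.gz")
        (out / "coxmap.json").write_text(json.dumps({
            "covariates_used": cmap.covariates_used, "n_events": cmap.n_events,
            **cmap.log}, indent=2))
        status["stages"]["univoxel_cox"] = {"ok": True,
                                            "covariates_used": cmap.covariates_used}
    except Exception as exc:                                    # noqa: BLE001
        status["stages"]["univoxel_cox"] = {"ok": False, "error": str(exc),
                                            "trace": traceback.format_exc(limit=3)}

    try:
        design, kept, dropped = build_design(ep_grids, mask_s)
        grid = lambda_grid(design, times, events, n_lambda=config.n_lambda)
        res = cv_cox_lasso(design, times, events, grid, kept_voxel_indices=kept,
                           n_folds=config.folds, seed=config.seed)
        path_table(res).to_csv(out / "lasso_path.csv", index=False)
        (out / "lasso.json").write_text(json.dumps({
            "lambda_star": res.lambda_star,
            "lambda_1se": res.lambda_1se,
            "selection_rule": res.selection_rule,
            "lambda_selected": res.lambda_selected,
            "selected_voxel_indices": res.selected_voxel_indices.tolist(),
            "selected_hrs": res.selected_hrs.tolist(),
            "n_dropped_columns": int(len(dropped))}, indent=2))
        status["stages"]["multivoxel_lasso"] = {
            "ok": True, "n_selected": int(len(res.selected_columns))}
    except Exception as exc:                                    # noqa: BLE001
        status["stages"]["multivoxel_lasso"] = {"ok": False, "error": str(exc),
                                                "trace": traceback.format_exc(limit=3)}

    status["provenance"] = {"config_hash": _config_hash(config),
                            "version": __version__, "seed": config.seed}
    (out / "status.json").write_text(json.dumps(status, indent=2))
    return status


def run_all(config: RunConfig) -> dict[str, dict]:
    """All configured endpoints on a shared cohort; returns per-endpoint status."""
    config.validate()
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    grids, records, mask = _materialize_cohort(config, Path(config.out_dir))
    return {ep: run_endpoint(config, ep, grids, records, mask)
            for ep in config.endpoints}


def combine_cohorts(manifests: Sequence[str | Path], out_path: str | Path,
                    balance: bool = False, seed: int = 0) -> Path:
    """Pool cohort manifests into one (naive concatenation, source tags kept).

    ``balance=True`` subsamples every member cohort to the smallest cohort's
    size, so the pooled analysis is not dominated by the largest trial.
    Rejects geometry mismatches and duplicate patient ids.
    """
    manifests = [Path(m) for m in manifests]
    members = []
    ref_grid = None
    for m in manifests:
        doc = json.loads(m.read_text())
        first = read_grid(m.parent / doc["dose_files"][0], payload_kind="dose")
        if ref_grid is None:
            ref_grid = first
        elif not ref_grid.is_compatible(first):
            raise GridError(f"incompatible template geometry in {m}")
        members.append((m, doc))

    rng = np.random.default_rng(seed)
    if balance:
        n_min = min(len(doc["patient_ids"]) for _, doc in members)
    entries, seen = [], set()
    for m, doc in members:
        idx = np.arange(len(doc["patient_ids"]))
        if balance and len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        for i in idx:
            pid = doc["patient_ids"][i]
            if pid in seen:
                raise ValueError(f"duplicate patient id across cohorts: {pid}")
            seen.add(pid)
            entries.append({"patient_id": pid, "source": doc.get("source", m.parent.name),
                            "cohort_dir": str(m.parent),
                            "dose_file": doc["dose_files"][i]})
    pooled = {"pooled": True, "members": [str(m) for m, _ in members],
              "patient_ids": [e["patient_id"] for e in entries],
              "entries": entries}
    out_path = Path(out_path)
    out_path.write_text(json.dumps(pooled, indent=2))
    return out_path


def verify_bundle(bundle_dir: str | Path) -> dict:
    """Confirm every artifact referenced by a bundle's status ledger exists."""
    bundle_dir = Path(bundle_dir)
    status_path = bundle_dir / "status.json"
    if not status_path.exists():
        raise FileNotFoundError(f"no status.json in {bundle_dir}")
    status = json.loads(status_path.read_text())
    expected = {"perm_test": ["diff_map.nii.gz", "stat_map.nii.gz", "permtest.json"],
                "univoxel_cox": ["hr_map.nii.gz", "p_map.nii.gz", "coxmap.json"],
                "multivoxel_lasso": ["lasso_path.csv", "lasso.json"]}
    report = {"bundle": str(bundle_dir), "complete": True, "missing": []}
    for stage, files in expected.items():
        if status["stages"].get(stage, {}).get("ok"):
            for f in files:
                if not (bundle_dir / f).exists():
                    report["missing"].append(f)
                    report["complete"] = False
    return report
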