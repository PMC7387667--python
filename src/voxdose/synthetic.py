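"""Synthetic registered dose-toxicity cohorts with known ground truth.

Emulates the structure of pooled prostate EBRT trial data: conformal
beam-structured 3D dose fields sharing one template geometry, a high-dose
CTV, prescription arms (e.g. 66/70/74 Gy at 2 Gy per fraction), six baseline
covariates, and late genitourinary toxicity event times generated from a
Weibull proportional-hazards model driven by the mean dose inside a planted
spatial effect region, then interval-censored onto a follow-up visit grid
(every 3 months to 18 months, every 6 months to 5 years, then annually).

Because every beam is calibrated so the CTV mean equals the prescribed dose,
inter-patient dose variance is concentrated outside the CTV — beam number and
angles vary per patient — which mirrors real conformal cohorts where the
target is uniformly covered and the variation lives in the beam paths.

Grade trajectories are not modelled mechanistically: the generator emits the
threshold grade at the event visit and 0 elsewhere, plus an optional
baseline grade >= 1 with configurable prevalence, because the analysis only
consumes first-crossing times and baseline flags.

All randomness derives from per-patient streams spawned from the master
seed, so cohorts are bit-reproducible under any execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .endpoints import DEFAULT_ENDPOINTS, ClinicalRecord, ToxicityEndpoint
from .eqd2 import PhaseDose, sum_phases
from .grid_io import GridError, TemplateSpace, VoxelGrid, write_grid

#: Post-treatment follow-up visit months (3-monthly to 18, 6-monthly to 60,
#: then annually to 84).
DEFAULT_VISIT_SCHEDULE = tuple(
    list(range(3, 19, 3)) + list(range(24, 61, 6)) + [72, 84]
)


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass
class FractionationScheme:
    prescribed_dose: float
    dose_per_fraction: float
    n_fractions: int
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if min(self.prescribed_dose, self.dose_per_fraction, self.n_fractions,
               self.alpha_beta) <= 0:
            raise ValueError("all fractionation parameters must be positive")
        if abs(self.prescribed_dose - self.dose_per_fraction * self.n_fractions) > 1e-9:
            raise ValueError("prescribed_dose must equal dose_per_fraction * n_fractions")


#: Dose-escalated 2 Gy/fraction arms with weights emulating a conformal trial.
DEFAULT_ARMS = (
    (FractionationScheme(66.0, 2.0, 33), 0.13),
    (FractionationScheme(70.0, 2.0, 35), 0.55),
    (FractionationScheme(74.0, 2.0, 37), 0.32),
)

#: Hypofractionated arms (3 Gy/fraction) for multi-trial pooling scenarios.
HYPOFRACTIONATED_ARMS = (
    (FractionationScheme(57.0, 3.0, 19), 0.5),
    (FractionationScheme(60.0, 3.0, 20), 0.5),
)


@dataclass
class BeamModel:
    """Geometry/noise parameters of the conformal beam simulator (mm / Gy).

    ``disp_sigma_mm`` controls a smooth random displacement field emulating
    residual registration/anatomy variability: each patient's dose is
    perturbed by ``u . grad(D)``, which vanishes in the flat CTV plateau and
    peaks at field edges, so localized inter-patient dose variance arises
    exactly where real registered cohorts show it.
    """

    field_margin_mm: float = 12.0
    penumbra_mm: float = 5.0
    noise_sigma: float = 0.04          # lognormal sigma of voxelwise noise
    angle_jitter_deg: float = 30.0
    isocenter_jitter_mm: float = 3.0
    margin_jitter_mm: float = 8.0
    z_extension_jitter_mm: float = 0.0
    disp_sigma_mm: float = 4.0
    disp_corr_vox: float = 2.0


@dataclass
class CovariateModel:
    """Baseline covariate distributions (ages in years, PSA in ng/ml)."""

    age_mean: float = 68.5
    age_sd: float = 6.0
    psa_median: float = 14.0
    psa_log_sd: float = 0.5
    p_high_risk: float = 0.52
    p_high_stage: float = 0.31


@dataclass
class CohortConfig:
    n_patients: int
    template: TemplateSpace
    arms: Sequence[tuple[FractionationScheme, float]] = DEFAULT_ARMS
    n_beams_choices: Sequence[int] = (3, 4, 5, 6, 7)
    n_beams_weights: Sequence[float] = (0.11, 0.52, 0.13, 0.14, 0.10)
    beam_model: BeamModel = field(default_factory=BeamModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for weights in (tuple(w for _, w in self.arms), tuple(self.n_beams_weights)):
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError("sampling weights must sum to 1")


@dataclass
class SimulationTruth:
    """The proportional-hazards data-generating model and its effect region.

    ``log_hr_per_10gy`` is the log hazard ratio per 10 Gy of mean EQD2 inside
    ``effect_region`` (relative to ``reference_dose_gy``); covariate log-HRs
    are per standard deviation of each covariate.
    """

    effect_region: VoxelGrid
    log_hr_per_10gy: float = float(np.log(2.0))
    covariate_log_hrs: dict[str, float] = field(default_factory=lambda: {"age": 0.25})
    weibull_shape: float = 1.1
    weibull_scale_months: float = 300.0
    censor_schedule: Sequence[float] = DEFAULT_VISIT_SCHEDULE
    #: None centers the dose effect at the cohort mean region dose, keeping
    #: the marginal event rate at the baseline level for any geometry.
    reference_dose_gy: float | None = None
    baseline_tox_prevalence: float = 0.05
    late_window_months: float = 3.0

    def __post_init__(self) -> None:
        if self.weibull_shape <= 0 or self.weibull_scale_months <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        sched = list(self.censor_schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("visit schedule must be strictly increasing")
        if not any(v > self.late_window_months for v in sched):
            raise ValueError("no visits after the late window in the schedule")


def default_template(dims: tuple[int, int, int] = (24, 24, 14),
                     spacing: tuple[float, float, float] = (4.0, 4.0, 5.0)) -> TemplateSpace:
    """A desk-scale pelvic template: ellipsoidal CTV mid-volume, bladder
    anterior-superior, rectum posterior, full-grid analysis region."""
    nx, ny, nz = dims
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2

    def ellipsoid(c, r):
        return (((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2
                + ((z - c[2]) / r[2]) ** 2) <= 1.0

    ctv = ellipsoid((cx, cy, cz + 1), (nx * 0.14, ny * 0.14, nz * 0.18))
    bladder = ellipsoid((cx, cy - ny * 0.22, cz + nz * 0.25), (nx * 0.16, ny * 0.14, nz * 0.2))
    rectum = ellipsoid((cx, cy + ny * 0.25, cz), (nx * 0.1, ny * 0.1, nz * 0.3))
    geometry = VoxelGrid(np.zeros(dims, dtype=np.float32), spacing=spacing, payload_kind="stat")
    masks = {
        "ctv": geometry.with_payload(ctv.astype(np.uint8), "mask"),
        "bladder": geometry.with_payload(bladder.astype(np.uint8), "mask"),
        "rectum": geometry.with_payload(rectum.astype(np.uint8), "mask"),
        "analysis_region": geometry.with_payload(np.ones(dims, dtype=np.uint8), "mask"),
    }
    return TemplateSpace(geometry=geometry, structure_masks=masks)


def default_effect_region(template: TemplateSpace) -> VoxelGrid:
    """A small tube inferior to the CTV (urethra-like fixture region)."""
    ctv = np.asarray(template.mask("ctv").data, dtype=bool)
    dims = template.geometry.dims
    xs, ys, zs = np.nonzero(ctv)
    cx, cy = int(round(xs.mean())), int(round(ys.mean()))
    z_lo = max(0, int(zs.min()) - max(2, dims[2] // 5))
    z_hi = int(zs.min())
    region = np.zeros(dims, dtype=np.uint8)
    r = max(1, dims[0] // 12)
    region[cx - r:cx + r + 1, cy - r:cy + r + 1, z_lo:z_hi] = 1
    region[ctv] = 0
    if region.sum() == 0:
        raise GridError("default effect region is empty for this template")
    return template.geometry.with_payload(region, "mask")


def _smooth_box(dist_from_center: np.ndarray, half_width: float, penumbra: float) -> np.ndarray:
    # erf-blurred rectangular profile: ~1 inside the field, ~0 beyond the penumbra
    return 0.5 * (1.0 + erf((half_width - np.abs(dist_from_center)) / (np.sqrt(2.0) * penumbra)))


def simulate_dose(config: CohortConfig, patient_index: int) -> tuple[VoxelGrid, dict]:
    """One patient's physical planned dose (single phase) plus beam metadata.

    Beams rotate about the z (cranio-caudal) axis through an isocenter inside
    the CTV; each has a rectangular cross-profile with a Gaussian penumbra
    sized to cover the CTV plus a margin.  The summed field is calibrated so
    the CTV mean equals the arm's prescribed dose, then multiplied by
    voxelwise lognormal noise.  Deterministic given (config.seed, index).
    """
    rng = rng_for(config.seed, 1, patient_index)
    tpl = config.template
    ctv = np.asarray(tpl.mask("ctv").data, dtype=bool)
    if not ctv.any():
        raise GridError("CTV mask empty")
    bm = config.beam_model

    arm_idx = rng.choice(len(config.arms), p=[w for _, w in config.arms])
    arm = config.arms[arm_idx][0]
    n_beams = int(rng.choice(config.n_beams_choices, p=config.n_beams_weights))
    if n_beams < 1:
        raise GridError("beam count < 1")

    dims, spacing = tpl.geometry.dims, tpl.geometry.spacing
    x, y, z = np.meshgrid(*(np.arange(d) * s for d, s in zip(dims, spacing)), indexing="ij")
    xs, ys, zs = (c[ctv] for c in (x, y, z))
    iso = np.array([xs.mean(), ys.mean(), zs.mean()])
    iso[:2] += rng.normal(0.0, bm.isocenter_jitter_mm, size=2)

    # CTV extent defines field size (equivalent radius + margin)
    r_xy = max(np.hypot(xs - iso[0], ys - iso[1]).max(), spacing[0])
    # per-patient superior-inferior field extension (inferior borders differ
    # across plans, so the cohort's dose variance peaks at the field edge)
    half_z = (max((zs.max() - zs.min()) / 2, spacing[2]) + bm.field_margin_mm
              + rng.uniform(-bm.z_extension_jitter_mm, bm.z_extension_jitter_mm))

    base_angles = np.arange(n_beams) * (360.0 / n_beams)
    angles = base_angles + rng.uniform(-bm.angle_jitter_deg, bm.angle_jitter_deg, n_beams)
    margins = bm.field_margin_mm + rng.uniform(0.0, bm.margin_jitter_mm, n_beams)

    dose = np.zeros(dims, dtype=float)
    z_prof = _smooth_box(z - iso[2], half_z, bm.penumbra_mm)
    for ang, margin in zip(angles, margins):
        theta = np.deg2rad(ang)
        # signed distance from the beam axis plane (beam travels along u)
        t = -(x - iso[0]) * np.sin(theta) + (y - iso[1]) * np.cos(theta)
        profile = _smooth_box(t, r_xy + margin, bm.penumbra_mm)
        dose += profile * z_prof
    dose /= n_beams

    if bm.disp_sigma_mm > 0:
        grads = np.gradient(dose, *spacing)          # Gy/mm per axis
        for g_ax in grads:
            u = gaussian_filter(rng.standard_normal(dims), bm.disp_corr_vox)
            sd = u.std()
            if sd > 0:
                dose += (bm.disp_sigma_mm / sd) * u * g_ax
        np.maximum(dose, 0.0, out=dose)

    if bm.noise_sigma > 0:
        noise = rng.lognormal(mean=-0.5 * bm.noise_sigma ** 2, sigma=bm.noise_sigma,
                              size=dims)
        dose *= noise
    dose *= arm.prescribed_dose / dose[ctv].mean()

    grid = VoxelGrid(np.asarray(dose, dtype=np.float32), spacing=spacing,
                     origin=tpl.geometry.origin, payload_kind="dose")
    meta = {"patient_index": patient_index, "arm": arm_idx,
            "prescribed_dose": arm.prescribed_dose, "n_fractions": arm.n_fractions,
            "dose_per_fraction": arm.dose_per_fraction, "n_beams": n_beams,
            "beam_angles_deg": [float(a) for a in angles]}
    return grid, meta


def _sample_covariates(config: CohortConfig, patient_index: int, meta: dict) -> dict:
    rng = rng_for(config.seed, 2, patient_index)
    cm = config.covariates
    return {
        "age": float(np.clip(rng.normal(cm.age_mean, cm.age_sd), 45.0, 90.0)),
        "prescribed_dose_group": float(meta["prescribed_dose"]),
        "disease_risk": int(rng.random() < cm.p_high_risk),
        "cancer_stage": int(rng.random() < cm.p_high_stage),
        "baseline_psa": float(np.exp(rng.normal(np.log(cm.psa_median), cm.psa_log_sd))),
        "n_beams": int(meta["n_beams"]),
    }


def region_mean_doses(dose_grids: Sequence[VoxelGrid], region: VoxelGrid) -> np.ndarray:
    mask = np.asarray(region.data, dtype=bool)
    return np.array([float(g.data[mask].mean()) for g in dose_grids])


def simulate_outcomes(
    dose_grids: Sequence[VoxelGrid],
    covariate_table: pd.DataFrame,
    truth: SimulationTruth,
    seed: int,
    endpoint: ToxicityEndpoint | None = None,
) -> pd.DataFrame:
    """Visit-censored event times under the planted proportional-hazards model.

    The latent time is Weibull with per-patient hazard multiplier
    ``exp(beta * (meanDose(region) - ref)/10 + gamma' z)`` (z standardized
    within-cohort), discretized to the first visit at or after the latent
    time.  Events landing at visits inside the late window become baseline
    toxicity flags; patients outliving the schedule are censored at the last
    visit.  Returns a frame with latent/visit times, event and baseline flags.
    """
    endpoint = endpoint or DEFAULT_ENDPOINTS["dysuria"]
    n = len(dose_grids)
    if n != len(covariate_table):
        raise ValueError("dose grids and covariate table lengths differ")
    visits = np.asarray(sorted(truth.censor_schedule), dtype=float)
    if not np.any(visits > truth.late_window_months):
        raise ValueError("no visits after the late window in the schedule")

    d = region_mean_doses(dose_grids, truth.effect_region)
    ref = truth.reference_dose_gy if truth.reference_dose_gy is not None else float(d.mean())
    log_hr = truth.log_hr_per_10gy * (d - ref) / 10.0
    for name, gamma in truth.covariate_log_hrs.items():
        if gamma == 0.0 or name not in covariate_table:
            continue
        v = covariate_table[name].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd > 0:
            log_hr = log_hr + gamma * (v - v.mean()) / sd

    rng = rng_for(seed, 3)
    E = rng.exponential(size=n)
    latent = truth.weibull_scale_months * (E / np.exp(log_hr)) ** (1.0 / truth.weibull_shape)

    rows = []
    base_flags = rng.random(n) < truth.baseline_tox_prevalence
    for i in range(n):
        idx = np.searchsorted(visits, latent[i], side="left")
        if idx >= len(visits):               # outlives the schedule
            event, t, baseline = False, float(visits[-1]), False
        elif visits[idx] <= truth.late_window_months:
            event, t, baseline = False, float(visits[-1]), True
        else:
            event, t, baseline = True, float(visits[idx]), False
        baseline = baseline or bool(base_flags[i])
        rows.append({"region_mean_dose": float(d[i]), "latent_months": float(latent[i]),
                     "event": bool(event), "time_months": t,
                     "baseline_grade": int(baseline)})
    return pd.DataFrame(rows)


def _records_from(outcomes: pd.DataFrame, covariate_table: pd.DataFrame,
                  endpoint: ToxicityEndpoint, visits: Sequence[float],
                  source: str) -> list[ClinicalRecord]:
    records = []
    for i, (out, cov) in enumerate(zip(outcomes.itertuples(), covariate_table.itertuples())):
        grades = {float(v): 0 for v in visits}
        if out.event:
            grades[float(out.time_months)] = endpoint.grade_threshold
        rec = ClinicalRecord(
            patient_id=f"{source}-{i:04d}", age=cov.age,
            prescribed_dose_group=cov.prescribed_dose_group,
            disease_risk=cov.disease_risk, cancer_stage=cov.cancer_stage,
            baseline_psa=cov.baseline_psa, n_beams=cov.n_beams,
            follow_up_grades={endpoint.name: grades},
            baseline_grades={endpoint.name: int(out.baseline_grade)},
            source_cohort=source,
        )
        records.append(rec)
    return records


def simulate_cohort(
    config: CohortConfig,
    truth: SimulationTruth,
    endpoints: Sequence[ToxicityEndpoint] | None = None,
    source: str = "synthetic",
) -> tuple[list[VoxelGrid], list[ClinicalRecord], pd.DataFrame]:
    """In-memory cohort: summed EQD2 grids, clinical records, covariate table.

    Endpoint outcomes are simulated independently per endpoint from the same
    truth (distinct random sub-streams), then merged into one record per
    patient.
    """
    endpoints = list(endpoints or [DEFAULT_ENDPOINTS["dysuria"]])
    grids, covs = [], []
    for i in range(config.n_patients):
        phys, meta = simulate_dose(config, i)
        eqd2 = sum_phases([PhaseDose(phys, n_fractions=meta["n_fractions"])])
        eqd2.meta.update(meta)
        grids.append(eqd2)
        covs.append(_sample_covariates(config, i, meta))
    cov_table = pd.DataFrame(covs)

    records: list[ClinicalRecord] | None = None
    visits = sorted(truth.censor_schedule)
    for k, ep in enumerate(endpoints):
        outcomes = simulate_outcomes(grids, cov_table, truth,
                                     seed=config.seed * 1000 + 7 + k, endpoint=ep)
        ep_records = _records_from(outcomes, cov_table, ep, visits, source)
        if records is None:
            records = ep_records
        else:
            for rec, new in zip(records, ep_records):
                rec.follow_up_grades.update(new.follow_up_grades)
                rec.baseline_grades.update(new.baseline_grades)
    assert records is not None
    return grids, records, cov_table


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def records_to_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Long-format clinical table (one row per patient x endpoint x visit)."""
    rows = []
    for rec in records:
        for ep_name, grades in rec.follow_up_grades.items():
            for month, grade in sorted(grades.items()):
                rows.append({"patient_id": rec.patient_id, **rec.covariate_dict(),
                             "source_cohort": rec.source_cohort,
                             "ebrt_only": int(rec.ebrt_only),
                             "endpoint": ep_name, "visit_month": month,
                             "grade": grade,
                             "baseline_grade": rec.baseline_grades.get(ep_name, 0)})
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[ClinicalRecord]:
    records = []
    for pid, sub in frame.groupby("patient_id", sort=True):
        first = sub.iloc[0]
        follow: dict[str, dict[float, int]] = {}
        baseline: dict[str, int] = {}
        for ep_name, ep_sub in sub.groupby("endpoint"):
            follow[ep_name] = {float(r.visit_month): int(r.grade)
                               for r in ep_sub.itertuples()}
            baseline[ep_name] = int(ep_sub["baseline_grade"].iloc[0])
        records.append(ClinicalRecord(
            patient_id=str(pid), age=float(first["age"]),
            prescribed_dose_group=float(first["prescribed_dose_group"]),
            disease_risk=int(first["disease_risk"]),
            cancer_stage=int(first["cancer_stage"]),
            baseline_psa=float(first["baseline_psa"]), n_beams=int(first["n_beams"]),
            follow_up_grades=follow, baseline_grades=baseline,
            ebrt_only=bool(first.get("ebrt_only", 1)),
            source_cohort=str(first["source_cohort"])))
    return records


def generate_cohort(
    config: CohortConfig,
    truth: SimulationTruth,
    out_dir: str | Path,
    endpoints: Sequence[ToxicityEndpoint] | None = None,
    source: str = "synthetic",
) -> Path:
    """Write a cohort to disk: per-patient EQD2 NIfTI grids, a clinical CSV,
    the truth JSON + effect-region mask, and a SHA-256 manifest.

    Returns the manifest path; :func:`load_cohort` is the inverse.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grids, records, _ = simulate_cohort(config, truth, endpoints, source)

    entries = {}
    for i, g in enumerate(grids):
        name = f"dose_{i:04d}.nii.gz"
        write_grid(g, out / name, sidecar={"patient_id": records[i].patient_id})
        entries[name] = _sha256(out / name)

    clinical = records_to_frame(records)
    clinical.to_csv(out / "clinical.csv", index=False)
    entries["clinical.csv"] = _sha256(out / "clinical.csv")

    write_grid(truth.effect_region, out / "effect_region.nii.gz")
    entries["effect_region.nii.gz"] = _sha256(out / "effect_region.nii.gz")

    truth_doc = {"log_hr_per_10gy": truth.log_hr_per_10gy,
                 "covariate_log_hrs": truth.covariate_log_hrs,
                 "weibull_shape": truth.weibull_shape,
                 "weibull_scale_months": truth.weibull_scale_months,
                 "censor_schedule": list(truth.censor_schedule),
                 "reference_dose_gy": truth.reference_dose_gy,
                 "baseline_tox_prevalence": truth.baseline_tox_prevalence,
                 "effect_region_file": "effect_region.nii.gz"}
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=2, sort_keys=True))
    entries["truth.json"] = _sha256(out / "truth.json")

    manifest = {"n_patients": config.n_patients, "seed": config.seed,
                "source": source,
                "patient_ids": [r.patient_id for r in records],
                "dose_files": [f"dose_{i:04d}.nii.gz" for i in range(len(grids))],
                "files": entries}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def validate_manifest(manifest_path: str | Path) -> None:
    """Re-hash every file listed in a manifest; raise on mismatch/missing."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    for name, digest in manifest["files"].items():
        p = root / name
        if not p.exists():
            raise FileNotFoundError(f"manifest entry missing on disk: {name}")
        if _sha256(p) != digest:
            raise ValueError(f"checksum mismatch for {name}")


def load_cohort(manifest_path: str | Path) -> tuple[list[VoxelGrid], list[ClinicalRecord]]:
    from .grid_io import read_grid

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    grids = [read_grid(root / f, payload_kind="dose") for f in manifest["dose_files"]]
    records = frame_to_records(pd.read_csv(root / "clinical.csv"))
    order = {pid: k for k, pid in enumerate(manifest["patient_ids"])}
    records.sort(key=lambda r: order[r.patient_id])
    return grids, records
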