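import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

import voxdose as vd
from voxdose.synthetic import region_mean_doses
from voxdose.univoxel import (NonInformativeVoxel, cox_map, fit_cox_voxel,
                              median_dichotomize, select_covariates)


def simulate_two_group(rng, n, true_hr, censor_at=None):
    """Exponential survival with a binary covariate at the given hazard ratio."""
    groups = (rng.random(n) > 0.5).astype(int)
    times = rng.exponential(1.0 / np.where(groups == 1, true_hr, 1.0))
    events = np.ones(n, dtype=int)
    if censor_at is not None:
        events = (times <= censor_at).astype(int)
        times = np.minimum(times, censor_at)
    return groups, times, events


class TestMedianDichotomize:
    def test_even_split(self):
        labels = median_dichotomize([1, 2, 3, 4])
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])

    def test_constant_values_non_informative(self):
        with pytest.raises(NonInformativeVoxel):
            median_dichotomize([50, 50, 50, 50])

    def test_ties_go_low(self):
        labels = median_dichotomize([1, 2, 2, 3])
        np.testing.assert_array_equal(labels, [0, 0, 0, 1])


class TestFitCoxVoxel:
    def test_identical_groups_hr_is_one(self, rng):
        # duplicated survival data in both groups: HR = 1 by symmetry
        times = np.array([5.0, 8, 12, 20, 30, 30])
        events = np.array([1, 1, 0, 1, 0, 1])
        groups = np.r_[np.zeros(6, int), np.ones(6, int)]
        hr, p = fit_cox_voxel(groups, None, np.r_[times, times], np.r_[events, events])
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_label_swap_gives_reciprocal_hr(self, rng):
        groups, times, events = simulate_two_group(rng, 150, 2.0, censor_at=2.0)
        hr, p = fit_cox_voxel(groups, None, times, events)
        hr_swap, p_swap = fit_cox_voxel(1 - groups, None, times, events)
        assert hr_swap == pytest.approx(1.0 / hr, rel=1e-6)
        assert p_swap == pytest.approx(p, rel=1e-6)

    def test_sign_agrees_with_logrank(self, rng):
        groups, times, events = simulate_two_group(rng, 200, 2.5, censor_at=1.5)
        hr, _ = fit_cox_voxel(groups, None, times, events)
        lr = logrank_test(times[groups == 1], times[groups == 0],
                          events[groups == 1], events[groups == 0])
        assert hr > 1 and lr.p_value < 0.05

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            fit_cox_voxel([0, 1, 0, 1], None, [1.0, 2, 3, 4], [0, 0, 0, 0])

    def test_all_events_in_one_group_non_informative(self):
        groups = np.array([1, 1, 1, 0, 0, 0])
        times = np.array([1.0, 2, 3, 10, 11, 12])
        events = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises((NonInformativeVoxel, ValueError)):
            fit_cox_voxel(groups, None, times, events)

    def test_parameter_recovery_hr2(self, rng):
        ok = 0
        reps = 60
        for r in range(reps):
            local = np.random.default_rng(500 + r)
            groups, times, events = simulate_two_group(local, 400, 2.0)
            hr, _ = fit_cox_voxel(groups, None, times, events)
            ok += 1.6 <= hr <= 2.5
        assert ok / reps >= 0.9


class TestSelectCovariates:
    def _outcome(self, rng, n, lin):
        times = rng.exponential(np.exp(-lin))
        cens = rng.exponential(np.median(times) * 3, n)
        events = (times <= cens).astype(int)
        return np.minimum(times, cens), events

    def test_null_covariate_rarely_retained(self):
        retained = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(2000 + r)
            x = rng.normal(size=300)
            times, events = self._outcome(rng, 300, np.zeros(300))
            cand = pd.DataFrame({"x": x})
            retained += "x" in select_covariates(cand, times, events)
        # screening level 0.157 => retention ~16% under the null
        assert retained / reps <= 0.157 + 3 * np.sqrt(0.157 * 0.843 / reps)

    def test_strong_covariate_always_retained(self):
        retained = 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(3000 + r)
            x = (rng.random(500) > 0.5).astype(float)
            times, events = self._outcome(rng, 500, np.log(3.0) * x)
            assert events.sum() >= 50
            retained += "x" in select_covariates(pd.DataFrame({"x": x}), times, events)
        assert retained / reps >= 0.95

    def test_empty_candidates_unadjusted(self, rng):
        times, events = self._outcome(rng, 50, np.zeros(50))
        assert select_covariates(pd.DataFrame(), times, events) == []


class TestCoxMap:
    def test_pvalues_uniform_under_global_null(self):
        # independent-label fits across many voxels: p ~ Uniform(0,1)
        rng = np.random.default_rng(4000)
        n, n_vox = 500, 1000
        times = rng.exponential(1.0, n)
        events = np.ones(n, dtype=int)
        ps = []
        for v in range(n_vox):
            groups = (rng.random(n) > 0.5).astype(int)
            _, p = fit_cox_voxel(groups, None, times, events)
            ps.append(p)
        ps = np.sort(ps)
        ks = np.max(np.abs(ps - np.arange(1, n_vox + 1) / n_vox))
        assert ks < 0.05

    def test_all_censored_rejected(self, small_cohort, template):
        grids, records, _ = small_cohort
        tab = vd.outcome_table(records, vd.DEFAULT_ENDPOINTS["dysuria"]).copy()
        tab["event"] = 0
        mask = template.mask("analysis_region")
        with pytest.raises(ValueError, match="zero events"):
            cox_map(grids[: len(tab)], tab, mask)

    def test_patient_order_invariance(self, template, truth):
        cfg = vd.CohortConfig(n_patients=40, template=template, seed=6)
        grids, records, _ = vd.simulate_cohort(cfg, truth,
                                               endpoints=[vd.DEFAULT_ENDPOINTS["dysuria"]])
        tab = vd.outcome_table(records, vd.DEFAULT_ENDPOINTS["dysuria"])
        ids = {r.patient_id: i for i, r in enumerate(records)}
        epg = [grids[ids[p]] for p in tab["patient_id"]]
        sub = vd.subsample_grid(template.mask("ctv"), (2, 2, 2))
        epg_s = [vd.subsample_grid(g, (2, 2, 2)) for g in epg]
        m1 = cox_map(epg_s, tab, sub, covariates=[])
        order = np.random.default_rng(1).permutation(len(tab))
        m2 = cox_map([epg_s[i] for i in order], tab.iloc[order].reset_index(drop=True),
                     sub, covariates=[])
        np.testing.assert_allclose(m1.hr_map.data, m2.hr_map.data, rtol=1e-6)
        np.testing.assert_allclose(m1.p_map.data, m2.p_map.data, atol=1e-8)

    def test_planted_effect_recovered_in_map(self, template, truth):
        """The HR>1 overlay finds the planted region; detections stay within
        the set of voxels whose dose is correlated with the region dose."""
        from scipy.ndimage import binary_dilation

        cfg = vd.CohortConfig(n_patients=400, template=template, seed=42)
        grids, records, _ = vd.simulate_cohort(cfg, truth,
                                               endpoints=[vd.DEFAULT_ENDPOINTS["dysuria"]])
        tab = vd.outcome_table(records, vd.DEFAULT_ENDPOINTS["dysuria"])
        ids = {r.patient_id: i for i, r in enumerate(records)}
        epg = [grids[ids[p]] for p in tab["patient_id"]]

        # analysis sub-box: truth region plus generous surroundings
        box = np.zeros(template.geometry.dims, np.uint8)
        box[6:18, 6:18, 0:8] = 1
        mask = template.geometry.with_payload(box, "mask")
        cm = cox_map(epg, tab, mask, covariates=[])

        overlay = cm.overlay_hr_gt1.data.astype(bool)
        region = truth.effect_region.data.astype(bool)
        dilated = binary_dilation(region, iterations=3) & box.astype(bool)
        assert overlay.sum() > 0
        recall = (overlay & dilated).sum() / dilated.sum()
        assert recall >= 0.2

        d = region_mean_doses(epg, truth.effect_region)
        X = np.stack([g.data for g in epg]).reshape(len(epg), -1)
        Xc = X - X.mean(axis=0)
        dc = d - d.mean()
        denom = np.sqrt((Xc ** 2).sum(axis=0) * (dc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.nan_to_num((Xc.T @ dc) / denom).reshape(template.geometry.dims)
        correlated = (np.abs(corr) >= 0.1) & box.astype(bool)
        tp = (overlay & correlated).sum()
        precision = tp / overlay.sum()
        baseline = correlated.sum() / box.sum()
        assert precision >= 0.9
        assert precision > baseline          # enrichment over the box at large
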