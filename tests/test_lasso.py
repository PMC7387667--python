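import numpy as np
import pytest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

import voxdose as vd
from voxdose.lasso import (build_design, cox_lasso_lambda_max, cox_partial_loglik,
                           cv_cox_lasso, lambda_grid, path_table)


def make_grids(values_per_patient):
    """One grid per patient from a (n_patients, n_voxels) value array (z-stacked)."""
    arr = np.asarray(values_per_patient, dtype=float)
    n, p = arr.shape
    return [vd.VoxelGrid(arr[i].reshape(1, 1, p)) for i in range(n)]


def survival_data(rng, design, beta, censor_q=0.7):
    lin = design @ beta
    times = rng.exponential(np.exp(-lin))
    cens = np.quantile(times, censor_q)
    events = times <= cens
    return np.minimum(times, cens), events.astype(int)


class TestBuildDesign:
    def test_median_split_column(self):
        grids = make_grids([[1], [2], [3], [4]])
        mask = grids[0].with_payload(np.ones((1, 1, 1), np.uint8), "mask")
        design, kept, dropped = build_design(grids, mask)
        np.testing.assert_array_equal(design[:, 0], [0, 0, 1, 1])
        assert len(dropped) == 0

    def test_constant_column_dropped(self):
        grids = make_grids([[1, 7], [2, 7], [3, 7], [4, 7]])
        mask = grids[0].with_payload(np.ones((1, 1, 2), np.uint8), "mask")
        design, kept, dropped = build_design(grids, mask)
        assert design.shape == (4, 1) and len(dropped) == 1

    def test_rebuild_is_byte_identical(self, rng):
        vals = rng.random((10, 6)) * 60
        grids = make_grids(vals)
        mask = grids[0].with_payload(np.ones((1, 1, 6), np.uint8), "mask")
        d1, _, _ = build_design(grids, mask)
        d2, _, _ = build_design(grids, mask)
        assert d1.tobytes() == d2.tobytes()

    def test_all_constant_rejected(self):
        grids = make_grids([[5], [5], [5]])
        mask = grids[0].with_payload(np.ones((1, 1, 1), np.uint8), "mask")
        with pytest.raises(ValueError, match="constant"):
            build_design(grids, mask)


class TestLambdaGrid:
    def test_closed_form_matches_coxnet_convention(self, rng):
        # independent cross-check against the solver's own path start,
        # with heavy ties as produced by visit-grid follow-up
        X = (rng.random((80, 12)) > 0.5).astype(float)
        times = rng.choice([6.0, 12, 24, 36, 60], size=80)
        events = rng.random(80) < 0.4
        events[0] = True
        lmax = cox_lasso_lambda_max(X, times, events)
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=20)
        m.fit(X, Surv.from_arrays(events, times))
        assert lmax == pytest.approx(m.alphas_[0], rel=1e-6)

    def test_grid_shape_and_monotone(self, rng):
        X = (rng.random((40, 5)) > 0.5).astype(float)
        times, events = survival_data(rng, X, np.zeros(5))
        grid = lambda_grid(X, times, events)
        assert len(grid) == 100
        assert np.all(np.diff(grid) < 0)

    def test_no_selection_at_lambda_max(self, rng):
        X = (rng.random((60, 8)) > 0.5).astype(float)
        times, events = survival_data(rng, X, np.r_[1.0, np.zeros(7)])
        grid = lambda_grid(X, times, events)
        res = cv_cox_lasso(X, times, events, grid, n_folds=4, seed=0)
        assert res.active_counts[0] == 0

    def test_rank_invariance_of_lambda_max(self, rng):
        X = (rng.random((50, 6)) > 0.5).astype(float)
        times, events = survival_data(rng, X, np.zeros(6))
        assert cox_lasso_lambda_max(X, times, events) == pytest.approx(
            cox_lasso_lambda_max(X, 2.0 * times, events), rel=1e-12)


class TestPartialLoglik:
    def test_matches_lifelines_at_fitted_beta(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd
        n = 60
        x = (rng.random(n) > 0.5).astype(float)
        times = rng.exponential(np.exp(-0.8 * x))
        df = pd.DataFrame({"x": x, "t": times, "e": np.ones(n, int)})
        cph = CoxPHFitter().fit(df, "t", "e")     # untied data: Efron == Breslow
        beta = cph.params_.to_numpy()
        ll = cox_partial_loglik(beta, x[:, None], times, np.ones(n, bool))
        assert ll == pytest.approx(cph.log_likelihood_, rel=1e-6)


class TestCvCoxLasso:
    def test_deterministic_given_seed(self, rng):
        X = (rng.random((60, 10)) > 0.5).astype(float)
        times, events = survival_data(rng, X, np.r_[1.2, np.zeros(9)])
        r1 = cv_cox_lasso(X, times, events, n_folds=5, seed=4)
        r2 = cv_cox_lasso(X, times, events, n_folds=5, seed=4)
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        np.testing.assert_array_equal(r1.selected_columns, r2.selected_columns)
        np.testing.assert_allclose(r1.cv_deviance_mean, r2.cv_deviance_mean)

    def test_informative_column_enters_path_first(self, rng):
        n = 120
        informative = (rng.random(n) > 0.5).astype(float)
        noise = rng.permutation(informative)
        X = np.column_stack([informative, noise])
        times, events = survival_data(rng, X, np.array([1.5, 0.0]))
        res = cv_cox_lasso(X, times, events, n_folds=4, seed=1)
        entry = [np.flatnonzero(res.coef_path[j] != 0) for j in range(2)]
        first_inf = entry[0][0] if entry[0].size else np.inf
        first_noise = entry[1][0] if entry[1].size else np.inf
        assert first_inf < first_noise

    def test_planted_voxel_recovered(self):
        hits = 0
        reps = 8
        for r in range(reps):
            rng = np.random.default_rng(900 + r)
            X = (rng.random((200, 100)) > 0.5).astype(float)
            beta = np.zeros(100)
            beta[37] = 1.2
            times, events = survival_data(rng, X, beta, censor_q=0.6)
            assert events.sum() >= 60
            res = cv_cox_lasso(X, times, events, n_folds=10, seed=r,
                               kept_voxel_indices=np.arange(100))
            hits += 37 in res.selected_columns
        assert hits / reps >= 0.8

    def test_null_design_selects_few(self):
        sparse = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(700 + r)
            X = (rng.random((150, 100)) > 0.5).astype(float)
            times, events = survival_data(rng, X, np.zeros(100), censor_q=0.5)
            res = cv_cox_lasso(X, times, events, n_folds=5, seed=r)
            sparse += len(res.selected_columns) <= 2
        assert sparse / reps >= 0.8

    def test_post_selection_refit_signs_match(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd
        X = (rng.random((250, 30)) > 0.5).astype(float)
        beta = np.zeros(30)
        beta[3], beta[11] = 1.3, -1.3
        times, events = survival_data(rng, X, beta, censor_q=0.7)
        res = cv_cox_lasso(X, times, events, n_folds=5, seed=2)
        assert res.selected_columns.size > 0
        df = pd.DataFrame(X[:, res.selected_columns],
                          columns=[f"v{j}" for j in res.selected_columns])
        df["t"], df["e"] = times, events
        cph = CoxPHFitter().fit(df, "t", "e")
        refit = cph.params_.to_numpy()
        assert np.all(np.sign(refit) == np.sign(res.selected_coefs))

    def test_zero_event_rejection(self, rng):
        X = (rng.random((20, 4)) > 0.5).astype(float)
        with pytest.raises(ValueError, match="zero events"):
            cv_cox_lasso(X, np.arange(20.0) + 1, np.zeros(20, int), n_folds=3, seed=0)

    def test_path_table_columns(self, rng):
        X = (rng.random((50, 5)) > 0.5).astype(float)
        times, events = survival_data(rng, X, np.zeros(5))
        res = cv_cox_lasso(X, times, events, n_folds=4, seed=0)
        tab = path_table(res)
        assert list(tab.columns) == ["lambda", "active_count",
                                     "cv_deviance_mean", "cv_deviance_se"]
        assert len(tab) == 100
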