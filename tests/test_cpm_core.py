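"""Edge selection, strength models, and cross-validated CPM."""

import numpy as np
import pytest
from scipy import stats

import cpmflow as cf
from cpmflow.cpm import (assign_folds, fit_fold_model, median_run_index,
                         predict, select_edges)


class TestAssignFolds:
    def test_sizes_differ_by_at_most_one(self):
        labels = assign_folds(69, 10, seed=1)
        sizes = sorted(np.bincount(labels, minlength=10))
        assert sizes == [6] + [7] * 9

    def test_ten_in_ten_is_leave_one_out(self):
        labels = assign_folds(10, 10, seed=3)
        assert sorted(labels) == list(range(10))

    def test_deterministic_in_seed(self):
        a, b = assign_folds(30, 5, seed=11), assign_folds(30, 5, seed=11)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, assign_folds(30, 5, seed=12))

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            assign_folds(5, 10, seed=0)


def brute_force_select(x, y, alpha):
    """Per-edge scipy.stats.pearsonr loop — the selection oracle."""
    pos = np.zeros(x.shape[1], dtype=bool)
    neg = np.zeros(x.shape[1], dtype=bool)
    for e in range(x.shape[1]):
        if np.ptp(x[:, e]) == 0:
            continue
        r, p = stats.pearsonr(x[:, e], y)
        pos[e] = r > 0 and p < alpha
        neg[e] = r < 0 and p < alpha
    return pos, neg


class TestSelectEdges:
    def test_matches_per_edge_pearsonr_loop(self, rng):
        for _ in range(10):
            x = rng.standard_normal((30, 80))
            y = rng.standard_normal(30)
            x[:, :5] += 0.8 * y[:, None]  # some real signal
            pos, neg = select_edges(x, y, alpha=0.05)
            opos, oneg = brute_force_select(x, y, 0.05)
            assert np.array_equal(pos, opos)
            assert np.array_equal(neg, oneg)

    def test_spearman_statistic_matches_rank_loop(self, rng):
        x = rng.standard_normal((40, 60))
        y = rng.standard_normal(40)
        x[:, :4] += y[:, None]
        pos, neg = select_edges(x, y, alpha=0.05, statistic="spearman")
        rx = stats.rankdata(x, axis=0)
        ry = stats.rankdata(y)
        opos, oneg = brute_force_select(rx, ry, 0.05)
        assert np.array_equal(pos, opos)
        assert np.array_equal(neg, oneg)

    def test_planted_edge_selected(self, rng):
        y = rng.standard_normal(50)
        x = rng.standard_normal((50, 10)) * 0.1
        x[:, 3] = y + 0.5 * rng.standard_normal(50)  # r ~ 0.9
        pos, neg = select_edges(x, y, alpha=0.01)
        assert pos[3] and not neg[3]

    def test_confound_controlled_by_partial_correlation(self, rng):
        confound = rng.standard_normal(60)
        y = confound + 0.3 * rng.standard_normal(60)
        x = rng.standard_normal((60, 5)) * 0.05
        x[:, 0] = confound
        pos, _ = select_edges(x, y, alpha=0.01)
        assert pos[0]  # selected when unadjusted
        ppos, pneg = select_edges(x, y, alpha=0.01, statistic="partial_pearson",
                                  train_covariates=confound[:, None])
        assert not ppos[0] and not pneg[0]

    def test_partial_matches_residualize_oracle(self, rng):
        c = rng.standard_normal((50, 2))
        y = c @ [0.5, -0.3] + rng.standard_normal(50)
        x = rng.standard_normal((50, 40))
        x[:, :3] += 0.5 * y[:, None]
        pos, neg = select_edges(x, y, alpha=0.05, statistic="partial_pearson",
                                train_covariates=c)
        design = np.column_stack([np.ones(50), c])
        proj = lambda v: v - design @ np.linalg.lstsq(design, v, rcond=None)[0]
        xr, yr = proj(x), proj(y)
        opos = np.zeros(40, dtype=bool)
        oneg = np.zeros(40, dtype=bool)
        for e in range(40):
            r = stats.pearsonr(xr[:, e], yr).statistic
            t = r * np.sqrt((50 - 2 - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), 50 - 2 - 2)
            opos[e], oneg[e] = (r > 0) & (p < 0.05), (r < 0) & (p < 0.05)
        assert np.array_equal(pos, opos)
        assert np.array_equal(neg, oneg)

    def test_zero_variance_edge_never_selected(self, rng):
        x = rng.standard_normal((20, 4))
        x[:, 2] = 7.0
        y = rng.standard_normal(20)
        pos, neg = select_edges(x, y, alpha=0.99)
        assert not pos[2] and not neg[2]

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            select_edges(rng.standard_normal((10, 3)), np.ones(10))

    def test_alpha_monotonicity(self, rng):
        x = rng.standard_normal((40, 200))
        y = rng.standard_normal(40)
        p1, n1 = select_edges(x, y, alpha=0.001)
        p2, n2 = select_edges(x, y, alpha=0.05)
        assert np.all(p2[p1]) and np.all(n2[n1])  # stricter alpha is a subset


class TestNetworkStrength:
    def test_empty_mask_is_zero(self):
        assert cf.network_strength(np.ones(6), np.zeros(6, dtype=bool)) == 0.0

    def test_three_edge_sum(self):
        edges = np.array([0.1, 0.2, -0.05, 9.0])
        mask = np.array([True, True, True, False])
        assert cf.network_strength(edges, mask) == pytest.approx(0.25)

    def test_matches_bruteforce_loop(self, rng):
        edges = rng.standard_normal(100)
        mask = rng.random(100) < 0.3
        expected = sum(v for v, m in zip(edges, mask) if m)
        assert cf.network_strength(edges, mask) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mask length"):
            cf.network_strength(np.ones(5), np.ones(4, dtype=bool))


class TestFoldModel:
    def test_noiseless_single_predictor_recovery(self):
        s = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.0 * s + 1.0
        m = fit_fold_model(s, np.zeros(4), y, "combined")
        preds = predict(m, np.array([3.0]), np.array([0.0]))
        assert preds[0] == pytest.approx(7.0)

    def test_coefficients_match_normal_equations(self, rng):
        sp = rng.standard_normal(50)
        sn = rng.standard_normal(50)
        y = 1.0 + 2.0 * sp - 0.5 * sn + 0.1 * rng.standard_normal(50)
        m = fit_fold_model(sp, sn, y, "combined")
        design = np.column_stack([np.ones(50), sp, sn])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)
        assert m.pos_coef == pytest.approx(beta[1], abs=1e-8)
        assert m.neg_coef == pytest.approx(beta[2], abs=1e-8)

    def test_constant_predictor_dropped_to_mean_model(self):
        y = np.array([1.0, 2.0, 3.0])
        m = fit_fold_model(np.zeros(3), np.zeros(3), y, "combined")
        assert m.pos_coef is None and m.neg_coef is None
        assert m.intercept == pytest.approx(2.0)

    def test_single_network_forms_ignore_other_strength(self, rng):
        sp = rng.standard_normal(30)
        y = 3.0 * sp
        m = fit_fold_model(sp, rng.standard_normal(30), y, "positive_only")
        assert m.neg_coef is None
        assert m.pos_coef == pytest.approx(3.0, abs=1e-8)


def _planted_problem(n=80, e=120, n_sig=8, noise=0.3, seed=5):
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    x = rng.standard_normal((n, e)) * noise
    sig = np.arange(n_sig)
    x[:, sig] += y[:, None]
    return x, y, sig


class TestRunCV:
    def test_no_leakage_from_heldout_behavior(self):
        x, y, _ = _planted_problem()
        config = cf.CPMConfig(n_folds=5, n_iterations=1, seed=9)
        run1 = cf.run_cv(x, y, config, iteration_seed=10)
        s = 0
        fold_of_s = run1.fold_assignment[s]
        y2 = y.copy()
        y2[s] += 100.0  # wildly different held-out behavior
        run2 = cf.run_cv(x, y2, config, iteration_seed=10)
        m1 = run1.fold_models[fold_of_s]
        m2 = run2.fold_models[fold_of_s]
        assert np.array_equal(m1.pos_mask, m2.pos_mask)
        assert np.array_equal(m1.neg_mask, m2.neg_mask)
        assert m1.intercept == m2.intercept
        assert m1.pos_coef == m2.pos_coef
        assert run1.predictions[s] == run2.predictions[s]

    def test_every_subject_predicted_once_and_metrics_finite(self):
        x, y, _ = _planted_problem()
        run = cf.run_cv(x, y, cf.CPMConfig(seed=0), iteration_seed=4)
        assert run.predictions.shape == y.shape
        assert -1.0 <= run.rho <= 1.0
        assert run.rmse >= 0.0
        assert run.rho > 0.5  # strong planted signal

    def test_empty_selection_predicts_training_mean(self, rng):
        x = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        config = cf.CPMConfig(n_folds=3, selection_alpha=1e-12, seed=0)
        run = cf.run_cv(x, y, config, iteration_seed=2)
        assert run.degenerate
        f0 = run.fold_assignment == 0
        assert np.allclose(run.predictions[f0], y[~f0].mean())

    def test_shuffled_behavior_rho_near_zero(self):
        x, y, _ = _planted_problem(seed=8)
        rng = np.random.default_rng(0)
        rhos = [cf.run_cv(x, y[rng.permutation(len(y))],
                          cf.CPMConfig(seed=0), iteration_seed=100 + i).rho
                for i in range(20)]
        assert abs(np.mean(rhos)) < 0.15


class TestRunCPM:
    def test_median_run_order_statistic(self):
        assert median_run_index(np.array([0.1, 0.5, 0.3])) == 2
        assert median_run_index(np.array([0.9])) == 0
        # even count: lower middle
        assert median_run_index(np.array([0.4, 0.1, 0.3, 0.2])) == 3

    def test_single_iteration_is_median(self):
        x, y, _ = _planted_problem()
        res = cf.run_cpm(x, y, cf.CPMConfig(n_iterations=1, seed=3))
        assert res.median_run_index == 0
        assert res.rho_median == res.runs[0].rho

    def test_noiseless_consensus_recovers_planted_edges_exactly(self):
        x, y, sig = _planted_problem(noise=1e-8, e=60, n_sig=6, seed=2)
        res = cf.run_cpm(x, y, cf.CPMConfig(n_iterations=3, seed=1,
                                            consensus_fraction=1.0))
        expected = np.zeros(60, dtype=bool)
        expected[sig] = True
        assert np.array_equal(res.consensus_pos, expected)
        assert res.rho_median > 0.99

    def test_bit_identical_under_same_seed(self):
        x, y, _ = _planted_problem()
        cfg = cf.CPMConfig(n_iterations=5, seed=77)
        r1 = cf.run_cpm(x, y, cfg)
        r2 = cf.run_cpm(x, y, cfg)
        assert r1.median_run_index == r2.median_run_index
        assert np.array_equal(r1.median_run.predictions, r2.median_run.predictions)
        assert np.array_equal(r1.consensus_pos, r2.consensus_pos)
        assert [run.rho for run in r1.runs] == [run.rho for run in r2.runs]

    def test_rho_median_equals_selected_runs_rho(self):
        x, y, _ = _planted_problem()
        res = cf.run_cpm(x, y, cf.CPMConfig(n_iterations=4, seed=5))
        rhos = [r.rho for r in res.runs]
        assert res.rho_median == sorted(rhos)[(len(rhos) - 1) // 2]

    def test_missing_behavior_dropped_listwise(self):
        x, y, _ = _planted_problem()
        y = y.copy()
        y[[1, 7, 11]] = np.nan
        res = cf.run_cpm(x, y, cf.CPMConfig(n_iterations=1, seed=2))
        assert res.n_dropped == 3
        assert len(res.median_run.predictions) == len(y) - 3

    def test_named_covariate_missing_from_table_rejected(self):
        x, y, _ = _planted_problem()
        import pandas as pd
        cov = pd.DataFrame({"motion": np.zeros(len(y))})
        cfg = cf.CPMConfig(n_iterations=1, covariates=("age",))
        with pytest.raises(ValueError, match="age"):
            cf.run_cpm(x, y, cfg, cov)
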