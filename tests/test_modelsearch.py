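import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zosrec import modelsearch as ms


def feat_frame(rng, n=20, p=6, prefix="x"):
    cols = [f"{prefix}{j}" for j in range(p)]
    return pd.DataFrame(rng.normal(0, 1, (n, p)), columns=cols,
                        index=pd.RangeIndex(n, name="census_year"))


class TestScreen:
    def test_exact_predictor_retained_with_r_one(self, rng):
        X = feat_frame(rng)
        y = X["x0"] * 1.0
        out = ms.screen(X, y)
        hit = [s for s in out if s.label == "x0"]
        assert hit and hit[0].r == pytest.approx(1.0)

    def test_critical_r_at_n7_matches_t_quantile(self):
        # two-tailed P<0.05 with 5 df <=> |r| > t/sqrt(t^2+5)
        t = stats.t.ppf(0.975, 5)
        r_crit = t / np.sqrt(t**2 + 5)
        assert r_crit == pytest.approx(0.754, abs=1e-3)
        X = np.linspace(-1, 1, 7)
        for r_target, keep in ((0.80, True), (0.70, False)):
            noise = X * r_target + np.sqrt(1 - r_target**2) * np.array(
                [0.3, -1.2, 0.8, -0.1, 0.5, -0.9, 0.6])
            r, p = stats.pearsonr(X, noise)
            assert (p < 0.05) == (abs(r) > r_crit)

    def test_null_predictors_screen_near_alpha_before_stability(self, rng):
        n, p = 30, 1000
        X = feat_frame(rng, n=n, p=p)
        y = pd.Series(rng.normal(0, 1, n), index=X.index)
        r, pv = ms._corr_pvals(X.to_numpy(), y.to_numpy())
        frac = (pv < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_constant_predictor_excluded(self, rng):
        X = feat_frame(rng, p=2)
        X["flat"] = 2.0
        y = X["x0"]
        assert all(s.label != "flat" for s in ms.screen(X, y))

    def test_single_outlier_driven_correlation_dropped(self, rng):
        n = 20
        x = np.zeros(n)
        x[0] = 10.0  # all dispersion in one year
        y = pd.Series(x * 0.5 + rng.normal(0, 0.1, n))
        X = pd.DataFrame({"lev": x})
        assert ms.screen(X, y) == []


class TestCollinearityGroups:
    def make_screened(self, X, y):
        return ms.screen(X, y, alpha=1.1)  # keep everything; grouping under test

    def test_duplicated_predictor_grouped_and_culled(self, rng):
        X = feat_frame(rng, p=2)
        X["dup"] = X["x0"]
        y = X["x0"] + 0.1 * X["x1"]
        groups = ms.collinearity_groups(self.make_screened(X, y), X, max_per_group=1)
        flat = [g for g in groups if "x0" in g or "dup" in g]
        assert len(flat) == 1 and len(flat[0]) == 1

    def test_three_way_chain_forms_one_group(self, rng):
        z = rng.normal(0, 1, 300)
        X = pd.DataFrame({
            "a": z + rng.normal(0, 0.25, 300),
            "b": z + rng.normal(0, 0.25, 300),
            "c": z + rng.normal(0, 0.55, 300),
        })
        y = pd.Series(z)
        groups = ms.collinearity_groups(self.make_screened(X, y), X)
        assert len(groups) == 1 and set(groups[0]) == {"a", "b", "c"}

    def test_uncorrelated_predictors_stay_singletons(self, rng):
        X = feat_frame(rng, n=500, p=4)
        screened = [ms.ScreenResult(c, 0.5, 0.01, 500) for c in X.columns]
        groups = ms.collinearity_groups(screened, X)
        assert sorted(len(g) for g in groups) == [1, 1, 1, 1]

    def test_dispersion_statistics_culled_before_location(self, rng):
        z = rng.normal(0, 1, 200)
        X = pd.DataFrame({
            "mRWE_pFeb": z + rng.normal(0, 0.1, 200),
            "sdRWE_pFeb": z + rng.normal(0, 0.1, 200),
        })
        y = pd.Series(z)
        groups = ms.collinearity_groups(self.make_screened(X, y), X, max_per_group=1)
        assert groups == [["mRWE_pFeb"]]


def brute_force_best_subsets(X, y, predictors):
    out = {}
    yv = y.to_numpy()
    tss = ((yv - yv.mean()) ** 2).sum()
    for size in range(1, len(predictors) + 1):
        best = None
        for combo in itertools.combinations(predictors, size):
            A = np.column_stack([np.ones(len(X)), X[list(combo)].to_numpy()])
            beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
            r2 = 1 - ((yv - A @ beta) ** 2).sum() / tss
            if best is None or r2 > best[1]:
                best = (combo, r2)
        out[size] = best
    return out


class TestAllSubsetsAndRevs:
    def test_matches_brute_force_oracle_up_to_p5(self, rng):
        X = feat_frame(rng, n=25, p=5)
        y = X["x0"] * 2 - X["x3"] + pd.Series(rng.normal(0, 0.5, 25), index=X.index)
        got = ms.all_subsets(X, y, list(X.columns))
        want = brute_force_best_subsets(X, y, list(X.columns))
        for size in want:
            assert set(got[size][0]) == set(want[size][0])
            assert got[size][1] == pytest.approx(want[size][1])

    def test_dominant_predictor_ranked_first_every_time(self):
        wins = 0
        for s in range(100):
            r = np.random.default_rng(s)
            X = feat_frame(r, n=25, p=4)
            y = X["x2"] * 3 + pd.Series(r.normal(0, 0.3, 25), index=X.index)
            order = ms._importance_order(X, y, list(X.columns))
            wins += order[0] == "x2"
        assert wins == 100

    def test_nested_candidate_sequence_has_nondecreasing_r2(self, rng):
        X = feat_frame(rng, n=25, p=4)
        y = X["x0"] - 0.5 * X["x1"] + pd.Series(rng.normal(0, 0.4, 25), index=X.index)
        cands = ms.revs([[c] for c in X.columns], X, y)
        by_preds = {m.predictors: m for m in cands}
        nested = [m for m in cands if set(m.predictors) <= {"x0", "x1", "x2", "x3"}]
        seq = sorted(nested, key=lambda m: len(m.predictors))
        for a, b in zip(seq, seq[1:]):
            if set(a.predictors) <= set(b.predictors):
                assert b.r2 >= a.r2 - 1e-12

    def test_oversized_combination_skipped_with_warning(self, rng):
        X = feat_frame(rng, n=6, p=5)
        y = pd.Series(rng.normal(0, 1, 6), index=X.index)
        with pytest.warns(UserWarning, match="p > n - 2"):
            ms.revs([[c] for c in X.columns], X, y)


class TestDiagnostics:
    def test_orthonormal_design_has_unit_vifs(self, rng):
        n = 24
        q, _ = np.linalg.qr(rng.normal(0, 1, (n, 3)))
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        y = pd.Series(q @ np.array([1.0, 2.0, 0.5]) + rng.normal(0, 0.2, n))
        m = ms.fit_candidate(X, y, ("a", "b", "c"))
        assert all(v == pytest.approx(1.0, abs=0.15) for v in m.vif.values())

    def test_duplicated_predictor_fails_vif(self, rng):
        X = feat_frame(rng, n=25, p=1)
        X["dup"] = X["x0"] + rng.normal(0, 1e-6, 25)
        y = X["x0"] + pd.Series(rng.normal(0, 0.1, 25), index=X.index)
        m = ms.diagnostics(ms.fit_candidate(X, y, ("x0", "dup")))
        assert max(m.vif.values()) > 10
        assert "multicollinearity (VIF)" in m.diag_fail_reasons

    def test_durbin_watson_near_two_for_white_noise(self):
        dws = []
        for s in range(30):
            r = np.random.default_rng(s)
            X = feat_frame(r, n=100, p=2)
            y = X["x0"] + pd.Series(r.normal(0, 1, 100), index=X.index)
            dws.append(ms.fit_candidate(X, y, ("x0", "x1")).dw)
        assert np.mean(dws) == pytest.approx(2.0, abs=0.15)

    def test_unfittable_model_rejected(self, rng):
        X = feat_frame(rng, n=4, p=3)
        y = pd.Series(rng.normal(0, 1, 4), index=X.index)
        with pytest.raises(ValueError, match="unfittable"):
            ms.fit_candidate(X, y, ("x0", "x1", "x2"))


class TestAiccWeights:
    def mk(self, aicc):
        m = ms.CandidateModel(
            predictors=("x",), params=pd.Series(dtype=float), cov=pd.DataFrame(),
            adj_r2=0, r2=0, aic=aicc - 1, aicc=aicc, resid_var=1, nobs=10, vif={},
            cp=2, shapiro_p=0.5, bp_p=0.5, dw=2.0, max_cooks_d=0.1,
            loocv_rmse=1.0, loocv_se=0.1, f_pvalue=0.01)
        return m

    def test_single_model_gets_weight_one(self):
        w = ms.aicc_weights([self.mk(10.0)])
        assert w[0] == pytest.approx(1.0)

    def test_delta_two_closed_form(self):
        w = ms.aicc_weights([self.mk(10.0), self.mk(12.0)])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1)))
        assert w[1] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)))

    def test_weights_sum_to_one_and_monotone(self, rng):
        models = [self.mk(a) for a in rng.uniform(5, 40, 9)]
        w = ms.aicc_weights(models)
        assert w.sum() == pytest.approx(1.0)
        order = np.argsort([m.aicc for m in models])
        assert np.all(np.diff(w[order]) <= 1e-15)

    def test_permutation_invariance(self, rng):
        models = [self.mk(a) for a in (11.0, 14.0, 9.0)]
        w = ms.aicc_weights(models)
        w_rev = ms.aicc_weights(models[::-1])
        assert np.allclose(w, w_rev[::-1])

    def test_undefined_correction_excluded(self):
        good, bad = self.mk(10.0), self.mk(float("inf"))
        with pytest.warns(UserWarning, match="excluded"):
            w = ms.aicc_weights([good, bad])
        assert w[1] == 0.0 and w.sum() == pytest.approx(1.0)


class TestLoocv:
    def test_noiseless_linear_data_has_zero_rmse(self, rng):
        X = feat_frame(rng, n=15, p=2)
        y = 2 * X["x0"] - X["x1"] + 3
        assert ms.loocv_rmse(X, y, ("x0", "x1")) == pytest.approx(0.0, abs=1e-10)

    def test_shortcut_equals_explicit_refits(self, rng):
        X = feat_frame(rng, n=18, p=3)
        y = X["x0"] + pd.Series(rng.normal(0, 1, 18), index=X.index)
        # check_identity raises if the hat-matrix shortcut and the explicit
        # n-refit loop disagree beyond 1e-10 relative
        rmse = ms.loocv_rmse(X, y, ("x0", "x1", "x2"), check_identity=True)
        assert rmse > 0

    def test_noise_predictor_does_not_improve_expected_loocv(self):
        diffs = []
        for s in range(100):
            r = np.random.default_rng(s)
            X = feat_frame(r, n=20, p=3)
            y = X["x0"] + pd.Series(r.normal(0, 0.5, 20), index=X.index)
            base = ms.loocv_rmse(X, y, ("x0",))
            noisy = ms.loocv_rmse(X, y, ("x0", "x2"))
            diffs.append(noisy - base)
        assert np.mean(diffs) > 0

    def test_too_small_sample_rejected(self, rng):
        X = feat_frame(rng, n=4, p=3)
        y = pd.Series(rng.normal(0, 1, 4), index=X.index)
        with pytest.raises(ValueError):
            ms.loocv_rmse(X, y, ("x0", "x1", "x2"))


class TestSelectBest:
    def test_single_passer_returned(self, rng):
        X = feat_frame(rng, n=25, p=3)
        y = X["x0"] + pd.Series(rng.normal(0, 0.3, 25), index=X.index)
        cands = ms.revs([["x0"]], X, y)
        best, audit = ms.select_best(cands)
        assert best.predictors == ("x0",)
        assert not audit.empty

    def test_no_passers_raises_with_failure_modes(self, rng):
        X = feat_frame(rng, n=25, p=1)
        X["dup"] = X["x0"] + rng.normal(0, 1e-8, 25)
        y = X["x0"] + pd.Series(rng.normal(0, 0.2, 25), index=X.index)
        m = ms.diagnostics(ms.fit_candidate(X, y, ("x0", "dup")))
        with pytest.raises(ValueError, match="failure modes"):
            ms.select_best([m])

    def test_true_model_selected_when_among_candidates(self):
        # truth model guaranteed in the candidate pool (grouping fixed);
        # selection should pick a truth-containing model in >= 90% of runs
        wins = total = 0
        for s in range(50):
            r = np.random.default_rng(s)
            X = feat_frame(r, n=25, p=4)
            y = 2 * X["x1"] - 2 * X["x3"] + pd.Series(r.normal(0, 0.4, 25), index=X.index)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cands = ms.revs([[c] for c in X.columns], X, y)
            try:
                best, _ = ms.select_best(cands)
            except ValueError:
                continue  # no diagnostics passer: selection not exercised
            total += 1
            wins += {"x1", "x3"} <= set(best.predictors)
        assert total >= 40
        assert wins / total >= 0.90
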