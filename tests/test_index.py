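"""Mahalanobis index, ANOVA/Dunnett inference, dose-response classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ethomarker import discriminant as da
from ethomarker import index as ix


def _table(rng, concs=(0.0, 1.0, 2.0, 4.0), n_per=3, p=3, slope=0.0, noise=1.0):
    """Feature table whose group means drift linearly with concentration."""
    rows, groups = [], []
    for c in concs:
        centre = slope * c * np.ones(p)
        rows.append(centre + rng.normal(0, noise, size=(n_per, p)))
        groups.extend([c] * n_per)
    return da.FeatureTable(
        X=pd.DataFrame(np.vstack(rows), columns=[f"x{j}" for j in range(p)]),
        groups=pd.Series(groups),
    )


def _index_frame(values_by_group):
    rows = []
    for g, vals in values_by_group.items():
        for v in vals:
            rows.append({"observation": len(rows), "condition": g, "d2": v})
    return pd.DataFrame(rows)


class TestMahalanobisIndex:
    def test_control_centroid_scores_zero(self):
        rng = np.random.default_rng(0)
        t = _table(rng)
        m = da.fit_lda(t, tuple(t.X.columns))
        idx = ix.mahalanobis_index(m, t)
        ctl_mean = m.group_means[0]
        probe = da.FeatureTable(
            X=pd.DataFrame([ctl_mean] * 4, columns=t.X.columns),
            groups=pd.Series([0.0, 0.0, 1.0, 1.0]),
        )
        d2 = ix.mahalanobis_index(m, probe)["d2"]
        assert np.allclose(d2, 0.0, atol=1e-12)
        assert (idx["d2"] >= 0).all()

    def test_matches_whitening_oracle(self):
        # independent route: Cholesky-whiten, then plain Euclidean distance
        rng = np.random.default_rng(1)
        t = _table(rng, slope=1.0)
        m = da.fit_lda(t, tuple(t.X.columns))
        idx = ix.mahalanobis_index(m, t)
        L = np.linalg.cholesky(m.pooled_cov)
        ctl = m.group_means[0]
        for i, row in enumerate(t.X.to_numpy()):
            z = np.linalg.solve(L, row - ctl)
            assert idx["d2"].iloc[i] == pytest.approx(float(z @ z), rel=1e-9)

    def test_affine_invariance_of_index(self):
        rng = np.random.default_rng(2)
        t = _table(rng, slope=0.5)
        scale = np.array([4.0, 0.1, 7.0])
        t2 = da.FeatureTable(
            X=pd.DataFrame(t.X.to_numpy() * scale + 3.0, columns=t.X.columns),
            groups=t.groups,
        )
        i1 = ix.mahalanobis_index(da.fit_lda(t, tuple(t.X.columns)), t)
        i2 = ix.mahalanobis_index(da.fit_lda(t2, tuple(t2.X.columns)), t2)
        assert np.allclose(i1["d2"], i2["d2"], rtol=1e-9)

    def test_explicit_control_label(self):
        rng = np.random.default_rng(3)
        t = _table(rng)
        m = da.fit_lda(t, tuple(t.X.columns))
        idx = ix.mahalanobis_index(m, t, control=2.0)
        ctl_rows = idx[idx["condition"] == 2.0]["d2"]
        assert ctl_rows.min() < idx[idx["condition"] == 0.0]["d2"].min() + ctl_rows.sum()
        with pytest.raises(ValueError, match="control"):
            ix.mahalanobis_index(m, t, control=99.0)


class TestAnova:
    def test_df_for_8_groups_of_3(self):
        rng = np.random.default_rng(4)
        vals = {c: rng.normal(c, 1, 3) for c in range(8)}
        res = ix.anova_on_index(_index_frame(vals))
        assert res.df == (7, 16)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        vals = {c: rng.normal(0, 1, 4) for c in range(5)}
        res = ix.anova_on_index(_index_frame(vals))
        F, p = stats.f_oneway(*vals.values())
        assert res.F == pytest.approx(F) and res.p == pytest.approx(p)

    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        res = ix.anova_on_index(_index_frame({0.0: a, 1.0: b}))
        tstat = stats.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(tstat**2, rel=1e-9)

    def test_all_identical_values_noted(self):
        res = ix.anova_on_index(_index_frame({0.0: [1.0, 1.0], 1.0: [1.0, 1.0]}))
        assert np.isnan(res.F) and "identical" in res.note


class TestDunnett:
    def test_matches_scipy_dunnett_pvalues(self):
        rng = np.random.default_rng(7)
        vals = {c: rng.normal(0.4 * c, 1, 5) for c in range(4)}
        idx = _index_frame(vals)
        res = ix.dunnett_test(idx, 0, mc_draws=2_000_000, seed=3)
        sp = stats.dunnett(vals[1], vals[2], vals[3], control=vals[0])
        assert np.allclose(res.comparisons["p_adjusted"], sp.pvalue, atol=2e-3)

    def test_all_equal_groups_p_one(self):
        idx = _index_frame({c: [2.0, 2.0, 2.0] for c in range(4)})
        res = ix.dunnett_test(idx, 0, mc_draws=10_000, seed=0)
        assert (res.comparisons["p_adjusted"] == 1.0).all()
        assert not res.comparisons["significant"].any()

    def test_two_groups_reduces_to_t_test(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 6), rng.normal(2, 1, 6)
        idx = _index_frame({0.0: a, 1.0: b})
        res = ix.dunnett_test(idx, 0.0, mc_draws=500_000, seed=1)
        t = stats.ttest_ind(b, a)  # same group - reference sign convention
        assert res.comparisons["t"].iloc[0] == pytest.approx(t.statistic, rel=1e-9)
        assert res.comparisons["p_adjusted"].iloc[0] == pytest.approx(t.pvalue, abs=2e-3)

    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(9)
        vals = {c: rng.normal(0.3 * c, 1, 3) for c in range(6)}
        idx = _index_frame(vals)
        res = ix.dunnett_test(idx, 0, mc_draws=100_000, seed=2)
        for _, row in res.comparisons.iterrows():
            p_un = 2 * stats.t.sf(abs(row["t"]), res.df_error)
            assert row["p_adjusted"] >= p_un - 1e-12

    def test_p_monotone_in_abs_t(self):
        rng = np.random.default_rng(10)
        vals = {c: rng.normal(0.5 * c, 1, 4) for c in range(5)}
        res = ix.dunnett_test(_index_frame(vals), 0, mc_draws=100_000, seed=4)
        comp = res.comparisons.assign(abs_t=lambda d: d["t"].abs()).sort_values("abs_t")
        assert comp["p_adjusted"].is_monotonic_decreasing

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(11)
        vals = {c: rng.normal(c, 1, 3) for c in range(4)}
        idx = _index_frame(vals)
        r1 = ix.dunnett_test(idx, 0, mc_draws=50_000, seed=7)
        r2 = ix.dunnett_test(idx, 0, mc_draws=50_000, seed=7)
        pd.testing.assert_frame_equal(r1.comparisons, r2.comparisons)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            ix.dunnett_test(_index_frame({0.0: [1, 2], 1.0: [3, 4]}), 9.0)


class TestClassifyDoseResponse:
    @staticmethod
    def _verdict(vals, seed=0):
        idx = _index_frame(vals)
        anova = ix.anova_on_index(idx)
        peak = idx.groupby("condition")["d2"].mean().idxmax()
        d_peak = ix.dunnett_test(idx, peak, mc_draws=100_000, seed=seed)
        return ix.classify_dose_response(idx, anova, d_peak)

    def test_strictly_increasing_means_monotone_tau_one(self):
        rng = np.random.default_rng(12)
        vals = {c: c * 10.0 + rng.normal(0, 0.1, 3) for c in [0.0, 1.0, 2.0, 4.0]}
        v = self._verdict(vals)
        assert v.pattern == "monotone"
        assert v.peak_group == 4.0
        assert v.monotonicity_score == pytest.approx(1.0)

    def test_slight_nonsignificant_drop_at_top_is_plateau(self):
        rng = np.random.default_rng(13)
        vals = {0.0: rng.normal(0, 1, 4), 1.0: rng.normal(20, 1, 4),
                2.0: rng.normal(19.5, 1, 4)}
        v = self._verdict(vals)
        assert v.pattern == "plateau"
        assert not v.top_dose_significantly_below_peak

    def test_strong_top_dose_reversal_is_non_monotone(self):
        rng = np.random.default_rng(14)
        vals = {0.0: rng.normal(0, 0.2, 4), 1.0: rng.normal(30, 0.2, 4),
                2.0: rng.normal(2, 0.2, 4)}
        v = self._verdict(vals)
        assert v.pattern == "non-monotone"
        assert v.top_dose_significantly_below_peak
        assert v.monotonicity_score < 1.0


class TestSelectFinalModel:
    @staticmethod
    def _candidates(table, pool):
        res = da.best_subsets_exhaustive(table, pool)
        perfect = da.collect_perfect_models(res)
        return perfect if perfect else res[:3]

    def test_monotone_candidate_chosen(self):
        rng = np.random.default_rng(15)
        t = _table(rng, concs=(0.0, 1.0, 2.0, 4.0), n_per=4, p=3,
                   slope=5.0, noise=0.3)
        cands = self._candidates(t, tuple(t.X.columns))
        sel = ix.select_final_model(cands, t, mc_draws=50_000, seed=0)
        assert sel.chosen is not None
        assert sel.chosen_verdict.pattern in ("monotone", "plateau")
        assert len(sel.audit) == len(cands)
        assert (sel.audit["anova_p"] < 0.05).any()

    def test_candidate_order_does_not_change_choice(self):
        rng = np.random.default_rng(16)
        t = _table(rng, slope=4.0, noise=0.3, n_per=4)
        cands = self._candidates(t, tuple(t.X.columns))
        sel1 = ix.select_final_model(cands, t, mc_draws=20_000, seed=1)
        sel2 = ix.select_final_model(list(reversed(cands)), t, mc_draws=20_000, seed=1)
        assert sel1.chosen.subset == sel2.chosen.subset

    def test_null_data_warns_and_chooses_none(self):
        rng = np.random.default_rng(17)
        t = _table(rng, slope=0.0, noise=1.0, n_per=4)
        res = da.best_subsets_exhaustive(t, tuple(t.X.columns))
        with pytest.warns(UserWarning, match="none chosen"):
            sel = ix.select_final_model(res[:2], t, mc_draws=20_000, seed=2)
        assert sel.chosen is None and sel.chosen_verdict is None

    def test_empty_candidates_rejected(self):
        rng = np.random.default_rng(18)
        t = _table(rng)
        with pytest.raises(ValueError, match="empty"):
            ix.select_final_model([], t)
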