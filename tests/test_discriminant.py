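"""LDA classification, exact LOOCV, and best-subset searches."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ethomarker import discriminant as da


def _table(rng, n_groups=3, n_per=6, p=4, sep=3.0, names=None):
    centres = rng.normal(0, sep, size=(n_groups, p))
    X = np.vstack([c + rng.normal(0, 1, size=(n_per, p)) for c in centres])
    groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per)
    names = names or tuple(f"x{j}" for j in range(p))
    return da.FeatureTable(
        X=pd.DataFrame(X, columns=list(names)),
        groups=pd.Series(groups),
        provenance={c: "biomarker" for c in names},
    )


class TestFeatureTable:
    def test_rank_bound_is_n_minus_g(self):
        t = _table(np.random.default_rng(0), n_groups=3, n_per=6)
        assert t.rank_bound == 18 - 3

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="align"):
            da.FeatureTable(X=pd.DataFrame({"a": [1.0, 2.0]}), groups=pd.Series(["g"]))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            da.FeatureTable(
                X=pd.DataFrame({"a": [1.0, 2.0, 3.0]}),
                groups=pd.Series(["g1", "g1", "g2"]),
            )


class TestFitAndPredict:
    def test_midpoint_is_decision_boundary(self):
        # two 1-D groups with equal spread: boundary at the midpoint of means
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
        t = da.FeatureTable(X=X, groups=pd.Series(["lo"] * 3 + ["hi"] * 3))
        m = da.fit_lda(t, ("a",))
        assert da.predict(m, np.array([[5.9]]))[0] == "lo"
        assert da.predict(m, np.array([[6.1]]))[0] == "hi"

    def test_training_data_duplication_invariance(self):
        rng = np.random.default_rng(1)
        t = _table(rng)
        t2 = da.FeatureTable(
            X=pd.concat([t.X, t.X], ignore_index=True),
            groups=pd.concat([t.groups, t.groups], ignore_index=True),
        )
        m1 = da.fit_lda(t, ("x0", "x1"))
        m2 = da.fit_lda(t2, ("x0", "x1"))
        probe = rng.normal(size=(50, 2))
        assert np.array_equal(da.predict(m1, probe), da.predict(m2, probe))

    def test_matches_sklearn_lda_predictions(self):
        rng = np.random.default_rng(2)
        t = _table(rng, n_groups=4, n_per=8, p=5, sep=1.5)
        m = da.fit_lda(t, tuple(t.X.columns))
        sk = LinearDiscriminantAnalysis(priors=np.full(4, 0.25))
        sk.fit(t.X.to_numpy(), t.groups.to_numpy())
        probe = rng.normal(0, 3, size=(200, 5))
        assert np.array_equal(da.predict(m, probe), sk.predict(probe))

    def test_matches_explicit_mahalanobis_oracle(self):
        rng = np.random.default_rng(3)
        t = _table(rng, n_groups=3, n_per=7, p=3, sep=1.0)
        sub = ("x0", "x2")
        m = da.fit_lda(t, sub)
        probe = rng.normal(size=(30, 2))
        # independent route: explicit solve per point and per group
        for row in probe:
            d2 = [
                float((row - mu) @ np.linalg.solve(m.pooled_cov, row - mu))
                for mu in m.group_means
            ]
            assert da.predict(m, row[None, :])[0] == m.group_labels[int(np.argmin(d2))]

    def test_affine_feature_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        t = _table(rng, p=3)
        scale = np.array([10.0, 0.2, 3.0])
        shift = np.array([5.0, -1.0, 0.0])
        t2 = da.FeatureTable(
            X=pd.DataFrame(t.X.to_numpy() * scale + shift, columns=t.X.columns),
            groups=t.groups,
        )
        probe = rng.normal(size=(40, 3))
        m1 = da.fit_lda(t, tuple(t.X.columns))
        m2 = da.fit_lda(t2, tuple(t.X.columns))
        assert np.array_equal(da.predict(m1, probe), da.predict(m2, probe * scale + shift))

    def test_oversized_subset_rejected_with_rank_bound(self):
        t = _table(np.random.default_rng(5), n_groups=3, n_per=3, p=8)
        with pytest.raises(ValueError, match="N - G"):
            da.fit_lda(t, tuple(t.X.columns))

    def test_duplicated_column_subset_singular(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 1))
        t = da.FeatureTable(
            X=pd.DataFrame(np.hstack([X, X]), columns=["a", "b"]),
            groups=pd.Series(np.repeat(["g0", "g1"], 6)),
        )
        with pytest.raises(da.SingularSubsetError):
            da.fit_lda(t, ("a", "b"))


class TestLOOCV:
    def test_downdate_equals_naive_refit_all_folds(self):
        rng = np.random.default_rng(7)
        t = _table(rng, n_groups=3, n_per=6, p=4, sep=1.0)
        sub = ("x0", "x1", "x3")
        _, pred = da.loocv_error(t, sub)
        # oracle: literally drop row i and refit from scratch
        for i in range(t.n_obs):
            keep = np.arange(t.n_obs) != i
            t_i = da.FeatureTable(
                X=t.X.loc[keep].reset_index(drop=True),
                groups=t.groups.loc[keep].reset_index(drop=True),
            )
            m_i = da.fit_lda(t_i, sub)
            assert da.predict(m_i, t.X.iloc[[i]])[0] == pred[i], f"fold {i}"

    def test_well_separated_groups_zero_error(self):
        rng = np.random.default_rng(8)
        t = _table(rng, n_groups=4, n_per=5, p=3, sep=50.0)
        err, _ = da.loocv_error(t, tuple(t.X.columns))
        assert err == 0.0

    def test_error_is_fraction_of_mismatches(self):
        rng = np.random.default_rng(9)
        t = _table(rng, sep=0.5)
        err, pred = da.loocv_error(t, ("x0",))
        assert err == pytest.approx(np.mean(pred != t.groups.to_numpy()))


class TestSubsetSearch:
    def test_exhaustive_enumerates_all_nonempty_subsets(self):
        rng = np.random.default_rng(10)
        t = _table(rng, p=3)
        res = da.best_subsets_exhaustive(t, tuple(t.X.columns))
        assert len(res) == 2**3 - 1
        assert {frozenset(r.subset) for r in res} == {
            frozenset(s)
            for k in (1, 2, 3)
            for s in itertools.combinations(t.X.columns, k)
        }

    def test_results_sorted_by_error_then_size(self):
        rng = np.random.default_rng(11)
        t = _table(rng, p=4, sep=1.0)
        res = da.best_subsets_exhaustive(t, tuple(t.X.columns))
        keys = [(r.loocv_error if r.loocv_error is not None else np.inf,
                 r.n_effects, r.subset) for r in res]
        assert keys == sorted(keys)

    def test_oversized_pool_refused(self):
        t = _table(np.random.default_rng(12), p=4)
        with pytest.raises(ValueError, match="fixed_size"):
            da.best_subsets_exhaustive(t, tuple(f"x{i}" for i in range(21)))

    def test_fixed_size_k_above_rank_bound_rejected(self):
        # 24 obs in 8 groups: rank bound 16, so k = 17 is unfittable
        rng = np.random.default_rng(13)
        X = rng.normal(size=(24, 18))
        t = da.FeatureTable(
            X=pd.DataFrame(X, columns=[f"x{i}" for i in range(18)]),
            groups=pd.Series(np.repeat([f"g{i}" for i in range(8)], 3)),
        )
        assert t.rank_bound == 16
        with pytest.raises(ValueError, match="N - G"):
            da.best_subsets_fixed_size(t, tuple(t.X.columns), 17)
        # boundary: k = 16 from a 16-column pool is exactly one subset
        res = da.best_subsets_fixed_size(t, tuple(t.X.columns)[:16], 16)
        assert len(res) == 1

    def test_union_of_fixed_sizes_equals_exhaustive(self):
        rng = np.random.default_rng(14)
        t = _table(rng, p=4, sep=1.0)
        pool = tuple(t.X.columns)
        exhaustive = da.best_subsets_exhaustive(t, pool)
        union = []
        for k in range(1, 5):
            union.extend(da.best_subsets_fixed_size(t, pool, k))
        assert sorted(r.subset for r in union) == sorted(r.subset for r in exhaustive)
        by_sub = {r.subset: r.loocv_error for r in union}
        assert all(by_sub[r.subset] == r.loocv_error for r in exhaustive)

    def test_collect_perfect_models(self):
        rng = np.random.default_rng(15)
        t = _table(rng, n_groups=3, n_per=6, p=3, sep=40.0)
        res = da.best_subsets_exhaustive(t, tuple(t.X.columns))
        perfect = da.collect_perfect_models(res)
        assert perfect, "well-separated groups should yield perfect models"
        assert all(r.loocv_error == 0.0 and r.status == "ok" for r in perfect)
        # idempotent and de-duplicating
        again = da.collect_perfect_models([res, res])
        assert [r.subset for r in again] == [r.subset for r in perfect]

    def test_collect_perfect_empty_when_overlapping(self):
        rng = np.random.default_rng(16)
        # one shared cloud split arbitrarily into 3 'groups': no perfect model
        X = rng.normal(size=(30, 2))
        t = da.FeatureTable(
            X=pd.DataFrame(X, columns=["a", "b"]),
            groups=pd.Series(np.repeat(["g0", "g1", "g2"], 10)),
        )
        res = da.best_subsets_exhaustive(t, ("a", "b"))
        assert da.collect_perfect_models(res) == []

    def test_provenance_counts_in_results(self):
        rng = np.random.default_rng(17)
        t = _table(rng, p=3)
        t.provenance["x2"] = "behaviour"
        res = da.best_subsets_fixed_size(t, ("x0", "x2"), 2)
        assert res[0].provenance == {"biomarker": 1, "behaviour": 1}
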