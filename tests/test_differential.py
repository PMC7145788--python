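import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_sample_meta
from immunogem import differential as diff


def frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestLog2Normalize:
    @pytest.mark.parametrize("value, offset, expected", [
        (0.0, 1.0, 0.0),
        (7.0, 1.0, 3.0),
        (1.0, 1.0, 1.0),
    ])
    def test_values(self, value, offset, expected):
        out = diff.log2_normalize(frame([[value]]), offset=offset)
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            diff.log2_normalize(frame([[-1.0]]))

    def test_monotone(self):
        x = np.sort(np.random.default_rng(0).uniform(0, 100, 50))
        out = diff.log2_normalize(frame(x[:, None])).to_numpy().ravel()
        assert (np.diff(out) >= 0).all()


class TestAgeBins:
    def _meta(self, rows):
        return pd.DataFrame(rows).set_index("sample")

    def test_nearest_bin(self):
        meta = self._meta([{"sample": "a", "subject": "s1", "age_months": 13.0}])
        bins = diff.assign_age_bins(meta)
        assert bins["a"] == 12

    def test_closest_per_subject_kept_with_tiebreak(self):
        meta = self._meta([
            {"sample": "a", "subject": "s1", "age_months": 11.0},
            {"sample": "b", "subject": "s1", "age_months": 13.0},
        ])
        bins = diff.assign_age_bins(meta)
        assert list(bins.index) == ["a"] and bins["a"] == 12

    def test_outside_window_dropped(self):
        meta = self._meta([{"sample": "a", "subject": "s1", "age_months": 45.0},
                          {"sample": "b", "subject": "s2", "age_months": 19.0}])
        bins = diff.assign_age_bins(meta, window=6)
        assert "a" not in bins.index          # 45 is beyond every window
        assert bins["b"] == 24                # 19 is within 6 of 24
        assert len(diff.assign_age_bins(meta, window=4)) == 0


class TestPCAOutliers:
    def test_identical_samples_unflagged(self):
        X = frame(np.tile([3.0, 5.0, 7.0], (30, 1)))
        assert diff.pca_outlier_check(X) == []

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (50, 20))
        X[0] += 20  # 20 pooled-sd displacement along the all-feature direction
        flagged = diff.pca_outlier_check(frame(X))
        assert "s0" in flagged

    def test_confidence_one_flags_nothing(self):
        rng = np.random.default_rng(3)
        X = frame(rng.normal(0, 1, (40, 5)))
        assert diff.pca_outlier_check(X, confidence=1.0) == []

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            diff.pca_outlier_check(frame(np.zeros((2, 4))), n_components=2)


class TestVarianceExplained:
    def _meta(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(n)],
            "group": rng.choice(["CTRL", "P1Ab", "PT1D"], n),
            "sex": rng.choice(["F", "M"], n),
            "age_months": rng.uniform(10, 40, n),
            "nominal_age": 24,
        }, index=[f"s{i}" for i in range(n)])

    def test_pure_age_feature_fully_explained(self):
        meta = self._meta(60)
        X = frame(meta["age_months"].to_numpy()[:, None])
        X.index = meta.index
        ev = diff.variance_explained(X, meta, interactions=False)
        assert ev.loc["f0", "age"] == pytest.approx(100.0, abs=1e-6)

    def test_null_features_low_ev(self):
        """Covariate-independent features explain almost nothing: the null
        per-factor EV is ~chi2_k/(2n) percent, so nearly all entries sit
        below 5% at n=200."""
        meta = self._meta(200, seed=4)
        rng = np.random.default_rng(5)
        X = frame(rng.normal(0, 1, (200, 40)))
        X.index = meta.index
        ev = diff.variance_explained(X, meta, interactions=False).to_numpy()
        assert (ev < 5.0).mean() >= 0.99
        assert ev.max() < 15.0

    def test_ev_sums_below_hundred(self):
        meta = self._meta(80, seed=6)
        rng = np.random.default_rng(7)
        X = frame(rng.normal(0, 1, (80, 15)))
        X.index = meta.index
        ev = diff.variance_explained(X, meta)
        assert (ev.sum(axis=1) <= 100 + 1e-9).all()


class TestTwoSampleContrast:
    def test_identical_groups(self):
        meta = make_sample_meta(3, 3)
        X = frame(np.tile([[1.0, 2.0]], (6, 1)))
        X.index = meta.index
        res = diff.two_sample_contrast(X, meta, "PT1D", "CTRL")
        assert (res.table["t"] == 0).all()
        assert (res.table["p"] == 1).all()
        assert res.table["degenerate"].all()

    def test_welch_hand_example(self):
        """A={1,2,3}, B={4,5,6}: log2FC=-3, Welch p ~= 0.0214 (df = 4)."""
        meta = make_sample_meta(3, 3)
        X = frame(np.array([1, 2, 3, 4, 5, 6], dtype=float)[:, None])
        X.index = meta.index
        res = diff.two_sample_contrast(X, meta, "PT1D", "CTRL")
        assert res.table["log2fc"].iloc[0] == pytest.approx(-3.0)
        assert res.table["p"].iloc[0] == pytest.approx(0.02139, abs=2e-4)

    def test_label_swap_negates_fold_change(self):
        rng = np.random.default_rng(8)
        meta = make_sample_meta(10, 10)
        X = frame(rng.normal(0, 1, (20, 30)))
        X.index = meta.index
        r1 = diff.two_sample_contrast(X, meta, "PT1D", "CTRL")
        r2 = diff.two_sample_contrast(X, meta, "CTRL", "PT1D")
        np.testing.assert_allclose(r1.table["log2fc"], -r2.table["log2fc"])
        np.testing.assert_allclose(r1.table["p"], r2.table["p"])

    def test_empty_group_raises(self):
        meta = make_sample_meta(4, 4)
        X = frame(np.zeros((8, 2)))
        X.index = meta.index
        with pytest.raises(ValueError):
            diff.two_sample_contrast(X, meta, "PT1D", "P1Ab")


class TestPairedContrast:
    def _cohort(self, n_subjects, drop, seed=0, sd=0.3):
        rng = np.random.default_rng(seed)
        rows, data = [], []
        for i in range(n_subjects):
            for age, tag in ((12, "pre"), (36, "post")):
                rows.append({"sample": f"s{i}_{tag}", "subject": f"s{i}",
                             "group": "PT1D", "sex": "F", "age_months": age,
                             "nominal_age": age, "seroconversion_age": 20.0})
                base = rng.normal(10, sd, 5)
                data.append(base + (drop if tag == "post" else 0.0))
        meta = pd.DataFrame(rows).set_index("sample")
        X = frame(np.array(data))
        X.index = meta.index
        return X, meta

    def test_no_change_gives_null(self):
        X, meta = self._cohort(10, drop=0.0)
        X.loc[[s for s in X.index if s.endswith("post")]] = \
            X.loc[[s.replace("post", "pre") for s in X.index if s.endswith("post")]].to_numpy()
        res = diff.paired_seroconversion_contrast(X, meta, "PT1D")
        assert (res.table["p"] == 1).all()

    def test_planted_drop_detected_across_seeds(self):
        """-0.8 log2 after seroconversion, 20 subjects, sd 0.3: p < 0.01
        in nearly every replicate."""
        hits, n = 0, 50
        for seed in range(n):
            X, meta = self._cohort(20, drop=-0.8, seed=seed)
            res = diff.paired_seroconversion_contrast(X, meta, "PT1D")
            hits += (res.table["p"] < 0.01).all()
        assert hits >= int(0.95 * n)

    def test_single_subject_raises(self):
        X, meta = self._cohort(1, drop=0.0)
        with pytest.raises(ValueError):
            diff.paired_seroconversion_contrast(X, meta, "PT1D")


class TestGroupTotalsAnova:
    def _three_group(self, shift, seed=0, n=15):
        rng = np.random.default_rng(seed)
        rows, data = [], []
        for g in ("CTRL", "P1Ab", "PT1D"):
            for i in range(n):
                rows.append({"sample": f"{g}{i}", "subject": f"{g}{i}",
                             "group": g, "sex": "F", "age_months": 24,
                             "nominal_age": 24, "seroconversion_age": np.nan})
                data.append(rng.normal(10, 1, 20) + (shift if g == "PT1D" else 0))
        meta = pd.DataFrame(rows).set_index("sample")
        X = frame(np.array(data))
        X.index = meta.index
        return X, meta

    def test_null_pvalues_uniform_over_seeds(self):
        ps = []
        for seed in range(60):
            X, meta = self._three_group(0.0, seed=seed)
            ps.append(diff.group_totals_anova(X, meta, 24)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_group_detected(self):
        X, meta = self._three_group(3.0, seed=1)
        _, p = diff.group_totals_anova(X, meta, 24)
        assert p < 0.001

    def test_degenerate_variance_policy(self):
        X, meta = self._three_group(0.0, seed=2, n=2)
        X.loc[:, :] = 5.0
        f, p = diff.group_totals_anova(X, meta, 24)
        assert p == 1.0 and np.isnan(f)


class TestPLSDA:
    def _one_informative(self, seed=0, n=60, p=50):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, p))
        X[:, 7] += 3 * y  # single well-separated informative feature
        return frame(X), y

    def test_informative_feature_dominates_rc(self):
        X, y = self._one_informative()
        model = diff.plsda_fit(X, y, n_components=2, keep_per_component=20)
        coefs = pd.Series(np.abs(model.coef), index=model.features)
        assert coefs.idxmax() == "f7"

    def test_informative_feature_has_high_vip(self):
        X, y = self._one_informative()
        model = diff.plsda_fit(X, y, n_components=2, keep_per_component=20)
        assert diff.vip_scores(model)["f7"] > 1

    def test_keep_all_is_ordinary_plsda(self):
        X, y = self._one_informative(seed=1)
        dense = diff.plsda_fit(X, y, keep_per_component=None)
        same = diff.plsda_fit(X, y, keep_per_component=X.shape[1])
        np.testing.assert_allclose(dense.coef, same.coef, atol=1e-12)

    def test_duplicated_columns_get_equal_weights(self):
        X, y = self._one_informative(seed=2, p=10)
        X["f9"] = X["f7"]
        model = diff.plsda_fit(X, y, keep_per_component=None)
        w = pd.DataFrame(model.weights, index=model.features)
        np.testing.assert_allclose(w.loc["f7"], w.loc["f9"], atol=1e-10)

    def test_vip_identity_on_random_fits(self):
        """Sum of squared VIPs equals the feature count on every fit."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            n, p = rng.integers(20, 60), rng.integers(5, 40)
            X = frame(rng.normal(0, 1, (int(n), int(p))))
            y = rng.integers(0, 2, int(n))
            if len(np.unique(y)) < 2:
                continue
            model = diff.plsda_fit(X, y, n_components=2,
                                   keep_per_component=min(10, int(p)))
            vip = diff.vip_scores(model)
            assert (vip ** 2).sum() == pytest.approx(int(p), abs=1e-8)

    def test_single_component_equal_weights_unit_vip(self):
        X = frame(np.array([[1., 1.], [2., 2.], [3., 3.], [4., 4.]]))
        y = np.array([0, 0, 1, 1])
        model = diff.plsda_fit(X, y, n_components=1, keep_per_component=None)
        np.testing.assert_allclose(diff.vip_scores(model), 1.0, atol=1e-10)

    def test_too_many_components_rejected(self):
        X, y = self._one_informative(n=6, p=10)
        with pytest.raises(ValueError):
            diff.plsda_fit(X, y, n_components=10)


class TestCVAUC:
    def test_perfect_separation(self):
        X, y = np.zeros((40, 3)), np.repeat([0, 1], 20)
        X[y == 1] += 10
        auc = diff.cv_auc(frame(X), y, repeats=2, seed=0)
        assert auc == pytest.approx(1.0)

    def test_label_inversion_symmetry(self):
        """Evaluating a fixed discriminant against inverted labels gives the
        complementary AUC; retraining with renamed labels gives the same
        cross-validated AUC (fold assignment is label-name invariant)."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        X = frame(rng.normal(0, 1, (40, 10)))
        y = np.repeat([0, 1], 20)
        model = diff.plsda_fit(X, y, keep_per_component=None)
        pred = diff.plsda_predict(model, X)
        assert (roc_auc_score(y, pred) + roc_auc_score(1 - y, pred)
                == pytest.approx(1.0, abs=1e-12))
        a1 = diff.cv_auc(X, y, repeats=3, seed=1)
        a2 = diff.cv_auc(X, 1 - y, repeats=3, seed=1)
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = frame(rng.normal(0, 1, (200, 30)))
        y = rng.integers(0, 2, 200)
        auc = diff.cv_auc(X, y, repeats=10, seed=2)
        assert 0.4 <= auc <= 0.6

    def test_tiny_class_reduces_folds(self):
        rng = np.random.default_rng(6)
        X = frame(rng.normal(0, 1, (23, 5)))
        y = np.array([1] * 3 + [0] * 20)
        auc = diff.cv_auc(X, y, folds=5, repeats=2, seed=3)
        assert 0 <= auc <= 1


class TestSelection:
    def _contrast(self, vip, rc, auc, p):
        table = pd.DataFrame({"log2fc": [1.0], "t": [2.0], "p": [p],
                              "q": [p], "vip": [vip], "rc": [rc]},
                             index=["f0"])
        return diff.ContrastResult(name="x_vs_y", table=table, auc=auc)

    @pytest.mark.parametrize("vip, rc, auc, p, basis", [
        (1.2, 0.06, 0.70, 0.01, "multi+uni"),
        (0.5, 0.06, 0.70, 0.03, "uni-only"),
        (1.2, 0.06, 0.70, 0.20, ""),
        (1.2, 0.04, 0.70, 0.01, "uni-only"),  # fails the RC gate
        (1.2, 0.06, 0.60, 0.01, "uni-only"),  # fails the AUC gate
    ])
    def test_selection_rule(self, vip, rc, auc, p, basis):
        res = diff.select_altered_features(self._contrast(vip, rc, auc, p))
        assert res.table["basis"].iloc[0] == basis


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(1.0, 11.0)
        A = frame(x[:, None], "a")
        B = frame(np.column_stack([2 * x + 1, -(x ** 3)]), "b")
        rho, p, mask = diff.spearman_map(A, B)
        assert rho.loc["a0", "b0"] == pytest.approx(1.0)
        assert rho.loc["a0", "b1"] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        A = frame(np.array([1., 2., 3., 4., 5.])[:, None], "a")
        B = frame(np.array([1., 3., 2., 5., 4.])[:, None], "b")
        rho, _, _ = diff.spearman_map(A, B)
        assert rho.iloc[0, 0] == pytest.approx(0.8)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        r1, _, _ = diff.spearman_map(frame(x[:, None], "a"), frame(y[:, None], "b"))
        r2, _, _ = diff.spearman_map(frame(np.exp(x)[:, None], "a"),
                                     frame((y ** 3)[:, None], "b"))
        assert r1.iloc[0, 0] == pytest.approx(r2.iloc[0, 0], abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            diff.spearman_map(frame(np.zeros((3, 1))), frame(np.zeros((3, 1))))


class TestBHFDR:
    def test_single_p(self):
        assert diff.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        np.testing.assert_allclose(diff.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_fdr([0.5, 1.5])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_statsmodels_exactly(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(1, 60)))
        q_ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_array_equal(diff.bh_fdr(p), q_ref)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 200)
        q = diff.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
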