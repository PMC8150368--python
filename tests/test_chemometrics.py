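"""Scaling, PCA, Kennard-Stone, OPLS-DA/VIP, validation and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cross_decomposition import PLSRegression

from oenomics import chemometrics as cm


def frame(array, prefix="v"):
    array = np.asarray(array, dtype=float)
    return pd.DataFrame(
        array,
        index=[f"s{i}" for i in range(array.shape[0])],
        columns=[f"{prefix}{j}" for j in range(array.shape[1])],
    )


def feature_matrix(values, classes=None):
    values = frame(values)
    if classes is None:
        classes = pd.Series(["A"] * len(values), index=values.index)
    else:
        classes = pd.Series(list(classes), index=values.index)
    return cm.FeatureMatrix(values, classes)


class TestNormalizeToIs:
    def test_division(self):
        fm = cm.normalize_to_is(frame([[5000.0]]), pd.Series([2500.0], index=["s0"]))
        assert fm.values.iloc[0, 0] == pytest.approx(2.0)

    def test_sample_scale_invariance(self):
        raw = frame([[100.0, 40.0], [200.0, 80.0]])
        is_areas = pd.Series([10.0, 20.0], index=raw.index)
        fm = cm.normalize_to_is(raw, is_areas)
        assert np.allclose(fm.values.iloc[0], fm.values.iloc[1])

    def test_missing_is_excludes_sample(self):
        raw = frame([[1.0], [2.0], [3.0]])
        is_areas = pd.Series([1.0, np.nan, 0.0], index=raw.index)
        with pytest.warns(UserWarning, match="IS"):
            fm = cm.normalize_to_is(raw, is_areas)
        assert fm.sample_ids == ["s0"]


class TestScaling:
    def test_pareto_simple_column(self):
        fm = feature_matrix([[1.0], [2.0], [3.0]])
        scaled = cm.scale_matrix(fm, "pareto")
        assert np.allclose(scaled.values.iloc[:, 0], [-1.0, 0.0, 1.0])

    def test_pareto_variance_identity(self):
        """var(pareto-scaled column) equals the original column's sd."""
        rng = np.random.default_rng(3)
        fm = feature_matrix(rng.lognormal(1.0, 0.8, size=(30, 5)))
        scaled = cm.scale_matrix(fm, "pareto")
        assert np.allclose(
            scaled.values.var(ddof=1), fm.values.std(ddof=1), rtol=1e-12
        )

    def test_auto_and_range_closed_forms(self):
        rng = np.random.default_rng(4)
        fm = feature_matrix(rng.normal(5.0, 2.0, size=(20, 4)))
        auto = cm.scale_matrix(fm, "auto").values
        assert np.allclose(auto.mean(), 0.0, atol=1e-12)
        assert np.allclose(auto.std(ddof=1), 1.0, rtol=1e-12)
        ranged = cm.scale_matrix(fm, "range").values
        assert np.allclose(ranged.min(), 0.0) and np.allclose(ranged.max(), 1.0)

    def test_zero_variance_column_dropped(self):
        fm = feature_matrix([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled = cm.scale_matrix(fm, "auto")
        assert scaled.variable_ids == ["v0"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            cm.ColumnScaler("log")

    def test_scaler_applies_training_parameters(self):
        train = frame([[0.0], [2.0], [4.0]])
        scaler = cm.ColumnScaler("auto").fit(train)
        out = scaler.transform(frame([[6.0]]))
        assert out.iloc[0, 0] == pytest.approx((6.0 - 2.0) / 2.0)


class TestPca:
    def test_two_points_single_component(self):
        fm = feature_matrix([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="rank"):
            scores, loadings, explained = cm.run_pca(fm, n_components=2)
        assert explained.shape == (1,)
        assert explained[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        """Oracle: eigendecomposition of the sample covariance matrix."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = rng.normal(size=(10, 6))
            fm = feature_matrix(x)
            scores, loadings, explained = cm.run_pca(fm, n_components=4)
            cov = np.cov(x, rowvar=False)
            eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
            ratio = eigvals / eigvals.sum()
            assert np.allclose(explained, ratio[:4], atol=1e-8)
            # loadings orthonormal
            assert np.allclose(loadings.T @ loadings, np.eye(4), atol=1e-8)

    def test_explained_fractions_monotone(self):
        rng = np.random.default_rng(9)
        fm = feature_matrix(rng.normal(size=(15, 6)))
        _, _, explained = cm.run_pca(fm, n_components=5)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1.0 + 1e-9


class TestKennardStone:
    def test_46_samples_gives_37_9(self):
        rng = np.random.default_rng(10)
        fm = frame(rng.normal(size=(46, 12)))
        train, test = cm.kennard_stone_split(fm, 0.8)
        assert (len(train), len(test)) == (37, 9)

    def test_first_pair_is_maximally_distant(self):
        pts = frame([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        train, _ = cm.kennard_stone_split(pts, 0.5)
        # brute force: the diagonal pairs are the farthest
        assert set(train) in ({"s0", "s1"}, {"s2", "s3"})

    def test_two_samples(self):
        train, test = cm.kennard_stone_split(frame([[0.0], [1.0]]), 0.5)
        assert len(train) == 1 and len(test) == 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        fm = frame(rng.normal(size=(20, 5)))
        train1, _ = cm.kennard_stone_split(fm, 0.7)
        shuffled = fm.sample(frac=1.0, random_state=1)
        train2, _ = cm.kennard_stone_split(shuffled, 0.7)
        assert set(train1) == set(train2)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            cm.kennard_stone_split(frame([[0.0], [1.0]]), 1.2)


def two_class_y(n_a, n_b):
    return ["A"] * n_a + ["B"] * n_b


class TestOplsda:
    def random_problem(self, seed=0, n=20, p=8):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, p)), two_class_y(n // 2, n - n // 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("shape", [(20, 8), (30, 15), (12, 5)])
    def test_zero_orthogonal_equals_pls1_oracle(self, seed, shape):
        """With no OSC components the predictive component is exactly PLS1."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=shape)
        y = two_class_y(shape[0] // 2, shape[0] - shape[0] // 2)
        model = cm.fit_oplsda(x, y, 0)
        y_enc = np.array([0.0] * (shape[0] // 2) + [1.0] * (shape[0] - shape[0] // 2))
        pls = PLSRegression(n_components=1, scale=False).fit(x, y_enc)
        t_oracle = pls.x_scores_[:, 0]
        sign = np.sign(t_oracle @ model.t)
        assert np.max(np.abs(model.t - sign * t_oracle)) < 1e-8
        assert np.max(np.abs(model.p - sign * pls.x_loadings_[:, 0])) < 1e-8

    def test_orthogonal_scores_uncorrelated_with_response(self):
        x, y = self.random_problem(3, 24, 10)
        model = cm.fit_oplsda(x, y, 3)
        y_enc = np.array([0.0] * 12 + [1.0] * 12)
        yc = y_enc - y_enc.mean()
        for k in range(model.n_orthogonal):
            corr = np.corrcoef(model.t_ortho[:, k], yc)[0, 1]
            assert abs(corr) < 1e-10

    def test_single_class_rejected(self):
        x, _ = self.random_problem()
        with pytest.raises(ValueError, match="two classes"):
            cm.fit_oplsda(x, ["A"] * 20)

    def test_excessive_orthogonal_components_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 4))
        with pytest.raises(ValueError):
            cm.fit_oplsda(x, two_class_y(3, 3), 10)

    def test_r2y_bounds_and_rmsee(self):
        x, y = self.random_problem(6)
        model = cm.fit_oplsda(x, y, 1)
        assert 0.0 <= model.r2y <= 1.0
        assert model.rmsee >= 0.0

    def test_separable_training_rmsee_small(self):
        """Class-shifted data on the study's effect scale: RMSEE < 0.25."""
        rng = np.random.default_rng(21)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = np.vstack(
                [rng.normal(0.0, 1.0, (14, 9)), rng.normal(2.0, 1.0, (12, 9))]
            )
            model = cm.fit_oplsda(x, two_class_y(14, 12), 1)
            assert model.rmsee < 0.25


class TestVip:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(13)
        for seed in range(4):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(18, 7))
            model = cm.fit_oplsda(x, two_class_y(9, 9), 1)
            assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_vip_proportional_to_weights(self):
        """Single predictive component: VIP/|w| is constant across variables.

        This is the structure behind a constant VIP/|p1| ratio in a marker
        table built from one predictive component.
        """
        rng = np.random.default_rng(14)
        x = rng.normal(size=(22, 9))
        model = cm.fit_oplsda(x, two_class_y(11, 11), 1)
        ratio = model.vip.to_numpy() / np.abs(model.w)
        assert np.ptp(ratio) / ratio.mean() < 1e-9

    def test_equal_weights_give_unit_vip(self):
        # two variables carrying identical class information
        base = np.array([0.0] * 8 + [1.0] * 8)
        rng = np.random.default_rng(15)
        x = np.column_stack([base, base]) + rng.normal(0, 1e-9, size=(16, 2))
        model = cm.fit_oplsda(x, two_class_y(8, 8), 0)
        assert np.allclose(model.vip, 1.0, atol=1e-3)


class TestValidation:
    def separable(self, seed=0, n_a=14, n_b=14, p=8, delta=3.0):
        rng = np.random.default_rng(seed)
        x = np.vstack(
            [rng.normal(0.0, 1.0, (n_a, p)), rng.normal(delta, 1.0, (n_b, p))]
        )
        return x, two_class_y(n_a, n_b)

    def test_q2_high_on_separable_data(self):
        x, y = self.separable()
        assert cm.cross_validate_q2(x, y, 1) > 0.5

    def test_q2_fold_determinism(self):
        x, y = self.separable(3)
        assert cm.cross_validate_q2(x, y, 1, seed=5) == cm.cross_validate_q2(
            x, y, 1, seed=5
        )

    def test_permutation_separable_all_below_actual(self):
        x, y = self.separable(7)
        result = cm.permutation_test(x, y, 1, n_perm=20, seed=2)
        actual_q2 = result["actual"][1]
        assert all(q2 < actual_q2 for _, q2 in result["permuted"])

    def test_permutation_null_on_noise(self):
        """Pure-noise X: the actual Q2 sits inside the permuted distribution."""
        rng = np.random.default_rng(16)
        x = rng.normal(size=(28, 10))
        y = two_class_y(14, 14)
        result = cm.permutation_test(x, y, 0, n_perm=20, seed=3)
        permuted_q2 = [q for _, q in result["permuted"]]
        assert min(permuted_q2) <= result["actual"][1] <= max(permuted_q2) + 0.2

    def test_permutation_determinism(self):
        x, y = self.separable(9)
        r1 = cm.permutation_test(x, y, 1, n_perm=5, seed=4)
        r2 = cm.permutation_test(x, y, 1, n_perm=5, seed=4)
        assert r1 == r2

    def test_permutation_argument_validation(self):
        x, y = self.separable()
        with pytest.raises(ValueError):
            cm.permutation_test(x, y, 1, n_perm=0)

    def test_select_n_orthogonal_prefers_simplicity(self):
        x, y = self.separable(11)
        n = cm.select_n_orthogonal(x, y, max_orthogonal=3)
        assert 0 <= n <= 3

    def test_maxdist_rule(self):
        x, y = self.separable(12)
        model = cm.fit_oplsda(x, y, 0)
        labels, rmsep, acc = cm.predict_class_maxdist(model, x, y)
        assert acc == 1.0
        assert rmsep == pytest.approx(model.rmsee, abs=1e-12)
        # threshold behavior on synthetic scores
        decode = {v: k for k, v in model.class_encoding.items()}
        assert labels[0] == decode[0.0] and labels[-1] == decode[1.0]

    def test_maxdist_column_mismatch(self):
        x, y = self.separable(13)
        model = cm.fit_oplsda(x, y, 0)
        with pytest.raises(ValueError, match="mismatch"):
            model.predict_scores(x[:, :5])


class TestRocAuc:
    def test_perfect_ordering(self):
        assert cm.roc_auc([0.1, 0.2, 0.8, 0.9], ["A", "A", "B", "B"]) == 1.0

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equals_pair_counting_oracle(self, seed):
        """Brute force over all (negative, positive) score pairs."""
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 8, size=2)
        scores = np.round(rng.normal(size=n_a + n_b), 2)  # ties likely
        labels = two_class_y(n_a, n_b)
        neg, pos = scores[:n_a], scores[n_a:]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert cm.roc_auc(scores, labels) == pytest.approx(wins / (n_a * n_b))

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            cm.roc_auc([0.1, 0.2], ["A", "A"])


class TestMarkerSelection:
    def test_planted_markers_recovered_with_signs(self):
        rng = np.random.default_rng(17)
        n_a, n_b, p = 14, 12, 12
        x = rng.normal(0.0, 1.0, (n_a + n_b, p))
        x[n_a:, 0] += 3.0  # higher in class B
        x[n_a:, 1] -= 3.0  # higher in class A
        model = cm.fit_oplsda(x, two_class_y(n_a, n_b), 0)
        markers = cm.select_markers(model)
        assert {"v0", "v1"} <= set(markers.index)
        assert markers.loc["v0", "class"] == "B"
        assert markers.loc["v1", "class"] == "A"
        assert markers.vip.is_monotonic_decreasing

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(20, 8))
        model = cm.fit_oplsda(x, two_class_y(10, 10), 0)
        low = set(cm.select_markers(model, 1.0).index)
        high = set(cm.select_markers(model, 2.0).index)
        assert high <= low

    def test_vplot_covers_all_variables(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(16, 6))
        model = cm.fit_oplsda(x, two_class_y(8, 8), 1)
        table = cm.vplot_table(model)
        assert list(table.columns) == ["p1", "vip", "pcorr1"]
        assert len(table) == 6
        assert table.pcorr1.abs().max() <= 1.0 + 1e-12


class TestVariableFilters:
    def test_iqr_drops_half(self):
        rng = np.random.default_rng(20)
        fm = feature_matrix(rng.normal(0, np.arange(1, 101), size=(30, 100)))
        out = cm.iqr_variable_filter(fm, 0.50)
        assert len(out.variable_ids) == 50

    def test_constant_variable_dropped_first(self):
        rng = np.random.default_rng(21)
        values = rng.normal(size=(20, 4))
        values[:, 2] = 5.0
        out = cm.iqr_variable_filter(feature_matrix(values), 0.25)
        assert "v2" not in out.variable_ids

    def test_drop_confounded_exact_arithmetic(self):
        fm = feature_matrix(np.arange(3 * 108.0).reshape(3, 108))
        removal = [f"v{j}" for j in range(17)]
        out = cm.drop_confounded_variables(fm, removal)
        assert len(out.variable_ids) == 91

    def test_drop_confounded_unknown_name_warns(self):
        fm = feature_matrix(np.arange(6.0).reshape(3, 2))
        with pytest.warns(UserWarning, match="not in matrix"):
            out = cm.drop_confounded_variables(fm, ["v0", "nope"])
        assert out.variable_ids == ["v1"]
        assert cm.drop_confounded_variables(fm, []).variable_ids == ["v0", "v1"]


class TestUnivariateScreen:
    def build(self, xa, xb):
        values = np.vstack([xa, xb])
        return feature_matrix(values, classes=["A"] * len(xa) + ["B"] * len(xb))

    def test_identical_distributions_not_significant(self):
        block = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 1))
        fm = self.build(block, block)
        out = cm.univariate_screen(fm)
        assert out.p.iloc[0] == pytest.approx(1.0, abs=0.05)
        assert not out.significant.iloc[0]

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(22)
        xa = rng.normal(0, 1, size=(10, 10))
        xb = rng.normal(0, 1, size=(10, 10))
        fm = self.build(xa, xb)
        out = cm.univariate_screen(fm)
        tested = out[out.test != "untestable"]
        assert np.allclose(
            tested.p_adj, np.minimum(1.0, tested.p * len(tested)), atol=1e-12
        )

    def test_strong_effect_significant(self):
        """A catechin-scale separation (27 vs 65, cv 0.25) is detected."""
        rng = np.random.default_rng(23)
        xa = rng.lognormal(np.log(27), 0.25, size=(27, 1))
        xb = rng.lognormal(np.log(65), 0.25, size=(19, 1))
        noise = np.column_stack([rng.normal(size=46) for _ in range(9)])
        values = np.column_stack([np.vstack([xa, xb]), noise])
        fm = feature_matrix(values, classes=["A"] * 27 + ["B"] * 19)
        out = cm.univariate_screen(fm)
        assert out.significant.iloc[0]
        assert out.test.iloc[0] in ("wilcoxon", "t")

    def test_constant_variable_untestable(self):
        values = np.ones((12, 2))
        values[:, 1] = np.arange(12.0)
        fm = feature_matrix(values, classes=["A"] * 6 + ["B"] * 6)
        out = cm.univariate_screen(fm)
        assert out.test.iloc[0] == "untestable"
        assert not out.significant.iloc[0]


class TestScalingRanking:
    def test_ranking_contract(self):
        rng = np.random.default_rng(24)
        x = np.vstack(
            [
                rng.lognormal(2.0, 0.4, size=(14, 10)),
                rng.lognormal(2.6, 0.4, size=(12, 10)),
            ]
        )
        fm = feature_matrix(x, classes=["A"] * 14 + ["B"] * 12)
        ranking = cm.rank_scaling_methods(fm, seed=0)
        scores = dict(ranking)
        assert set(scores) == set(cm.SCALING_METHODS)
        assert all(0.0 <= s <= 1.0 for s in scores.values())
        assert [s for _, s in ranking] == sorted(scores.values(), reverse=True)
        # determinism
        assert cm.rank_scaling_methods(fm, seed=0) == ranking

    def test_needs_two_methods(self):
        fm = feature_matrix(np.random.default_rng(0).normal(size=(10, 3)),
                            classes=["A"] * 5 + ["B"] * 5)
        with pytest.raises(ValueError):
            cm.rank_scaling_methods(fm, methods=("pareto",))
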