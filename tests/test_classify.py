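import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import mannwhitneyu

from afmpore import (
    accuracy_at_cutoff,
    auc,
    auc_category,
    fit_logistic,
    holdout_split,
    roc_curve,
    youden,
)


def brute_force_logistic(x, y, span=10.0, rounds=7, grid=41):
    """Nested grid search of the Bernoulli log-likelihood (oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def ll(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    c0, c1, s = 0.0, 0.0, span
    for _ in range(rounds):
        b0s = np.linspace(c0 - s, c0 + s, grid)
        b1s = np.linspace(c1 - s, c1 + s, grid)
        vals = np.array([[ll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        c0, c1 = b0s[i], b1s[j]
        s = s / 4.0  # window shrinks slower than grid resolution, so optimum stays inside
    return c0, c1


class TestLogisticFit:
    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 30, 500)
        y = (rng.random(500) < expit(-4.0 + 0.6 * x)).astype(float)
        ours = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert ours.beta0 == pytest.approx(ref.params[0], abs=1e-6)
        assert ours.beta1 == pytest.approx(ref.params[1], abs=1e-6)
        assert ours.converged and ours.grad_norm < 1e-8

    def test_matches_grid_search_on_toy_set(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        b0, b1 = brute_force_logistic(x, y)
        ours = fit_logistic(x, y)
        assert ours.beta0 == pytest.approx(b0, abs=1e-3)
        assert ours.beta1 == pytest.approx(b1, abs=1e-3)

    def test_null_slope_when_labels_permuted(self, rng):
        x = rng.uniform(0, 30, 2000)
        y = rng.permutation(np.repeat([0.0, 1.0], 1000))
        model = fit_logistic(x, y)
        # Fisher information SE of beta1 under the null
        p = model.predict_proba(x)
        w = p * (1 - p)
        X = np.column_stack([np.ones_like(x), x])
        cov = np.linalg.inv((X * w[:, None]).T @ X)
        assert abs(model.beta1) < 3 * np.sqrt(cov[1, 1])

    def test_complete_separation_flagged_and_capped(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        model = fit_logistic(x, y)
        assert model.separated
        assert max(abs(model.beta0), abs(model.beta1)) <= 50.0
        assert model.beta1 > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1.0, 2.0], [1.0, 1.0])


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        roc = roc_curve(np.ones(10), np.repeat([0, 1], 5))
        assert roc.auc == pytest.approx(0.5)

    def test_reversed_scores_give_zero(self):
        roc = roc_curve([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(0.0)

    def test_auc_equals_mann_whitney_with_ties(self, rng):
        for _ in range(50):
            s = np.round(rng.normal(size=40), 1)  # induce ties
            y = np.repeat([0.0, 1.0], 20)
            u = mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
            assert roc_curve(s, y).auc == pytest.approx(u / 400.0, abs=1e-12)

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.normal(size=60)
        y = (rng.random(60) < expit(s)).astype(float)
        if len(np.unique(y)) == 2:
            assert roc_curve(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self, rng):
        s = rng.normal(size=30)
        y = np.repeat([0.0, 1.0], 15)
        assert roc_curve(s, 1 - y).auc == pytest.approx(1 - roc_curve(s, y).auc, abs=1e-12)

    def test_invariant_under_monotone_link(self, rng):
        x = rng.normal(size=40)
        y = np.repeat([0.0, 1.0], 20)
        raw = roc_curve(x, y)
        linked = roc_curve(expit(-4.0 + 0.6 * x), y)
        assert linked.auc == pytest.approx(raw.auc, abs=1e-12)
        np.testing.assert_allclose(
            np.sort(linked.sensitivity), np.sort(raw.sensitivity), atol=1e-12
        )

    def test_curve_monotone_with_endpoints(self, rng):
        s = rng.normal(size=25)
        y = np.repeat([0.0, 1.0], [12, 13])
        roc = roc_curve(s, y)
        fpr = 1 - roc.specificity
        order = np.argsort(roc.cutoffs)[::-1]  # descending cutoff: (0,0) -> (1,1)
        assert np.all(np.diff(fpr[order]) >= -1e-12)
        assert np.all(np.diff(roc.sensitivity[order]) >= -1e-12)
        pts = set(zip(fpr, roc.sensitivity))
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_auc_helper_consistent_with_curve(self, rng):
        s = rng.normal(size=30)
        y = np.repeat([0.0, 1.0], 15)
        roc = roc_curve(s, y)
        assert auc(roc) == pytest.approx(roc.auc, abs=1e-12)


class TestYouden:
    def test_perfect_classifier_scores_half(self):
        roc = roc_curve([1, 2, 10, 11], [0, 0, 1, 1])
        yi, _ = youden(roc)
        assert yi == pytest.approx(0.5)

    def test_no_skill_scores_zero(self):
        roc = roc_curve(np.ones(8), np.repeat([0, 1], 4))
        yi, _ = youden(roc)
        assert yi == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration_on_toy(self):
        s = np.array([0.1, 0.3, 0.35, 0.4, 0.5, 0.65, 0.7, 0.9])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1], float)
        roc = roc_curve(s, y)
        best = -1.0
        for c in np.concatenate([[-np.inf], np.sort(s) - 1e-9, [np.inf]]):
            pred = s >= c
            se = np.sum(pred & (y == 1)) / 4
            sp = np.sum(~pred & (y == 0)) / 4
            best = max(best, (se + sp - 1) / 2)
        yi, _ = youden(roc)
        assert yi == pytest.approx(best, abs=1e-12)

    def test_halved_index_bounded(self, rng):
        for _ in range(50):
            s = rng.normal(size=20)
            y = np.repeat([0.0, 1.0], 10)
            yi, _ = youden(roc_curve(s, y))
            assert 0.0 <= yi <= 0.5

    def test_standard_convention_doubles(self, rng):
        s = rng.normal(size=20)
        y = np.repeat([0.0, 1.0], 10)
        roc = roc_curve(s, y)
        halved, c1 = youden(roc, halved=True)
        full, c2 = youden(roc, halved=False)
        assert full == pytest.approx(2 * halved) and c1 == c2


class TestAccuracy:
    def test_direct_count_example(self):
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.3, 0.6, 0.1])
        y = np.array([1, 1, 1, 1, 0, 0, 0], float)
        m = accuracy_at_cutoff(s, y, 0.5)
        assert (m.tp, m.tn, m.fp, m.fn) == (3, 2, 1, 1)
        assert m.accuracy == pytest.approx(5 / 7)

    def test_all_correct(self):
        m = accuracy_at_cutoff([0.9, 0.1], [1, 0], 0.5)
        assert m.accuracy == 1.0

    def test_minus_inf_cutoff_gives_prevalence(self, rng):
        s = rng.normal(size=20)
        y = np.repeat([0.0, 1.0], [12, 8])
        m = accuracy_at_cutoff(s, y, -np.inf)
        assert m.accuracy == pytest.approx(8 / 20)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_at_cutoff([], [], 0.5)


class TestAUCCategory:
    @pytest.mark.parametrize(
        "value, label",
        [(0.852, "high"), (0.762, "medium"), (0.579, "low"), (0.8, "high"), (0.7, "medium")],
    )
    def test_categorical_scale(self, value, label):
        assert auc_category(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_category(1.2)


class TestHoldoutSplit:
    def test_stratified_counts_at_published_design(self):
        y = np.repeat([0.0, 1.0], 60)
        train, evaluate = holdout_split(y, 0.8, rng=0)
        assert len(evaluate) == 96 and len(train) == 24
        assert np.sum(y[evaluate]) == 48 and np.sum(y[train]) == 12

    def test_partitions_disjoint_and_exhaustive(self):
        y = np.repeat([0.0, 1.0], [30, 45])
        train, evaluate = holdout_split(y, 0.6, rng=3)
        assert len(set(train) & set(evaluate)) == 0
        assert len(train) + len(evaluate) == 75

    def test_reproducible_under_fixed_seed(self):
        y = np.repeat([0.0, 1.0], 60)
        a = holdout_split(y, 0.8, rng=42)
        b = holdout_split(y, 0.8, rng=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_round_half_to_even_on_tiny_classes(self):
        y = np.repeat([0.0, 1.0], 3)
        train, evaluate = holdout_split(y, 0.5, rng=0)
        # round(1.5) = 2 per class under round-half-to-even
        assert np.sum(y[evaluate] == 0) == 2 and np.sum(y[evaluate] == 1) == 2

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(np.repeat([0.0, 1.0], 3), 0.9, rng=0)
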