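"""Metrics against brute-force oracles; CV protocol hygiene."""

import numpy as np
import pandas as pd
import pytest

from readmit.cohort import split_cohort
from readmit.evaluate import (
    ModelSpec,
    auc,
    compare_models,
    cross_validate,
    default_grid,
    make_model,
    nri,
    sensitivity_at_specificity,
)


def auc_brute(scores, labels):
    """Pair-counting oracle: P(random positive outscores random negative)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        assert auc([0.2, 0.3, 0.6, 0.8], [0, 1, 0, 1]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        """Rank-based AUC equals exhaustive pair counting (>=200 instances)."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = rng.integers(4, 51)
            y = np.zeros(n, dtype=int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert auc(scores, y) == pytest.approx(auc_brute(scores, y)), trial


class TestSensitivityAtSpecificity:
    def test_perfect_separator(self):
        assert sensitivity_at_specificity([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.9) == 1.0

    def test_accept_all_at_zero_target(self):
        assert sensitivity_at_specificity([0.4, 0.5, 0.6], [0, 1, 1], 0.0) == 1.0

    def test_two_point_distribution_hand_enumeration(self):
        # scores: negatives at 0.2 (4 of them), positives at 0.6 (2) except one
        # positive at 0.2 -> threshold at 0.6 gives spec 1.0, sens 2/3
        scores = [0.2, 0.2, 0.2, 0.2, 0.6, 0.6, 0.2]
        labels = [0, 0, 0, 0, 1, 1, 1]
        assert sensitivity_at_specificity(scores, labels, 0.75) == pytest.approx(2 / 3)
        # lowering the bar to spec >= 0 admits the all-positive threshold
        assert sensitivity_at_specificity(scores, labels, 0.0) == 1.0


class TestNri:
    def test_identical_scores_zero(self):
        r = nri([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], [0, 1, 1], n_bootstrap=50)
        assert r.overall == r.events == 0.0
        assert r.nonevents == 0.0

    def test_analytic_maximum(self):
        old = [0.5, 0.5, 0.5, 0.5]
        new = [0.9, 0.9, 0.1, 0.1]  # events up, non-events down
        r = nri(old, new, [1, 1, 0, 0], n_bootstrap=50)
        assert (r.overall, r.events, r.nonevents) == (2.0, 1.0, 1.0)

    def test_six_patient_sign_counting(self):
        old = [0.1, 0.4, 0.5, 0.3, 0.2, 0.9]
        new = [0.3, 0.2, 0.5, 0.5, 0.1, 0.8]
        y = [1, 1, 1, 0, 0, 0]
        # events: up, down, tie -> (1-1)/3 = 0
        # non-events: up, down, down -> (2-1)/3 = 1/3
        r = nri(old, new, y, n_bootstrap=50)
        assert r.events == pytest.approx(0.0)
        assert r.nonevents == pytest.approx(1 / 3)
        assert r.overall == pytest.approx(1 / 3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        old, new = rng.random(40), rng.random(40)
        y = (rng.random(40) < 0.3).astype(int)
        a = nri(old, new, y, n_bootstrap=20)
        b = nri(new, old, y, n_bootstrap=20)
        assert a.overall == pytest.approx(-b.overall)

    def test_overall_is_sum_of_components_and_ci_ordering(self):
        rng = np.random.default_rng(5)
        old, new = rng.random(200), rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        r = nri(old, new, y, n_bootstrap=300, seed=1)
        assert r.overall == pytest.approx(r.events + r.nonevents)
        assert r.ci_overall[0] <= r.overall <= r.ci_overall[1]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nri([0.1], [0.1, 0.2], [0, 1])


class TestCompareModels:
    def test_self_comparison_p_one(self):
        assert compare_models({"a": [0.5] * 10, "b": [0.5] * 10})[("a", "b")] == 1.0

    def test_constant_offset_significant(self):
        a = list(np.linspace(0.6, 0.7, 10))
        b = [x + 0.01 for x in a]
        assert compare_models({"a": a, "b": b})[("a", "b")] < 0.001

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(6)
        folds = {k: list(rng.normal(0.7, 0.01, 10)) for k in "abc"}
        from scipy import stats

        adj = compare_models(folds)
        for (x, y), p in adj.items():
            raw = stats.ttest_rel(folds[x], folds[y]).pvalue
            assert p == pytest.approx(min(1.0, 3 * raw))

    def test_misaligned_folds_rejected(self):
        with pytest.raises(ValueError):
            compare_models({"a": [0.5] * 10, "b": [0.5] * 9})


class TestCrossValidation:
    def _data(self, n=600, signal=True, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 5))
        logits = 1.5 * x[:, 0] - 2.6 if signal else np.full(n, -2.6)
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        cohort = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)]})
        parts = split_cohort(cohort, seed=1)
        return x, y, parts

    def test_deterministic(self):
        x, y, parts = self._data()
        spec = ModelSpec("lr", "logistic", ("manual",))
        assert cross_validate(x, y, parts, spec) == cross_validate(x, y, parts, spec)

    def test_planted_signal_detected(self):
        x, y, parts = self._data(signal=True)
        spec = ModelSpec("lr", "logistic", ("manual",))
        assert np.mean(cross_validate(x, y, parts, spec)) > 0.6

    def test_single_class_fold_rejected(self):
        x, y, parts = self._data()
        y[:] = 0
        y[0] = 1
        with pytest.raises(ValueError):
            cross_validate(x, y, parts, ModelSpec("lr", "logistic", ("manual",)))

    def test_holdout_never_seen_in_training(self):
        """Flipping every holdout label must not change any holdout score."""
        from readmit.evaluate import run_matrix
        from readmit.features import FeatureEncoder

        x, y, parts = self._data()
        feats = pd.DataFrame(x, columns=[f"f{i}" for i in range(5)])
        meta = {c: {"group": "manual"} for c in feats.columns}
        enc = FeatureEncoder().fit(feats, meta)
        specs = [ModelSpec("lr_manual", "logistic", ("manual",))]
        r1 = run_matrix(x, enc, y, parts, specs, nri_pairs=())
        y2 = y.copy()
        y2[parts == 0] = 1 - y2[parts == 0]
        r2 = run_matrix(x, enc, y2, parts, specs, nri_pairs=())
        np.testing.assert_array_equal(
            r1.holdout_scores["lr_manual"], r2.holdout_scores["lr_manual"]
        )
        assert r1.reports[0].fold_aucs == r2.reports[0].fold_aucs


class TestModelSpecs:
    def test_default_grid_shape(self):
        grid = default_grid()
        assert len(grid) == 8
        assert sum(s.family == "logistic" for s in grid) == 4
        assert sum(s.family == "gradient_boosting" for s in grid) == 4
        tuned = [s for s in grid if s.params][0]
        assert dict(tuned.params) == {
            "learning_rate": 0.01, "max_depth": 8, "n_estimators": 1000
        }

    def test_unknown_family_or_group_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("x", "forest", ("manual",))
        with pytest.raises(ValueError):
            ModelSpec("x", "logistic", ("nonsense",))
        with pytest.raises(ValueError):
            ModelSpec("x", "logistic", ())

    def test_exact_implementation_selectable(self):
        from sklearn.ensemble import GradientBoostingClassifier

        spec = ModelSpec("g", "gradient_boosting", ("manual",),
                         params=(("implementation", "exact"), ("n_estimators", 5)))
        assert isinstance(make_model(spec), GradientBoostingClassifier)
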