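"""ROC metrics, DeLong comparisons, association testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltarad.evaluation import (
    auroc,
    auroc_ci,
    compare_rocs,
    evaluate_scores,
    feature_association,
    operating_metrics,
)


def auc_pair_counting(scores, y):
    """Exhaustive concordant-pair oracle (ties count one half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        auc, lo, hi = auroc_ci(s, y)
        assert auc == 1.0
        assert lo <= auc <= hi <= 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 100))
        y = np.zeros(n, dtype=int)
        y[: max(1, n // 3)] = 1
        rng.shuffle(y)
        scores = np.round(rng.uniform(size=n), 2)  # induces ties
        assert auroc(scores, y) == pytest.approx(auc_pair_counting(scores, y), abs=1e-12)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        s = rng.uniform(size=4000)
        assert auroc(s, y) == pytest.approx(0.5, abs=0.03)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestCompareROCs:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 30)
        s = rng.uniform(size=60)
        delta, p = compare_rocs(s, s, y)
        assert delta == 0.0
        assert p == 1.0

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        n = 60
        y = (rng.uniform(size=n) < 0.4).astype(int)
        base = rng.standard_normal(n) + 0.9 * y
        a = base + 0.4 * rng.standard_normal(n)
        b = 0.7 * base + 0.8 * rng.standard_normal(n)
        _, p = compare_rocs(a, b, y)
        obs = abs(auroc(a, y) - auroc(b, y))
        count = 0
        shuffles = 10_000
        for _ in range(shuffles):
            swap = rng.uniform(size=n) < 0.5
            da = abs(auroc(np.where(swap, b, a), y) - auroc(np.where(swap, a, b), y))
            count += da >= obs - 1e-12
        p_perm = (count + 1) / (shuffles + 1)
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_separated_versus_random_is_significant(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 100)
        good = y + 0.1 * rng.standard_normal(200)
        noise = rng.standard_normal(200)
        _, p = compare_rocs(good, noise, y)
        assert p < 0.01

    def test_unpaired_inputs_raise(self):
        with pytest.raises(ValueError):
            compare_rocs(np.arange(5.0), np.arange(4.0), np.array([0, 1, 0, 1, 0]))


class TestOperatingMetrics:
    def test_perfect_classifier(self):
        s = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        m = operating_metrics(s, y, 0.5)
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            point, lo, hi = m[key]
            assert point == 1.0
            assert 0.0 <= lo <= point <= hi <= 1.0

    def test_all_positive_predictions(self):
        s = np.ones(10)
        y = np.array([1] * 6 + [0] * 4)
        m = operating_metrics(s, y, 0.5)
        assert m["sensitivity"][0] == 1.0
        assert m["specificity"][0] == 0.0

    def test_hand_computed_confusion_table(self):
        # TP=33 FN=10 TN=9 FP=4
        y = np.array([1] * 43 + [0] * 13)
        s = np.concatenate([np.ones(33), np.zeros(10), np.zeros(9), np.ones(4)])
        m = operating_metrics(s, y, 0.5)
        assert m["sensitivity"][0] == pytest.approx(33 / 43)
        assert m["specificity"][0] == pytest.approx(9 / 13)
        assert m["ppv"][0] == pytest.approx(33 / 37)
        assert m["npv"][0] == pytest.approx(9 / 19)


class TestFeatureAssociation:
    def make_table(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "flat": np.ones(12),
                "shifted": np.r_[rng.normal(0, 1, 6), rng.normal(4, 1, 6)],
                "noise": rng.normal(size=12),
                "label": ["pCR"] * 6 + ["no-pCR"] * 6,
            }
        )
        return df

    def test_constant_feature_p_one(self):
        res = feature_association(self.make_table(), ["flat", "shifted", "noise"])
        assert res.loc["flat", "p"] == 1.0

    def test_exact_rank_sum_small_sample(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, 5, 6], "label": ["pCR"] * 3 + ["no-pCR"] * 3}
        )
        res = feature_association(df, ["x"])
        assert res.loc["x", "p"] == pytest.approx(0.1)

    def test_bh_adjustment_properties(self):
        res = feature_association(self.make_table(), ["flat", "shifted", "noise"])
        assert (res["q"] >= res["p"] - 1e-12).all()
        ordered = res.sort_values("p")
        assert (np.diff(ordered["q"]) >= -1e-12).all()
        assert (res["q"] < 0.05).sum() <= (res["p"] < 0.05).sum()


class TestEvaluateScores:
    def test_report_orientation_and_bounds(self):
        rng = np.random.default_rng(4)
        labels = pd.Series(["pCR"] * 20 + ["no-pCR"] * 40)
        scores = np.where(labels == "pCR", 0.7, 0.3) + 0.1 * rng.standard_normal(60)
        rep = evaluate_scores(scores, labels, threshold=0.5)
        assert rep.n_positive == 40  # no-pCR is the positive class
        assert 0.0 <= rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1] <= 1.0
        for tup in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert 0.0 <= tup[1] <= tup[0] <= tup[2] <= 1.0
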