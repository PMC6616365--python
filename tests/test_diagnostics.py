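import numpy as np
import pytest

from sttkit.diagnostics import (
    auc,
    auc_ci,
    icc,
    optimal_cutoff,
    roc_curve,
    round_half_up,
    sens_spec_from_counts,
    spearman,
    two_sample_ttest,
)


def mann_whitney_auc(scores, labels, direction):
    """Independent pair-counting oracle: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "patient"]
    neg = scores[labels != "patient"]
    total = 0.0
    for p in pos:
        for n in neg:
            if p == n:
                total += 0.5
            elif (p < n) == (direction == "lower_is_positive"):
                total += 1.0
    return total / (len(pos) * len(neg))


def random_score_set(rng, max_n=12):
    n_pos = int(rng.integers(1, max_n))
    n_neg = int(rng.integers(1, max_n))
    # integer scores force plenty of ties
    scores = rng.integers(0, 8, n_pos + n_neg).astype(float)
    labels = np.array(["patient"] * n_pos + ["healthy"] * n_neg)
    return scores, labels


class TestROC:
    def test_perfect_separation_has_perfect_operating_point(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array(["patient", "patient", "healthy", "healthy"])
        roc = roc_curve(scores, labels, "lower_is_positive")
        assert roc.auc == 1.0
        assert roc.cutoff_sens == 1.0 and roc.cutoff_spec == 1.0
        assert 2.0 < roc.cutoff < 3.0  # midpoint threshold, not an observed score

    def test_identical_scores_only_trivial_operating_points(self):
        scores = np.full(6, 5.0)
        labels = np.array(["patient"] * 3 + ["healthy"] * 3)
        roc = roc_curve(scores, labels, "lower_is_positive")
        pairs = set(zip(roc.sens.tolist(), roc.spec.tolist()))
        assert pairs == {(1.0, 0.0), (0.0, 1.0)}

    def test_sens_spec_match_confusion_matrix_enumeration(self, rng):
        for _ in range(30):
            scores, labels = random_score_set(rng)
            for direction in ("lower_is_positive", "higher_is_positive"):
                roc = roc_curve(scores, labels, direction)
                pos = labels == "patient"
                for thr, sens, spec in zip(roc.thresholds, roc.sens, roc.spec):
                    called = scores <= thr if direction == "lower_is_positive" else scores >= thr
                    tp = np.sum(called & pos)
                    tn = np.sum(~called & ~pos)
                    assert sens == tp / pos.sum()
                    assert spec == tn / (~pos).sum()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1.0, 2.0], ["patient", "patient"], "lower_is_positive")

    def test_sens_antitone_spec_monotone_in_threshold(self, rng):
        scores, labels = random_score_set(rng, max_n=20)
        roc = roc_curve(scores, labels, "lower_is_positive")
        assert np.all(np.diff(roc.sens) >= 0)  # thresholds ascend, lower positive
        assert np.all(np.diff(roc.spec) <= 0)


class TestAUC:
    def test_interleaved_example(self):
        scores = [1.0, 3.0, 2.0, 4.0]
        labels = ["patient", "patient", "healthy", "healthy"]
        assert auc(scores, labels, "lower_is_positive") == 0.75

    def test_trapezoid_equals_mann_whitney_on_500_random_sets(self, rng):
        for _ in range(500):
            scores, labels = random_score_set(rng)
            direction = ("lower_is_positive", "higher_is_positive")[int(rng.integers(2))]
            ours = auc(scores, labels, direction)
            oracle = mann_whitney_auc(scores, labels, direction)
            assert abs(ours - oracle) < 1e-12

    def test_direction_swap_symmetry(self, rng):
        scores, labels = random_score_set(rng, max_n=15)
        a = auc(scores, labels, "lower_is_positive")
        b = auc(scores, labels, "higher_is_positive")
        assert a + b == pytest.approx(1.0)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores, labels = random_score_set(rng, max_n=15)
            expected = roc_auc_score((labels == "patient").astype(int), -scores)
            assert auc(scores, labels, "lower_is_positive") == pytest.approx(expected)


class TestOptimalCutoff:
    def test_exhaustive_enumeration_agreement(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 10, n).astype(float)
            labels = np.array(["patient"] * (n // 2) + ["healthy"] * (n - n // 2))
            if len(set(labels)) < 2:
                continue
            roc = roc_curve(scores, labels, "lower_is_positive")
            d2 = (1 - roc.sens) ** 2 + (1 - roc.spec) ** 2
            keys = list(zip(d2, -roc.sens, -roc.spec, roc.thresholds))
            expected = roc.thresholds[keys.index(min(keys))]
            assert optimal_cutoff(roc) == expected

    def test_perfect_separation_reaches_corner(self):
        roc = roc_curve(
            [1.0, 2.0, 30.0, 40.0],
            ["patient", "patient", "healthy", "healthy"],
            "lower_is_positive",
        )
        d2 = (1 - roc.cutoff_sens) ** 2 + (1 - roc.cutoff_spec) ** 2
        assert d2 == 0.0
        assert roc.cutoff == 16.0

    def test_tie_broken_by_higher_sensitivity(self):
        # one patient and one control misclassified symmetrically: the two
        # candidate thresholds have equal distance; the rule picks higher sens
        scores = [1.0, 4.0, 2.0, 5.0]
        labels = ["patient", "patient", "healthy", "healthy"]
        roc = roc_curve(scores, labels, "lower_is_positive")
        assert roc.cutoff_sens == 1.0


class TestCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((14, 1, 15, 3), (0.93, 0.83)),
            ((13, 2, 16, 2), (0.87, 0.89)),
            ((7, 0, 9, 0), (1.0, 1.0)),
        ],
    )
    def test_sens_spec_examples(self, counts, expected):
        assert sens_spec_from_counts(*counts) == expected

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="positives"):
            sens_spec_from_counts(0, 0, 5, 5)

    def test_rounding_is_half_up(self):
        assert round_half_up(0.925, 2) == 0.93
        assert round_half_up(84.35, 1) == 84.4


class TestAUCCI:
    def test_delong_is_deterministic_and_contains_point(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 15), rng.normal(1.5, 1, 18)])
        labels = np.array(["patient"] * 15 + ["healthy"] * 18)
        ci1 = auc_ci(scores, labels, "lower_is_positive", method="delong")
        ci2 = auc_ci(scores, labels, "lower_is_positive", method="delong")
        assert ci1 == ci2
        point = auc(scores, labels, "lower_is_positive")
        assert ci1[0] <= point <= ci1[1]
        assert 0.0 <= ci1[0] and ci1[1] <= 1.0

    def test_bootstrap_reproducible_and_requires_seed(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 12)])
        labels = np.array(["patient"] * 10 + ["healthy"] * 12)
        ci1 = auc_ci(scores, labels, "lower_is_positive", method="bootstrap", seed=42)
        ci2 = auc_ci(scores, labels, "lower_is_positive", method="bootstrap", seed=42)
        assert ci1 == ci2
        with pytest.raises(ValueError, match="seed"):
            auc_ci(scores, labels, "lower_is_positive", method="bootstrap")

    def test_wider_separation_gives_narrower_interval(self):
        # Monte-Carlo check on matched sample sizes
        widths = []
        for gap in (0.5, 3.0):
            w = []
            for rep in range(10):
                r = np.random.default_rng(100 + rep)
                scores = np.concatenate([r.normal(0, 1, 15), r.normal(gap, 1, 18)])
                labels = np.array(["patient"] * 15 + ["healthy"] * 18)
                lo, hi = auc_ci(scores, labels, "lower_is_positive", method="delong")
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[1] < widths[0]

    def test_degenerate_separation_warns(self):
        scores = [1.0, 2.0, 9.0, 10.0]
        labels = ["patient", "patient", "healthy", "healthy"]
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = auc_ci(scores, labels, "lower_is_positive", method="delong")
        assert (lo, hi) == (0.0, 1.0)


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 4.0, 5.0, 10.0])[0] == pytest.approx(1.0)
        assert spearman(x, [10.0, 5.0, 4.0, 2.0])[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d^2 = (0,1,1,0): rho = 1 - 6*2/(4*15) = 0.8
        rho, p = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)
        assert 0.0 < p <= 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestICC:
    @staticmethod
    def anova_oracle(X):
        """From-scratch two-way mean squares for ICC(3,1)."""
        X = np.asarray(X, dtype=float)
        n, k = X.shape
        grand = X.mean()
        ms_rows = k * np.sum((X.mean(axis=1) - grand) ** 2) / (n - 1)
        ss_cols = n * np.sum((X.mean(axis=0) - grand) ** 2)
        ss_err = np.sum((X - grand) ** 2) - k * np.sum((X.mean(axis=1) - grand) ** 2) - ss_cols
        ms_err = ss_err / ((n - 1) * (k - 1))
        return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    def test_identical_columns_give_one(self):
        X = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0], [9.0, 9.0, 9.0]])
        res = icc(X)
        assert res.icc == pytest.approx(1.0)
        assert "consistency" in res.model

    def test_matches_anova_oracle(self, rng):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert icc(X).icc == pytest.approx(self.anova_oracle(X), abs=1e-12)
        for _ in range(10):
            X = rng.normal(0, 1, (int(rng.integers(3, 12)), int(rng.integers(2, 5))))
            X += rng.normal(0, 2, (X.shape[0], 1))  # subject effects
            assert icc(X).icc == pytest.approx(self.anova_oracle(X), abs=1e-10)

    def test_matches_pingouin_cross_check(self, rng):
        import pandas as pd
        import pingouin as pg

        X = rng.normal(0, 1, (12, 3)) + rng.normal(0, 2, (12, 1))
        df = pd.DataFrame(X).reset_index().melt(id_vars="index", var_name="rater")
        out = pg.intraclass_corr(
            df, targets="index", raters="rater", ratings="value"
        ).set_index("Type")
        res = icc(X)
        assert res.icc == pytest.approx(out.loc["ICC(C,1)", "ICC"], abs=1e-9)
        lo, hi = out.loc["ICC(C,1)", "CI95"]
        assert res.ci[0] == pytest.approx(lo, abs=0.01)
        assert res.ci[1] == pytest.approx(hi, abs=0.01)

    def test_column_shift_invariance_under_consistency(self, rng):
        X = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
        shifted = X.copy()
        shifted[:, 1] += 7.5
        assert icc(shifted).icc == pytest.approx(icc(X).icc, abs=1e-12)

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(0, 1, (9, 3)) + rng.normal(0, 2, (9, 1))
        perm = rng.permutation(9)
        assert icc(X[perm]).icc == pytest.approx(icc(X).icc, abs=1e-12)

    def test_ci_contains_estimate(self, rng):
        X = rng.normal(0, 1, (10, 3)) + rng.normal(0, 1.5, (10, 1))
        res = icc(X)
        assert res.ci[0] <= res.icc <= res.ci[1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            icc(np.ones((1, 3)))
        with pytest.raises(ValueError, match="missing"):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError, match="variance"):
            icc(np.full((4, 3), 2.0))


class TestTTest:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0]
        t, p = two_sample_ttest(a, a)
        assert t == 0.0 and p == 1.0

    def test_swap_flips_sign_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        t1, p1 = two_sample_ttest(a, b)
        t2, p2 = two_sample_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_student_matches_hand_pooled_formula(self):
        # pooled sd = 1, t = (2 - 5) / sqrt(1/3 + 1/3) = -3.6742...
        t, _ = two_sample_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], "student")
        assert abs(t) == pytest.approx(3.674234614174767)

    def test_welch_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 0.2, 6)
        b = rng.normal(1, 3.0, 30)
        t_s, p_s = two_sample_ttest(a, b, "student")
        t_w, p_w = two_sample_ttest(a, b, "welch")
        assert p_s != p_w

    def test_zero_variance_equal_means_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_ttest([2.0, 2.0], [2.0, 2.0])
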