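import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from lexstress.evaluate import (
    RatingRecord,
    build_agreement_report,
    chi_square_2x2,
    cohens_kappa,
    collapse_likert,
    correctness_partition,
    correlation,
    hedges_g,
    mann_whitney,
    percent_agreement,
    phoneme_accuracy,
    summary_two_sample_t,
    weighted_kappa,
)

# Printed group summaries used as test inputs (mean, sd, n) per group.
PPC_TD, PPC_CAS = (95.2, 4.2, 16), (61.8, 21.1, 26)
PVC_TD, PVC_CAS = (93.9, 5.3, 16), (67.5, 17.6, 26)
SEX_TABLE = [[7, 9], [22, 4]]


def exact_moment_sample(mean, sd, n):
    """n values with exactly this mean and sample (ddof=1) sd."""
    d = sd * np.sqrt((n - 1) / n)
    half = n // 2
    return np.concatenate([np.full(half, mean - d), np.full(n - half, mean + d)])


class TestLikertCollapse:
    @pytest.mark.parametrize("likert,expected", [
        (1, "WS"), (2, "WS"), (3, "equal"), (4, "SW"), (5, "SW"),
    ])
    def test_mapping(self, likert, expected):
        assert collapse_likert(likert) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            collapse_likert(6)


class TestPercentAgreement:
    def test_identical_sequences_100(self):
        assert percent_agreement(["SW"] * 10, ["SW"] * 10) == 100.0

    def test_four_of_five_is_clinical_threshold(self):
        assert percent_agreement(list("SSSSW"), list("SSSSS")) == 80.0

    def test_complementary_binary_zero(self):
        assert percent_agreement(["SW", "WS"], ["WS", "SW"]) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            percent_agreement(["SW"], ["SW", "WS"])


class TestKappa:
    def test_perfect_agreement_is_one(self):
        assert cohens_kappa(["SW", "WS"] * 5, ["SW", "WS"] * 5) == 1.0

    def test_hand_2x2_table_gives_point_six(self):
        a = ["SW"] * 40 + ["WS"] * 40 + ["SW"] * 10 + ["WS"] * 10
        b = ["SW"] * 40 + ["WS"] * 40 + ["WS"] * 10 + ["SW"] * 10
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.choice(["SW", "WS"], 10_000)
        b = rng.choice(["SW", "WS"], 10_000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 6, 300)
        b = np.clip(a + rng.integers(-1, 2, 300), 1, 5)
        assert cohens_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)
        assert weighted_kappa(a, b, "linear") == pytest.approx(
            cohen_kappa_score(a, b, weights="linear"), abs=1e-12)
        assert weighted_kappa(a, b, "quadratic") == pytest.approx(
            cohen_kappa_score(a, b, weights="quadratic"), abs=1e-12)


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        a = [1, 2, 3, 4, 5] * 4
        assert weighted_kappa(a, a) == 1.0

    def test_equals_direct_double_summation(self):
        rng = np.random.default_rng(17)
        a = rng.integers(1, 6, 500)
        b = np.clip(a + rng.integers(-2, 3, 500), 1, 5)
        # brute-force: observed and chance tables, w_ij = |i-j|/(k-1)
        k = 5
        obs = np.zeros((k, k))
        for x, y in zip(a, b):
            obs[x - 1, y - 1] += 1
        obs /= obs.sum()
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
        num = den = 0.0
        for i in range(k):
            for j in range(k):
                w = abs(i - j) / (k - 1)
                num += w * obs[i, j]
                den += w * exp[i, j]
        assert weighted_kappa(a, b) == pytest.approx(1 - num / den, abs=1e-12)

    def test_near_disagreements_penalized_less_than_far(self):
        near_a, near_b = [1] * 10 + [3] * 10, [2] * 10 + [3] * 10
        far_a, far_b = [1] * 10 + [3] * 10, [5] * 10 + [3] * 10
        assert weighted_kappa(near_a, near_b) > weighted_kappa(far_a, far_b)

    def test_two_category_linear_equals_unweighted(self):
        rng = np.random.default_rng(4)
        a = rng.choice(["SW", "WS"], 200)
        b = rng.choice(["SW", "WS"], 200)
        assert weighted_kappa(a, b) == pytest.approx(cohens_kappa(a, b),
                                                     abs=1e-12)


class TestMannWhitney:
    def test_complete_separation_gives_u_zero(self):
        u, z, p = mann_whitney([1, 2, 3], [10, 11, 12, 13])
        assert u == 0.0

    def test_identical_multisets_give_half_and_z_zero(self):
        u, z, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 4 * 4 / 2
        assert z == pytest.approx(0.0, abs=0.2)  # continuity correction

    def test_equals_pairwise_enumeration_small_n(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 8 - n1 + 1)) if n1 < 7 else 1
            x = rng.integers(0, 5, n1).astype(float)
            y = rng.integers(0, 5, n2).astype(float)
            u, _, _ = mann_whitney(x, y)
            u1 = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
            assert u == pytest.approx(min(u1, n1 * n2 - u1))

    def test_p_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 25)
        _, _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestHedgesG:
    def test_identical_groups_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert hedges_g(x, x) == 0.0

    def test_table1_summaries_match_closed_form(self):
        x = exact_moment_sample(*PPC_TD)
        y = exact_moment_sample(*PPC_CAS)
        n1, n2 = PPC_TD[2], PPC_CAS[2]
        sp = np.sqrt(((n1 - 1) * PPC_TD[1] ** 2 + (n2 - 1) * PPC_CAS[1] ** 2)
                     / (n1 + n2 - 2))
        J = 1 - 3 / (4 * (n1 + n2) - 9)
        expected = J * (PPC_TD[0] - PPC_CAS[0]) / sp
        assert hedges_g(x, y) == pytest.approx(expected, rel=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        assert hedges_g(x + 100, y + 100) == pytest.approx(hedges_g(x, y))


class TestCorrelation:
    def test_identity_gives_one_for_all_methods(self):
        x = np.arange(10.0)
        assert correlation(x, x, "pearson") == pytest.approx(1.0)
        assert correlation(x, x, "spearman") == pytest.approx(1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        assert correlation(np.exp(x), y, "spearman") == pytest.approx(
            correlation(x, y, "spearman"))

    def test_spearman_agrees_with_rank_pearson(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 50, 1000).astype(float)  # ties exercised
        y = x + rng.normal(0, 10, 1000)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert correlation(x, y, "spearman") == pytest.approx(brute, abs=1e-12)

    def test_point_biserial_with_binary_variable(self):
        rng = np.random.default_rng(12)
        b = rng.integers(0, 2, 200)
        y = b * 2.0 + rng.normal(0, 1, 200)
        r = correlation(b.astype(float), y, "point_biserial")
        assert r == pytest.approx(sps.pointbiserialr(b, y).statistic)

    def test_zero_variance_undefined(self):
        assert np.isnan(correlation([1, 1, 1], [1, 2, 3], "pearson"))


class TestPhonemeAccuracy:
    def test_perfect_production(self):
        t = "b ax n ae n ax".split()
        acc = phoneme_accuracy(t, t)
        assert (acc.PCC, acc.PVC, acc.PPC) == (100.0, 100.0, 100.0)

    def test_one_consonant_substitution(self):
        t = "b ax n ae n ax".split()
        p = "b ax n ae d ax".split()
        acc = phoneme_accuracy(t, p)
        assert acc.PCC == pytest.approx(200 / 3)
        assert acc.PVC == 100.0
        assert acc.PPC == pytest.approx(500 / 6)

    def test_one_deleted_consonant(self):
        t = "b ax n ae n ax".split()
        p = "b ax ae n ax".split()
        acc = phoneme_accuracy(t, p)
        assert acc.PPC == pytest.approx(500 / 6)

    def test_ppc_between_pcc_and_pvc(self):
        t = "p aa t iy k uw".split()
        p = "p aa d iy k uw".split()
        acc = phoneme_accuracy(t, p)
        assert min(acc.PCC, acc.PVC) <= acc.PPC <= max(acc.PCC, acc.PVC)

    def test_inserting_correct_phoneme_never_lowers_counts(self):
        t = "p aa t iy".split()
        worse = "p aa".split()
        better = "p aa t".split()
        a, b = phoneme_accuracy(t, worse), phoneme_accuracy(t, better)
        assert b.PPC >= a.PPC and b.PCC >= a.PCC

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            phoneme_accuracy([], ["p"])


class TestSummaryTests:
    def test_equal_summaries_zero(self):
        assert summary_two_sample_t(5, 1, 10, 5, 1, 10) == 0.0

    def test_reproduces_printed_group_t_statistics(self):
        assert summary_two_sample_t(*PPC_TD, *PPC_CAS) == pytest.approx(
            6.24, abs=0.02)
        assert summary_two_sample_t(*PVC_TD, *PVC_CAS) == pytest.approx(
            5.82, abs=0.02)

    def test_sex_table_chi_square_printed_value(self):
        assert round(chi_square_2x2(SEX_TABLE), 1) == 7.7

    def test_proportional_table_zero(self):
        assert chi_square_2x2([[10, 20], [5, 10]]) == pytest.approx(0.0)

    def test_chi_square_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            t = rng.integers(1, 50, size=(2, 2))
            ref = sps.chi2_contingency(t, correction=False).statistic
            assert chi_square_2x2(t) == pytest.approx(ref, rel=1e-12)


class TestCorrectnessPartition:
    def test_rules(self):
        ratings = [RatingRecord(0, 5), RatingRecord(1, 3), RatingRecord(2, 4)]
        canonical = ["SW", "SW", "WS"]
        correct, incorrect, skipped = correctness_partition(ratings, canonical)
        assert [r.token_id for r in correct] == [0]
        assert [r.token_id for r in incorrect] == [1, 2]
        assert not skipped

    def test_ss_canonical_excluded(self):
        correct, incorrect, skipped = correctness_partition(
            [RatingRecord(0, 5)], ["SS"])
        assert not correct and not incorrect
        assert len(skipped) == 1


class TestAgreementReport:
    def make_df(self, n=80, disagree=0.0, seed=0):
        rng = np.random.default_rng(seed)
        call = rng.choice(["SW", "WS"], n)
        likert = np.where(call == "SW", 5, 1)
        flip = rng.random(n) < disagree
        likert = np.where(flip, 6 - likert, likert)
        return pd.DataFrame({
            "call": call, "likert": likert,
            "group": rng.choice(["TD", "CAS"], n),
            "stress": call, "mode": rng.choice(["single", "multiple"], n),
        })

    def test_perfect_match_every_stratum(self):
        rep = build_agreement_report(self.make_df())
        assert rep["pooled"].percent_agreement == 100.0
        assert rep["pooled"].kappa == 1.0
        for r in rep["strata"].values():
            assert r.percent_agreement == 100.0

    def test_stratification_shape(self):
        rep = build_agreement_report(self.make_df(n=400, seed=1))
        assert len(rep["strata"]) == 8  # group x stress x mode

    def test_injected_disagreement_recovered(self):
        rep = build_agreement_report(self.make_df(n=500, disagree=0.2, seed=2))
        lo, hi = sps.binom.interval(0.99, 500, 0.8)
        assert lo / 5 <= rep["pooled"].percent_agreement <= hi / 5

    def test_equal_rating_counts_as_disagreement(self):
        df = pd.DataFrame({"call": ["SW"] * 4, "likert": [5, 5, 3, 3],
                           "group": "TD", "stress": "SW", "mode": "single"})
        rep = build_agreement_report(df)
        assert rep["pooled"].percent_agreement == 50.0
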