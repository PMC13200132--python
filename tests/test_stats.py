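import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orbitsharp import (
    cohen_kappa,
    detector_agreement_report,
    icc_two_way_mixed,
    kendall_tau,
    paired_t,
    within_participant_cv,
    wilcoxon_signed_rank,
)
from orbitsharp.features import EdgeFeatureResult


# --------------------------------------------------------------------------
# independent brute-force oracles

def kappa_brute(r1, r2):
    cats = sorted(set(r1) | set(r2))
    n = len(r1)
    po = sum(a == b for a, b in zip(r1, r2)) / n
    pe = sum(
        (sum(a == c for a in r1) / n) * (sum(b == c for b in r2) / n) for c in cats
    )
    return (po - pe) / (1 - pe)


def tau_brute(x, y, variant):
    n = len(x)
    conc = disc = 0
    for i, j in itertools.combinations(range(n), 2):
        s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
        conc += s > 0
        disc += s < 0
    n0 = n * (n - 1) / 2
    if variant == "b":
        t1 = sum(t * (t - 1) / 2 for t in np.unique(x, return_counts=True)[1])
        t2 = sum(t * (t - 1) / 2 for t in np.unique(y, return_counts=True)[1])
        return (conc - disc) / np.sqrt((n0 - t1) * (n0 - t2))
    m = min(len(set(x)), len(set(y)))
    return 2 * m * (conc - disc) / (n**2 * (m - 1))


def icc_brute(table):
    """Mean squares by explicit loops over the two-way layout."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    gm = x.sum() / (n * k)
    ssr = sum(k * (x[i].mean() - gm) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - gm) ** 2 for j in range(k))
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + gm) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return {
        "single_consistency": (msr - mse) / (msr + (k - 1) * mse),
        "avg_consistency": (msr - mse) / msr,
        "single_agreement": (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n),
        "avg_agreement": (msr - mse) / (msr + (msc - mse) / n),
    }


# --------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            _, p = wilcoxon_signed_rank([(1.0, 1.0)] * 8)
        assert p == 1.0

    def test_exact_enumeration_five_positive(self):
        # all five differences positive: one-sided tail 1/32, two-sided 1/16
        pairs = [(2, 1), (4, 2), (6, 3), (8, 4), (10, 5)]
        _, p = wilcoxon_signed_rank(pairs)
        assert p == pytest.approx(0.0625, abs=1e-12)

    def test_matches_independent_implementation(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 0.1, 25)
        b = a - rng.normal(0.05, 0.05, 25)
        stat, p = wilcoxon_signed_rank(list(zip(a, b)))
        ref = scipy_wilcoxon(a, b)
        assert p == pytest.approx(float(ref.pvalue), abs=1e-6)


class TestPairedT:
    def test_constant_nonzero_differences_sentinel(self):
        with pytest.warns(UserWarning, match="constant"):
            t, p = paired_t([(2.0, 1.0)] * 5)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_alternating_differences_null(self):
        t, p = paired_t([(1, 0), (0, 1), (1, 0), (0, 1)])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_formula(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1.0, 25)
        pairs = [(x, 0.0) for x in d]
        t, _ = paired_t(pairs)
        assert t == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(25)), abs=1e-12)


class TestKappa:
    def test_identical_ratings(self):
        assert cohen_kappa([1, 2, 3, 2, 1], [1, 2, 3, 2, 1]) == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # confusion counts {{40,10},{10,40}}: po=0.8, pe=0.5, kappa=0.6
        r1 = [0] * 50 + [1] * 50
        r2 = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert cohen_kappa(r1, r2) == pytest.approx(0.6)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        r1 = rng.integers(1, 6, 10_000)
        r2 = rng.integers(1, 6, 10_000)
        assert abs(cohen_kappa(r1, r2)) < 0.05

    def test_single_category_sentinel(self):
        with pytest.warns(UserWarning, match="single"):
            assert np.isnan(cohen_kappa([3, 3, 3], [3, 3, 3]))

    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)),
                    min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, ratings):
        r1, r2 = zip(*ratings)
        if len(set(r1) | set(r2)) < 2:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = cohen_kappa(list(r1), list(r2))
        expect = kappa_brute(r1, r2)
        if np.isnan(expect) or np.isnan(got):
            assert np.isnan(expect) == np.isnan(got)
        else:
            assert got == pytest.approx(expect, abs=1e-12)


class TestKendallTau:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_input_sentinel(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(kendall_tau([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("variant", ["b", "c"])
    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)),
                    min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_pair_counting(self, variant, ratings):
        x, y = map(np.array, zip(*ratings))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert kendall_tau(x, y, variant) == pytest.approx(
            tau_brute(x, y, variant), abs=1e-12
        )


class TestCV:
    def test_identical_row_zero(self):
        cvs, _ = within_participant_cv([[5, 5, 5]])
        assert cvs[0] == 0.0

    def test_two_value_closed_form(self):
        cvs, summary = within_participant_cv([[4, 6]])
        assert cvs[0] == pytest.approx(np.sqrt(2) / 5 * 100)
        assert summary == pytest.approx(cvs[0])

    def test_identical_rows_aggregate_to_row_cv(self):
        table = [[4, 6]] * 10
        cvs, summary = within_participant_cv(table)
        assert summary == pytest.approx(cvs[0])

    def test_nonpositive_mean_excluded(self):
        with pytest.warns(UserWarning, match="non-positive"):
            cvs, summary = within_participant_cv([[1, 3], [0, 0]])
        assert np.isnan(cvs[1]) and summary == pytest.approx(cvs[0])


class TestICC:
    def test_identical_columns_all_ones(self):
        col = np.arange(1.0, 9.0)
        res = icc_two_way_mixed(np.column_stack([col, col, col]))
        for v in (res.icc_single_consistency, res.icc_avg_consistency,
                  res.icc_single_agreement, res.icc_avg_agreement):
            assert v == pytest.approx(1.0)

    def test_constant_offset_consistent_not_agreeing(self):
        col = np.arange(1.0, 9.0)
        res = icc_two_way_mixed(np.column_stack([col, col + 2.0]))
        assert res.icc_single_consistency == pytest.approx(1.0)
        assert res.icc_single_agreement < 1.0
        assert res.msc > res.mse

    def test_no_subject_variance_sentinel(self):
        with pytest.warns(UserWarning, match="no between-subject"):
            res = icc_two_way_mixed(np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]))
        assert np.isnan(res.icc_single_consistency)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            table = rng.normal(0, 1, (10, 3)) + rng.normal(0, 1, (10, 1))
            res = icc_two_way_mixed(table)
            oracle = icc_brute(table)
            assert res.icc_single_consistency == pytest.approx(
                oracle["single_consistency"], abs=1e-8)
            assert res.icc_avg_consistency == pytest.approx(
                oracle["avg_consistency"], abs=1e-8)
            assert res.icc_single_agreement == pytest.approx(
                oracle["single_agreement"], abs=1e-8)
            assert res.icc_avg_agreement == pytest.approx(
                oracle["avg_agreement"], abs=1e-8)

    def test_matches_pingouin_forms(self):
        pg = pytest.importorskip("pingouin")

        rng = np.random.default_rng(8)
        table = rng.normal(0, 1, (12, 3)) + rng.normal(0, 2, (12, 1))
        res = icc_two_way_mixed(table)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": table.ravel(),
            }
        )
        icc = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")["ICC"]
        assert res.icc_single_agreement == pytest.approx(icc["ICC(A,1)"], abs=1e-8)
        assert res.icc_single_consistency == pytest.approx(icc["ICC(C,1)"], abs=1e-8)
        assert res.icc_avg_agreement == pytest.approx(icc["ICC(A,k)"], abs=1e-8)
        assert res.icc_avg_consistency == pytest.approx(icc["ICC(C,k)"], abs=1e-8)

    def test_subject_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        table = rng.normal(0, 1, (9, 3))
        res = icc_two_way_mixed(table)
        perm = icc_two_way_mixed(table[rng.permutation(9)])
        assert res.icc_single_agreement == pytest.approx(
            perm.icc_single_agreement, abs=1e-12)


def _fake_result(detector, steep, width=3.0, contrast=0.5):
    return EdgeFeatureResult(
        detector=detector, mean_steepness=steep, mean_width_px=width,
        mean_contrast=contrast, n_edge_pixels=100, n_valid_widths=90,
    )


class TestDetectorAgreement:
    def test_identical_detectors_perfect_agreement(self):
        features = {
            f"S{i}": [_fake_result(d, 0.1 + 0.01 * i) for d in ("roberts", "sobel", "canny")]
            for i in range(6)
        }
        rep = detector_agreement_report(features)
        row = rep.set_index("feature").loc["steepness"]
        assert row.cv_percent == pytest.approx(0.0)
        assert row.icc_single_consistency == pytest.approx(1.0)
        assert row.icc_avg_agreement == pytest.approx(1.0)

    def test_scaled_detectors_consistent_but_offset(self):
        rng = np.random.default_rng(5)
        base = 0.1 + 0.1 * rng.random(10)
        features = {
            f"S{i}": [
                _fake_result("roberts", base[i]),
                _fake_result("sobel", 0.9 * base[i]),
                _fake_result("canny", 0.8 * base[i]),
            ]
            for i in range(10)
        }
        rep = detector_agreement_report(features).set_index("feature")
        row = rep.loc["steepness"]
        assert row.icc_single_consistency > 0.95
        assert row.icc_single_agreement < row.icc_single_consistency

    def test_incomplete_subject_dropped(self):
        features = {
            f"S{i}": [_fake_result(d, 0.1 + 0.01 * i) for d in ("roberts", "sobel", "canny")]
            for i in range(5)
        }
        features["S9"] = [_fake_result("roberts", 0.2)]
        with pytest.warns(UserWarning, match="incomplete"):
            rep = detector_agreement_report(features)
        assert rep.n_subjects.iloc[0] == 5
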