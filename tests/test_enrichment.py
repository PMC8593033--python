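"""Enrichment scores and sqrt-scaled proportion tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicenrich.enrichment import (
    EnrichmentScorer,
    compute_run,
    enrichment_score,
    prop_test_all,
    prop_test_sample,
    pseudocount,
    relative_read_count,
)


def make_matrix(r_by_sample, s_by_sample, contig="c", start=201, end=300):
    rows = []
    for i, (r, s) in enumerate(zip(r_by_sample, s_by_sample)):
        rows.append((f"S{i + 1}", contig, start, end, r, s, 0))
    return pd.DataFrame(
        rows, columns=["sample_id", "contig", "intron_start", "intron_end", "r", "s", "b"]
    )


class TestPseudocount:
    @pytest.mark.parametrize("s,expected", [(0, 10), (500, 10), (1000, 10), (5000, 50), (20000, 200)])
    def test_floor_and_one_percent_regimes(self, s, expected):
        assert pseudocount(s) == expected

    def test_negative_spanning_count_rejected(self):
        with pytest.raises(ValueError):
            pseudocount(-1)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=10**7))
    def test_pseudocount_is_max_of_floor_and_rate(self, s):
        assert pseudocount(s) == max(10.0, 0.01 * s)


class TestRelativeReadCount:
    def test_pseudocounted_fraction(self):
        assert relative_read_count(90, 1000) == pytest.approx(100 / 1010)

    def test_absent_coverage_saturates_with_pseudocounts(self):
        assert relative_read_count(0, 0, with_pc=True) == 1.0

    def test_absent_coverage_is_zero_without_pseudocounts(self):
        assert relative_read_count(0, 0, with_pc=False) == 0.0

    def test_r_greater_than_s_rejected(self):
        with pytest.raises(ValueError):
            relative_read_count(11, 10)


class TestEnrichmentScore:
    def test_spiked_sample_hand_value(self):
        # one sample at 200/1000 against four at 10/1000:
        # l'_spike = 0.2; background l_j = 20/1010 each; ERS = 10.10
        r, s = [200, 10, 10, 10, 10], [1000] * 5
        assert enrichment_score(0, r, s) == pytest.approx(10.10, abs=1e-3)

    def test_homogeneous_score_slightly_shrunk_below_one(self):
        r, s = [100] * 5, [1000] * 5
        assert enrichment_score(0, r, s) == pytest.approx(0.918, abs=1e-3)

    def test_zero_reads_give_zero_score(self):
        assert enrichment_score(1, [100, 0, 100], [1000] * 3) == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(0, [5], [10])

    def test_converges_to_one_at_high_depth(self):
        # identical true proportions, exact-proportion counts at s = 1e6.
        # The 1%-of-s pseudocount leaves an asymptotic shrinkage factor
        # 1.01p/(p + 0.01), negligible at the usage levels of reference
        # junctions (p >= 0.5).
        s = [10**6] * 6
        for p in (0.5, 0.75, 0.95):
            r = [int(p * 10**6)] * 6
            for i in range(6):
                assert abs(enrichment_score(i, r, s) - 1.0) < 0.02

    def test_competing_events_are_monotone(self):
        # locus with events A and B; moving reads from B to A (s fixed)
        # raises ERS(A) and lowers ERS(B) in the affected sample
        s = [2000] * 4
        prev_a, prev_b = -np.inf, np.inf
        for shift in (0, 100, 200, 300):
            r_a = [400 + shift, 400, 400, 400]
            r_b = [400 - shift, 400, 400, 400]
            ers_a = enrichment_score(0, r_a, s)
            ers_b = enrichment_score(0, r_b, s)
            assert ers_a > prev_a and ers_b < prev_b
            prev_a, prev_b = ers_a, ers_b

    def test_numerator_pseudocount_variant_inflates_empty_samples(self):
        r, s = [0, 100, 100], [0, 1000, 1000]
        assert enrichment_score(0, r, s) == 0.0
        assert enrichment_score(0, r, s, numerator_pseudocounts=True) > 5


class TestPropTestAll:
    def test_homogeneous_counts_give_p_one(self):
        assert prop_test_all([100] * 6, [1000] * 6) == 1.0

    def test_spiked_sample_is_significant(self):
        assert prop_test_all([400, 10, 10, 10, 10, 10], [1000] * 6) < 0.01

    def test_all_zero_successes_give_p_one(self):
        assert prop_test_all([0, 0], [100, 100]) == 1.0

    def test_fewer_than_two_covered_samples_undefined(self):
        assert math.isnan(prop_test_all([5, 0], [10, 0]))

    def test_permutation_invariance(self):
        r, s = [400, 10, 50, 10, 10, 10], [1000, 900, 1100, 1000, 1000, 950]
        p = prop_test_all(r, s)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(6)
            assert prop_test_all(np.array(r)[perm], np.array(s)[perm]) == pytest.approx(p)

    def test_matches_statsmodels_on_transformed_counts(self):
        from statsmodels.stats.proportion import proportions_chisquare

        r, s = [400, 10, 50, 10, 10, 10], [1000, 900, 1100, 1000, 1000, 950]
        stat, p, _ = proportions_chisquare(np.sqrt(r), np.sqrt(s))
        assert prop_test_all(r, s) == pytest.approx(p, rel=1e-9)


class TestPropTestSample:
    def test_depleted_sample_not_enriched(self):
        p = prop_test_sample(0, [10, 400, 400, 400], [1000] * 4)
        assert p >= 0.5

    def test_identical_sample_centers_at_half(self):
        assert prop_test_sample(0, [100] * 6, [1000] * 6) == pytest.approx(0.5, abs=1e-9)

    def test_enriched_sample_significant(self):
        assert prop_test_sample(0, [400, 10, 10, 10, 10, 10], [1000] * 6) < 0.01

    def test_pooled_background_uses_sqrt_of_sums(self):
        from scipy import stats as sps

        r = np.array([400.0, 30, 10, 5, 5])
        s = np.array([1000.0] * 5)
        x1, n1 = math.sqrt(r[0]), math.sqrt(s[0])
        x2, n2 = math.sqrt(r[1:].sum()), math.sqrt(s[1:].sum())
        pooled = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert prop_test_sample(0, r, s) == pytest.approx(float(sps.norm.sf(z)), rel=1e-12)

    def test_matches_statsmodels_one_tailed_ztest(self):
        from statsmodels.stats.proportion import proportions_ztest

        r = np.array([400.0, 30, 10, 5, 5])
        s = np.array([1000.0] * 5)
        count = [math.sqrt(r[0]), math.sqrt(r[1:].sum())]
        nobs = [math.sqrt(s[0]), math.sqrt(s[1:].sum())]
        stat, p = proportions_ztest(count, nobs, alternative="larger")
        assert prop_test_sample(0, r, s) == pytest.approx(p, rel=1e-9)

    def test_uncovered_background_undefined(self):
        assert math.isnan(prop_test_sample(0, [5, 0], [10, 0]))

    def test_group_heterogeneity_without_single_sample_enrichment(self):
        # one depleted sample: the k-sample test rejects homogeneity while
        # no sample is significantly *enriched*
        r = [900, 900, 900, 900, 900, 500]
        s = [1000] * 6
        assert prop_test_all(r, s) < 0.01
        for i in range(6):
            assert prop_test_sample(i, r, s) > 0.01


class TestEnrichmentScorer:
    def test_spiked_run_yields_exactly_one_flagged_record(self):
        mat = make_matrix([200, 10, 10, 10, 10], [1000] * 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = compute_run(mat)
        assert (rec.ers > 5).sum() == 1
        assert rec.loc[rec.ers.idxmax(), "sample_id"] == "S1"

    def test_homogeneous_high_coverage_scores_near_one(self):
        mat = make_matrix([4500] * 6, [5000] * 6)
        rec = compute_run(mat)
        assert rec.ers.between(0.8, 1.25).all()

    def test_small_group_warns_but_computes(self):
        mat = make_matrix([100, 100, 100], [1000] * 3)
        with pytest.warns(UserWarning, match="at least 4"):
            rec = compute_run(mat)
        assert len(rec) == 3

    def test_single_sample_run_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_run(make_matrix([100], [1000]))

    def test_sparse_matrix_rejected(self):
        mat = pd.concat(
            [make_matrix([100] * 4, [1000] * 4), make_matrix([50] * 4, [1000] * 4, start=401)]
        )
        with pytest.raises(ValueError, match="dense"):
            compute_run(mat.iloc[:-1])  # second event lacks one sample's row

    def test_get_set_params_round_trip(self):
        scorer = EnrichmentScorer()
        scorer.set_params(min_group=2, bh_correction=True)
        assert scorer.get_params()["min_group"] == 2
        with pytest.raises(ValueError):
            scorer.set_params(nonsense=1)

    def test_transform_requires_fit(self):
        with pytest.raises(RuntimeError):
            EnrichmentScorer().transform(make_matrix([1, 1], [10, 10]))

    def test_unknown_sample_rejected_at_transform(self):
        mat = make_matrix([100] * 4, [1000] * 4)
        scorer = EnrichmentScorer().fit(mat)
        other = mat.copy()
        other["sample_id"] = other["sample_id"].str.replace("S4", "S9")
        with pytest.raises(ValueError, match="S9"):
            scorer.transform(other)

    def test_bh_extension_adds_q_columns(self):
        mat = make_matrix([200, 10, 10, 10], [1000] * 4)
        rec = compute_run(mat, bh_correction=True)
        assert {"q_all", "q_sample"} <= set(rec.columns)
        assert (rec.q_sample.dropna() >= rec.p_sample.dropna()).all()

    def test_deterministic_given_matrix(self):
        mat = make_matrix([200, 10, 10, 10, 10], [1000] * 5)
        pd.testing.assert_frame_equal(compute_run(mat), compute_run(mat))


class TestNullCalibration:
    def test_homogeneous_null_rarely_significant(self):
        """Under a shared proportion the sqrt-scaled test is conservative."""
        rng = np.random.default_rng(11)
        n_sig = 0
        n_junctions = 400
        for _ in range(n_junctions):
            p = rng.uniform(0.05, 0.95)
            s = rng.integers(500, 5000, size=6)
            r = rng.binomial(s, p)
            if prop_test_all(r, s) < 0.01:
                n_sig += 1
        assert n_sig / n_junctions <= 0.01

    def test_per_sample_null_calibration(self):
        rng = np.random.default_rng(13)
        n_low = 0
        trials = 300
        for _ in range(trials):
            s = rng.integers(500, 5000, size=6)
            r = rng.binomial(s, 0.5)
            ps = [prop_test_sample(i, r, s) for i in range(6)]
            n_low += sum(p < 0.01 for p in ps)
        assert n_low / (trials * 6) <= 0.01
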