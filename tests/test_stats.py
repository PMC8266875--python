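"""Descriptive and nonparametric statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluorisk import (
    DegenerateInputError,
    GroupSummary,
    InsufficientDataError,
    Measurement,
    compare_groups,
    group_summaries,
    normality_check,
    pooled_sd,
    spearman_censored,
    weighted_overall_mean,
)
from fluorisk.stats import pairwise_type_comparisons
from fluorisk.synthetic import default_study_design, generate_infusion_study


def _summary(ptype, n, mean, sd, time=5.0):
    return GroupSummary(ptype, time, n, mean, sd)


class TestWeightedMean:
    def test_matches_hand_weighting(self, reference_summaries):
        # sum(n*mean)/sum(n) over the five 5-min groups, by hand:
        # (5*2.54 + 3*1.19 + 3*0.86 + 3*0.40 + 2*0.21) / 16
        expected = (5 * 2.54 + 3 * 1.19 + 3 * 0.86 + 3 * 0.40 + 2 * 0.21) / 16
        assert weighted_overall_mean(reference_summaries, 5.0) == pytest.approx(expected)

    def test_identical_means_returned_exactly(self):
        groups = [_summary(p, n, 0.7, 0.1) for p, n in [("black", 5), ("green", 3)]]
        assert weighted_overall_mean(groups, 5.0) == 0.7

    def test_empty_time_raises(self, reference_summaries):
        with pytest.raises(InsufficientDataError):
            weighted_overall_mean(reference_summaries, 15.0)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=8),
                st.floats(min_value=0.0, max_value=10.0),
            ),
            min_size=1,
            max_size=5,
        )
    )
    def test_lies_within_group_mean_range(self, pairs):
        groups = [
            _summary(f"black", n, m, 0.0) for (n, m) in pairs
        ]
        result = weighted_overall_mean(groups, 5.0)
        means = [m for _, m in pairs]
        assert min(means) - 1e-12 <= result <= max(means) + 1e-12


class TestPooledSd:
    def test_sum_of_squares_oracle(self, reference_summaries):
        # independent oracle: explicit within/between sum-of-squares enumeration
        groups = [(5, 2.54, 1.10), (3, 1.19, 0.22), (3, 0.86, 0.35), (3, 0.40, 0.35), (2, 0.21, 0.04)]
        total_n = sum(n for n, _, _ in groups)
        grand = sum(n * m for n, m, _ in groups) / total_n
        ss_within = sum((n - 1) * s**2 for n, _, s in groups)
        ss_between = sum(n * (m - grand) ** 2 for n, m, _ in groups)
        oracle = math.sqrt((ss_within + ss_between) / (total_n - 1))
        result = pooled_sd(reference_summaries, 5.0)
        assert result == pytest.approx(oracle, abs=1e-12)
        assert round(result, 3) == 1.112

    def test_single_group_returns_its_sd(self):
        assert pooled_sd([_summary("black", 4, 2.0, 0.37)], 5.0) == pytest.approx(0.37)

    def test_identical_groups_collapse_to_within_term(self):
        # brute-force oracle: raw multisets with exactly these moments
        # (n=3, mean 2, sd s): {2 - s, 2, 2 + s} has mean 2 and sample sd s.
        # With zero between-group spread the pooled value equals the direct
        # sample SD of the reconstructed raw multiset, sqrt(sum(n_i-1)s^2/(N-1))
        s = 0.5
        raw = [2 - s, 2.0, 2 + s] * 2
        direct = float(np.std(raw, ddof=1))
        groups = [_summary("black", 3, 2.0, s), _summary("green", 3, 2.0, s)]
        assert pooled_sd(groups, 5.0) == pytest.approx(direct)
        assert pooled_sd(groups, 5.0) == pytest.approx(s * math.sqrt(4 / 5), rel=1e-9)

    def test_matches_direct_sd_of_raw_data(self):
        # invariant: summarize-then-pool equals the plain sample SD
        rng = np.random.default_rng(7)
        groups, everything = [], []
        for i, n in enumerate([5, 3, 4]):
            vals = rng.normal(1 + i, 0.5, size=n)
            everything.extend(vals)
            groups.append(
                _summary("black", n, float(np.mean(vals)), float(np.std(vals, ddof=1)))
            )
        assert pooled_sd(groups, 5.0) == pytest.approx(float(np.std(everything, ddof=1)))

    def test_insufficient_combined_n(self):
        with pytest.raises(InsufficientDataError):
            pooled_sd([_summary("white", 1, 0.2, 0.0)], 5.0)


class TestNormalityCheck:
    def test_normal_draws_rarely_rejected(self):
        # under the null the pass rate is nominally 95%; with 200 repetitions
        # the binomial SD is ~3.1 hits, so the bound sits 3 SD below 190
        rng = np.random.default_rng(11)
        hits = sum(
            normality_check(rng.normal(size=50)).p_value > 0.05 for _ in range(200)
        )
        assert hits >= 181

    def test_lognormal_draws_reliably_rejected(self):
        rng = np.random.default_rng(13)
        hits = sum(
            normality_check(rng.lognormal(0.0, 1.0, size=200)).p_value < 0.05
            for _ in range(200)
        )
        assert hits >= 190

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normality_check([1.0, 1.0, 1.0, 1.0])

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            normality_check([1.0, 2.0])


def _exact_two_sided_p(a, b):
    """Enumerate every labeling of the pooled sample; two-sided p is the
    fraction of labelings at least as extreme (in min(U, nm - U)) as observed."""
    pooled = sorted(a + b)
    na, nm = len(a), len(a) * len(b)

    def u_stat(group_a):
        rest = list(pooled)
        for x in group_a:
            rest.remove(x)
        return sum(1 for x in group_a for y in rest if x < y) + 0.5 * sum(
            1 for x in group_a for y in rest if x == y
        )

    observed = min(u_stat(a), nm - u_stat(a))
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        group_a = [pooled[i] for i in combo]
        u = u_stat(group_a)
        hits += min(u, nm - u) <= observed + 1e-9
        total += 1
    return hits / total


class TestCompareGroups:
    def test_separated_groups_match_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups(a, b)
        assert res.statistic == 0.0  # no a-value beats any b-value
        assert "exact" in res.method
        assert res.p_value == pytest.approx(_exact_two_sided_p(a, b))
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_not_significant(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_all_ties_degenerate_path(self):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0
        assert "degenerate" in res.method
        assert res.statistic == 4.5

    def test_large_or_tied_samples_use_corrected_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=15)
        b = rng.normal(0.5, size=15)
        res = compare_groups(a, b)
        assert "approximation" in res.method
        assert 0 <= res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups([], [1.0])

    @given(
        st.lists(st.floats(min_value=-5, max_value=5), min_size=2, max_size=8),
        st.lists(st.floats(min_value=-5, max_value=5), min_size=2, max_size=8),
    )
    def test_two_sided_p_symmetric_in_group_order(self, a, b):
        assert compare_groups(a, b).p_value == pytest.approx(
            compare_groups(b, a).p_value
        )


def _rank_pearson(xr, yr):
    xr, yr = np.asarray(xr, float), np.asarray(yr, float)
    xd, yd = xr - xr.mean(), yr - yr.mean()
    return float(np.dot(xd, yd) / math.sqrt(np.dot(xd, xd) * np.dot(yd, yd)))


class TestSpearmanCensored:
    def test_censored_fluoride_matches_hand_rank_oracle(self, water_profiles, infusible_means):
        x = [w.fluoride for w in water_profiles]
        y = [infusible_means[w.water_type] for w in water_profiles]
        res = spearman_censored(x, y, censor_policy="substitute_dl")
        # hand ranks: three censored values tie at the limit -> average rank 2
        oracle = _rank_pearson([2, 2, 2, 4, 5, 6], [3, 1, 2, 4, 5, 6])
        assert res.rho == pytest.approx(oracle, abs=1e-9)
        assert res.rho == pytest.approx(0.941, abs=5e-4)

    def test_ph_ordering_is_perfectly_concordant(self, water_profiles, infusible_means):
        x = [w.pH for w in water_profiles]
        y = [infusible_means[w.water_type] for w in water_profiles]
        assert spearman_censored(x, y).rho == pytest.approx(1.0)

    def test_half_dl_policy_preserves_tie_structure(self, water_profiles, infusible_means):
        x = [w.fluoride for w in water_profiles]
        y = [infusible_means[w.water_type] for w in water_profiles]
        full = spearman_censored(x, y, censor_policy="substitute_dl")
        half = spearman_censored(x, y, censor_policy="substitute_half_dl")
        assert half.rho == pytest.approx(full.rho)

    def test_drop_censored_reduces_n(self, water_profiles, infusible_means):
        x = [w.fluoride for w in water_profiles]
        y = [infusible_means[w.water_type] for w in water_profiles]
        res = spearman_censored(x, y, censor_policy="drop_censored")
        assert res.n == 3
        assert res.rho == pytest.approx(1.0)  # remaining three waters concordant

    def test_antitone_pairs_give_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_censored(x, list(reversed(x))).rho == pytest.approx(-1.0)

    def test_symmetric_when_uncensored(self):
        x, y = [0.3, 1.2, 0.7, 2.0], [5.0, 9.0, 6.5, 8.0]
        assert spearman_censored(x, y).rho == pytest.approx(spearman_censored(y, x).rho)

    def test_too_few_pairs_after_dropping(self):
        x = [Measurement(0.02, censored=True)] * 4 + [0.5]
        with pytest.raises(InsufficientDataError):
            spearman_censored(x, [1, 2, 3, 4, 5], censor_policy="drop_censored")


class TestDatasetSummaries:
    def test_pairwise_table_shape_and_methods(self):
        ds = generate_infusion_study(default_study_design(seed=5))
        table = pairwise_type_comparisons(ds, brew_time_min=5.0)
        assert len(table) == 10  # C(5, 2) type pairs
        assert (table["p_value"] <= 1).all() and (table["p_value"] >= 0).all()

    def test_group_summaries_recover_design_shape(self):
        ds = generate_infusion_study(default_study_design(seed=5))
        summaries = group_summaries(ds)
        assert len(summaries) == 15
        assert {s.product_type for s in summaries} == {"black", "green", "oolong", "herbal", "white"}
        assert sum(s.n_brands for s in summaries if s.brew_time_min == 5.0) == 16
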