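"""Metabolic identity closure and the NEP statistical machinery."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from crossflux.errors import InsufficientDataError
from crossflux.metabolism import (
    MetabolismTriplet,
    bartlett_test,
    close_flux_triplet,
    kruskal_wallis,
    nep_ttest,
    posthoc_rank_letters,
)


def brute_force_kruskal(groups):
    """Independent rank-based H with tie correction, written from the definition."""
    pooled = sorted(
        (v, name) for name, vals in groups.items() for v in vals
    )
    n = len(pooled)
    # average ranks for ties
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        avg_rank = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks.setdefault(pooled[k][1], []).append(avg_rank)
        i = j
    h = 0.0
    for name, vals in groups.items():
        r = sum(ranks[name])
        h += r * r / len(vals)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        ties += t**3 - t
        i = j
    correction = 1.0 - ties / (n**3 - n)
    return h / correction if correction > 0 else 0.0


class TestTripletClosure:
    def test_nep_from_gpp_and_respiration(self):
        out = close_flux_triplet(MetabolismTriplet(gpp=100.0, r_e=40.0))
        assert out.triplet.nep == 60.0 and "nep" in out.derived

    def test_chained_derivation_to_autotrophic_respiration(self):
        out = close_flux_triplet(MetabolismTriplet(gpp=100.0, npp=70.0, r_h=30.0))
        t = out.triplet
        assert t.nep == 40.0 and t.r_a == 30.0 and t.r_e == 60.0
        assert out.consistent

    def test_inconsistent_overdetermined_triplet_flagged(self):
        out = close_flux_triplet(MetabolismTriplet(gpp=100.0, r_e=40.0, nep=10.0))
        assert not out.consistent
        assert out.residuals["nep_gpp_re"] == pytest.approx(50.0)

    def test_identity_on_complete_consistent_triplet(self):
        t = MetabolismTriplet(gpp=100.0, r_e=40.0, nep=60.0, npp=70.0, r_a=30.0, r_h=10.0)
        out = close_flux_triplet(t)
        assert out.consistent and out.derived == () and out.triplet == t


class TestNEPTTest:
    def test_symmetric_sample_centered_at_zero(self):
        res = nep_ttest([-2.0, 2.0, -1.0, 1.0])
        assert res.mean == 0.0 and res.p_plus == 0.5
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_closed_form_ci_for_one_to_five(self):
        res = nep_ttest([1.0, 2.0, 3.0, 4.0, 5.0])
        sd = math.sqrt(2.5)
        half = stats.t.ppf(0.975, 4) * sd / math.sqrt(5)
        assert res.mean == 3.0
        assert res.ci_low == pytest.approx(3.0 - half, rel=1e-12)
        assert res.ci_high == pytest.approx(3.0 + half, rel=1e-12)
        assert res.p_plus == pytest.approx(stats.norm.cdf(3.0 / sd), rel=1e-12)

    def test_p_plus_uses_data_sd_not_standard_error(self):
        x = list(np.random.default_rng(0).normal(1.0, 2.0, size=400))
        res = nep_ttest(x)
        # with the data sd the probability is near Phi(0.5); with the se it
        # would be near 1
        assert res.p_plus == pytest.approx(stats.norm.cdf(res.mean / res.sd), rel=1e-12)
        assert res.p_plus < 0.8

    def test_degenerate_constant_sample(self):
        res = nep_ttest([5.0, 5.0, 5.0])
        assert res.degenerate and res.p_plus == 1.0
        res_neg = nep_ttest([-5.0, -5.0])
        assert res_neg.p_plus == 0.0

    def test_too_small_sample(self):
        with pytest.raises(InsufficientDataError):
            nep_ttest([1.0])


class TestBartlett:
    def test_identical_groups_statistic_zero(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res = bartlett_test(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_strongly_heterogeneous_variances_detected(self, rng):
        g = {
            "a": rng.normal(0, 1, size=50),
            "b": rng.normal(0, 10, size=50),
        }
        assert bartlett_test(g).p < 1e-3

    def test_small_groups_excluded_with_warning(self, caplog):
        g = {"a": [1.0, 2.0, 3.0], "b": [4.0], "c": [2.0, 5.0, 1.0]}
        with caplog.at_level("WARNING", logger="crossflux"):
            res = bartlett_test(g)
        assert res.excluded == ("b",) and res.k == 2


class TestKruskalWallis:
    def test_two_separated_triplets(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [101, 102, 103]})
        assert res.chi2 == pytest.approx(3.857, abs=1e-3)
        assert res.p == pytest.approx(0.0495, abs=1e-3)
        assert res.df == 1 and res.n_total == 6

    def test_matches_brute_force_on_small_fixtures(self, rng):
        for trial in range(30):
            k = int(rng.integers(2, 5))
            groups = {}
            n_total = 0
            for gi in range(k):
                n = int(rng.integers(2, 8))
                n_total += n
                # integer values force ties, exercising the tie correction
                groups[f"g{gi}"] = list(map(float, rng.integers(0, 6, size=n)))
            if n_total > 30:
                continue
            pooled = np.concatenate(list(groups.values()))
            if np.all(pooled == pooled[0]):
                continue
            ours = kruskal_wallis(groups).chi2
            assert ours == pytest.approx(brute_force_kruskal(groups), rel=1e-10)

    def test_identical_observations(self):
        res = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_empty_group_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="crossflux"):
            res = kruskal_wallis({"a": [1, 2, 3], "b": [], "c": [4, 5, 6]})
        assert res.df == 1


class TestPosthocLetters:
    def test_identical_groups_share_a_letter(self):
        letters = posthoc_rank_letters({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert letters == {"a": "a", "b": "a"}

    def test_single_group(self):
        assert posthoc_rank_letters({"only": [1, 2, 3]}) == {"only": "a"}

    def test_far_separated_groups_get_distinct_letters(self, rng):
        g1 = list(rng.normal(0, 1, size=30))
        g2 = list(rng.normal(100, 1, size=30))
        letters = posthoc_rank_letters({"low": g1, "high": g2})
        assert set(letters["low"]) & set(letters["high"]) == set()

    def test_three_groups_with_only_extremes_differing(self):
        # shift 6 puts adjacent mean-rank differences (~14) under the
        # Siegel-Castellan critical difference (16.15 for three groups of 30)
        # while the extremes (~28) cross it
        low = [float(v) for v in range(0, 30)]
        mid = [v + 6.0 for v in low]
        high = [v + 12.0 for v in low]
        groups = {"low": low, "mid": mid, "high": high}
        letters = posthoc_rank_letters(groups)
        assert letters == {"low": "a", "mid": "ab", "high": "b"}

    def test_letters_match_critical_difference_inequality(self, rng):
        """The sharing structure equals the hand-evaluated inequality."""
        groups = {
            "a": list(rng.normal(0, 1, 20)),
            "b": list(rng.normal(1, 1, 25)),
            "c": list(rng.normal(5, 1, 15)),
        }
        letters = posthoc_rank_letters(groups, family_alpha=0.05)
        pooled = np.concatenate([groups[k] for k in groups])
        ranks = stats.rankdata(pooled)
        mean_ranks, pos = {}, 0
        for k in groups:
            n = len(groups[k])
            mean_ranks[k] = ranks[pos : pos + n].mean()
            pos += n
        n_tot = len(pooled)
        z = stats.norm.ppf(1 - 0.05 / (3 * 2))
        for i, j in itertools.combinations(groups, 2):
            crit = z * math.sqrt(
                n_tot * (n_tot + 1) / 12 * (1 / len(groups[i]) + 1 / len(groups[j]))
            )
            significant = abs(mean_ranks[i] - mean_ranks[j]) >= crit
            share = bool(set(letters[i]) & set(letters[j]))
            assert share == (not significant)

    def test_partition_invariant_to_input_order(self, rng):
        samples = {
            "a": list(rng.normal(0, 1, 20)),
            "b": list(rng.normal(0.5, 1, 20)),
            "c": list(rng.normal(6, 1, 20)),
            "d": list(rng.normal(6.5, 1, 20)),
        }

        def sharing(letters):
            return {
                frozenset((i, j)): bool(set(letters[i]) & set(letters[j]))
                for i, j in itertools.combinations(sorted(letters), 2)
            }

        base = sharing(posthoc_rank_letters(samples))
        for perm in (["d", "b", "a", "c"], ["c", "a", "d", "b"]):
            permuted = {k: samples[k] for k in perm}
            assert sharing(posthoc_rank_letters(permuted)) == base
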