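"""ORA and pre-ranked GSEA against independent oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exobench import enrich
from exobench.simulate import ZScoreProfile
from exobench.model import MetabolitePathwaySets


def hypergeom_right_tail_exact(k, K, n, N):
    """Exact P(X >= k) by integer enumeration of the hypergeometric pmf."""
    numer = sum(comb(K, x) * comb(N - K, n - x)
                for x in range(k, min(K, n) + 1)
                if n - x <= N - K)
    return numer / comb(N, n)  # big-int division is correctly rounded


def es_oracle(scores, hit_ids, ids, weight=1):
    """Step-by-step running sum with exact rational arithmetic."""
    total = Fraction(sum(Fraction(abs(s)) ** weight
                         for s, i in zip(scores, ids) if i in hit_ids))
    n, nh = len(ids), len(hit_ids)
    running, best = Fraction(0), Fraction(0)
    for s, i in zip(scores, ids):
        if i in hit_ids:
            if total == 0:  # all-zero hit scores: equal weights
                running += Fraction(1, nh)
            else:
                running += Fraction(abs(s)) ** weight / total
        else:
            running -= Fraction(1, n - nh)
        if abs(running) > abs(best):
            best = running
    return float(best)


def make_profile(zs: dict, scenario="s") -> ZScoreProfile:
    return ZScoreProfile(scenario=scenario, zscores=zs, n_wt=10, n_ko=10)


class TestZScoreToPValue:
    @pytest.mark.parametrize(
        "z, p, tol",
        [
            (0.0, 0.5, 1e-12),
            (1.6449, 0.05, 1e-4),  # numerical inversion of the normal CDF
            (-3.0, 0.99865, 1e-5),  # standard normal table
        ],
    )
    def test_survival_function(self, z, p, tol):
        assert enrich.zscore_to_pvalue(z) == pytest.approx(p, abs=tol)


class TestFisherRightTail:
    def test_zero_hits_gives_one(self):
        assert enrich.fisher_right_tail(0, 5, 10, 20) == pytest.approx(1.0)

    def test_whole_background_in_pathway_gives_one(self):
        for k in range(0, 6):
            assert enrich.fisher_right_tail(k, 20, 5, 20) == pytest.approx(1.0)

    def test_hand_case_matches_pmf_enumeration(self):
        expected = hypergeom_right_tail_exact(3, 5, 10, 20)
        assert enrich.fisher_right_tail(3, 5, 10, 20) == pytest.approx(
            expected, abs=1e-14
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrich.fisher_right_tail(6, 5, 10, 20)
        with pytest.raises(ValueError):
            enrich.fisher_right_tail(1, 25, 10, 20)

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exact_enumeration(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert enrich.fisher_right_tail(k, K, n, N) == pytest.approx(
            hypergeom_right_tail_exact(k, K, n, N), abs=1e-12
        )


class TestEnrichmentScore:
    def _ranked(self, scores, ids):
        return enrich.RankedList(ids=tuple(ids), scores=tuple(scores),
                                 mode="signed")

    def test_single_top_member_scores_one(self):
        ranked = self._ranked([4.0, 3.0, 2.0, 1.0], "abcd")
        es, pos = enrich.enrichment_score(ranked, frozenset("a"))
        assert es == 1.0 and pos == 0

    def test_single_last_member_scores_minus_one(self):
        # running sum: -1/3, -2/3, -3/3, then +1 back to 0 -> extreme -1
        ranked = self._ranked([4.0, 3.0, 2.0, 1.0], "abcd")
        es, pos = enrich.enrichment_score(ranked, frozenset("d"))
        assert es == pytest.approx(-1.0) and pos == 2

    def test_two_of_five_matches_enumeration(self):
        scores, ids = [5.0, 4.0, 3.0, 2.0, 1.0], "abcde"
        ranked = self._ranked(scores, ids)
        es, _ = enrich.enrichment_score(ranked, frozenset("ab"))
        assert es == pytest.approx(es_oracle(scores, set("ab"), ids), abs=1e-12)

    @given(st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_random_small_lists_match_rational_oracle(self, data):
        n = data.draw(st.integers(2, 10))
        scores = sorted(
            data.draw(
                st.lists(
                    st.integers(-50, 50).map(lambda v: v / 10),
                    min_size=n, max_size=n,
                )
            ),
            reverse=True,
        )
        n_hits = data.draw(st.integers(1, n - 1))
        hits = frozenset(
            data.draw(
                st.permutations(range(n)).map(lambda p: tuple(p[:n_hits]))
            )
        )
        ids = tuple(str(i) for i in range(n))
        hit_ids = frozenset(str(i) for i in hits)
        ranked = self._ranked(scores, ids)
        es, _ = enrich.enrichment_score(ranked, hit_ids)
        assert es == pytest.approx(es_oracle(scores, hit_ids, ids), abs=1e-12)
        assert -1.0 <= es <= 1.0 + 1e-12

    def test_reversal_negates_es_for_symmetric_scores(self):
        scores = [3.0, 1.0, 0.0, -1.0, -3.0]
        ids = tuple("abcde")
        ranked = self._ranked(scores, ids)
        reversed_ranked = self._ranked(scores, ids[::-1])
        hit = frozenset("ab")
        es_f, _ = enrich.enrichment_score(ranked, hit)
        es_r, _ = enrich.enrichment_score(reversed_ranked, hit)
        assert es_f == pytest.approx(-es_r)

    def test_agrees_with_gseapy_prerank(self):
        """Independent cross-check against the reference GSEA implementation."""
        import pandas as pd
        import gseapy

        scores = [5.0, 4.2, 3.1, 2.5, 1.9, 1.2, 0.7, -0.4, -1.1, -2.3]
        ids = [f"m{i}" for i in range(10)]
        members = ["m0", "m2", "m5"]
        rnk = pd.DataFrame({"gene": ids, "score": scores})
        ref = gseapy.prerank(rnk=rnk, gene_sets={"P": members},
                             permutation_num=10, min_size=1, max_size=50,
                             seed=1, weight=1.0, outdir=None, no_plot=True)
        expected = float(ref.res2d.loc[0, "ES"])
        es, _ = enrich.enrichment_score(
            self._ranked(scores, ids), frozenset(members))
        assert es == pytest.approx(expected, abs=1e-9)

    def test_full_coverage_rejected(self):
        ranked = self._ranked([2.0, 1.0], "ab")
        with pytest.raises(ValueError):
            enrich.enrichment_score(ranked, frozenset("ab"))


class TestRankedList:
    def test_tie_stable_secondary_sort_by_id(self):
        profile = make_profile({"b": 1.0, "a": 1.0, "c": 2.0})
        ranked = enrich.RankedList.from_profile(profile, "signed")
        assert ranked.ids == ("c", "a", "b")

    def test_absolute_mode_folds_signs(self):
        profile = make_profile({"a": -3.0, "b": 2.0, "c": 1.0})
        ranked = enrich.RankedList.from_profile(profile, "absolute")
        assert ranked.ids == ("a", "b", "c")
        assert ranked.scores == (3.0, 2.0, 1.0)


class TestRunOra:
    def _sets(self, mapping):
        return MetabolitePathwaySets(
            {k: frozenset(v) for k, v in mapping.items()}, include_side=True
        )

    def test_too_few_da_metabolites_means_nothing_testable(self):
        profile = make_profile({"a": 3.0, "b": 3.0, "c": 0.0, "d": 0.0})
        sets = self._sets({"P": "abcd"})
        res = enrich.run_ora(profile, sets, frozenset("abcd"))
        assert not res.per_pathway["P"].testable
        assert res.per_pathway["P"].n_hits == 2
        assert res.per_pathway["P"].p_value is None

    def test_survival_function_direction(self):
        # decreased metabolites (negative z) can never be DA by default
        profile = make_profile({m: -5.0 for m in "abc"} | {"d": 0.0})
        sets = self._sets({"P": "abc"})
        res = enrich.run_ora(profile, sets, frozenset("abcd"))
        assert res.per_pathway["P"].n_hits == 0
        res_abs = enrich.run_ora(
            profile, sets, frozenset("abcd"), da_stat="abs"
        )
        assert res_abs.per_pathway["P"].n_hits == 3

    def test_hypergeometric_table_construction(self):
        # DA = {a,b,c}; P: K=4, k=3 of n=3 from N=9
        zs = {m: 3.0 for m in "abc"} | {m: 0.0 for m in "defghi"}
        sets = self._sets({"P": "abcd", "Q": "ghi"})
        res = enrich.run_ora(make_profile(zs), sets, frozenset("abcdefghi"))
        expected = hypergeom_right_tail_exact(3, 4, 3, 9)
        assert res.per_pathway["P"].p_value == pytest.approx(expected)
        assert not res.per_pathway["Q"].testable

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            enrich.run_ora(make_profile({"a": 1.0}), self._sets({"P": "a"}),
                           frozenset())


class TestRunGsea:
    def _sets(self, mapping):
        return MetabolitePathwaySets(
            {k: frozenset(v) for k, v in mapping.items()}, include_side=True
        )

    def test_top_members_are_significant(self):
        rng = np.random.default_rng(0)
        zs = {f"m{i}": float(z) for i, z in enumerate(rng.normal(size=97))}
        zs |= {"a": 9.0, "b": 8.5, "c": 8.0}
        res = enrich.run_gsea(make_profile(zs), self._sets({"P": "abc"}),
                              mode="absolute", n_perm=1000, seed=1)
        assert res.per_pathway["P"].p_value <= 0.05

    def test_degenerate_equal_scores_do_not_crash(self):
        zs = {f"m{i}": 1.0 for i in range(10)}
        res = enrich.run_gsea(make_profile(zs),
                              self._sets({"P": ["m0", "m1", "m2"]}),
                              mode="signed", n_perm=200, seed=2)
        rec = res.per_pathway["P"]
        assert rec.testable and 0.0 < rec.p_value <= 1.0

    def test_no_ranked_member_is_non_testable(self):
        zs = {"a": 1.0, "b": 0.5}
        res = enrich.run_gsea(make_profile(zs), self._sets({"P": ["x", "y"]}),
                              mode="signed", n_perm=100, seed=3)
        assert not res.per_pathway["P"].testable

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        zs = {f"m{i}": float(z) for i, z in enumerate(rng.normal(size=30))}
        sets = self._sets({"P": ["m1", "m2", "m3"], "Q": ["m4", "m5"]})
        r1 = enrich.run_gsea(make_profile(zs), sets, n_perm=300, seed=5)
        r2 = enrich.run_gsea(make_profile(zs), sets, n_perm=300, seed=5)
        assert r1.per_pathway == r2.per_pathway

    def test_split_sign_pathway_detected_only_in_absolute_mode(self):
        # half the members push up, half push down: signed ranking scatters
        # them to both ends and cancels the enrichment score
        rng = np.random.default_rng(6)
        zs = {f"m{i}": float(z) for i, z in enumerate(rng.normal(0, 0.3, 60))}
        members = [f"p{i}" for i in range(8)]
        zs |= {m: 3.0 if i % 2 == 0 else -3.0 for i, m in enumerate(members)}
        profile = make_profile(zs)
        sets = self._sets({"P": members})
        p_abs = enrich.run_gsea(profile, sets, mode="absolute",
                                n_perm=500, seed=7).per_pathway["P"].p_value
        p_signed = enrich.run_gsea(profile, sets, mode="signed",
                                   n_perm=500, seed=7).per_pathway["P"].p_value
        assert p_abs < p_signed
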