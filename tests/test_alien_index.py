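import math
from decimal import Decimal, getcontext

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amoebascan.alien_index import (AlienIndexResult, alien_index,
                                    best_hits_by_group, call_lgt,
                                    score_genes, summarize_lgt)
from amoebascan.gene_taxonomy import TaxonomicCall
from amoebascan.io_formats import GeneModel, HitRecord, SampleDetectionTable

AI_BOUND = 200 * math.log(10) + math.log1p(1e-200)


def decimal_ai(br: float, bd: float, c: float = 1e-200) -> float:
    """High-precision reference evaluation of the Alien Index."""
    getcontext().prec = 50
    return float((Decimal(br) + Decimal(c)).ln()
                 - (Decimal(bd) + Decimal(c)).ln())


def _hit(sk, ev, bits=100.0, subject="s", lineage_tail=("PhylumX",)):
    return HitRecord("g1", subject, 80.0, 100, ev, bits,
                     (sk, *lineage_tail))


class TestAlienIndexFormula:
    def test_symmetric_inputs_give_zero(self):
        assert alien_index(1e-10, 1e-10) == 0.0

    def test_25_decades_of_separation(self):
        # ln(1e-5 + c) - ln(1e-30 + c) ~ 25 ln 10
        expected = decimal_ai(1e-5, 1e-30)
        assert math.isclose(alien_index(1e-5, 1e-30), expected, rel_tol=1e-12)
        assert math.isclose(expected, 25 * math.log(10), rel_tol=1e-9)

    def test_extreme_pair_attains_bound(self):
        assert math.isclose(alien_index(1.0, 0.0), AI_BOUND, rel_tol=0)
        assert math.isclose(alien_index(0.0, 1.0), -AI_BOUND, rel_tol=0)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.5, 1.5), (2.0, 0.0)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            alien_index(*bad)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_antisymmetry_and_bound(self, a, b):
        assert alien_index(a, b) == -alien_index(b, a)
        assert abs(alien_index(a, b)) <= AI_BOUND

    def test_monotone_in_both_arguments(self):
        # ai falls as the recipient hit strengthens, rises as donor does
        assert alien_index(1e-8, 1e-30) < alien_index(1e-5, 1e-30)
        assert alien_index(1e-5, 1e-40) > alien_index(1e-5, 1e-30)


class TestBestHitsByGroup:
    def test_minimum_per_group(self):
        hits = [_hit("Eukaryota", 1e-5), _hit("Eukaryota", 1e-8),
                _hit("Bacteria", 1e-40)]
        assert best_hits_by_group(hits) == (1e-8, 1e-40)

    def test_absent_group_defaults_to_one(self):
        assert best_hits_by_group([_hit("Bacteria", 1e-40)]) == (1.0, 1e-40)
        assert best_hits_by_group([]) == (1.0, 1.0)

    def test_exclude_lineage_self_hit_guard(self):
        hits = [_hit("Eukaryota", 1e-50, lineage_tail=("Amoebozoa",)),
                _hit("Viruses", 1e-20)]
        bbh_r, bbh_d = best_hits_by_group(hits, exclude_lineage="Amoebozoa")
        assert bbh_r == 1.0 and bbh_d == 1e-20

    def test_evalues_clamped_to_one(self):
        assert best_hits_by_group([_hit("Eukaryota", 3.0)]) == (1.0, 1.0)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            best_hits_by_group([], recipient_group={"Eukaryota"},
                               donor_group={"Eukaryota", "Bacteria"})


class TestCallLgt:
    def _res(self, ai):
        return AlienIndexResult("g1", 1.0, 1.0, ai)

    def test_threshold_boundary_inclusive(self):
        assert call_lgt([self._res(45.0)])[0].is_candidate
        assert not call_lgt([self._res(44.999)])[0].is_candidate

    def test_exclusive_comparator_option(self):
        assert not call_lgt([self._res(45.0)], inclusive=False)[0].is_candidate

    def test_candidate_set_monotone_in_threshold(self):
        results = [self._res(ai) for ai in (-10.0, 20.0, 45.0, 100.0, 400.0)]
        previous = None
        for threshold in (0.0, 45.0, 100.0, 500.0):
            called = {r.gene_id for r in call_lgt(results, threshold)
                      for r in [r] if r.is_candidate}
            n = sum(r.is_candidate for r in call_lgt(results, threshold))
            if previous is not None:
                assert n <= previous
            previous = n


class TestSummarizeLgt:
    def _setup(self, n_group=10, n_cand=4):
        calls, results = [], []
        for i in range(n_group):
            gid = f"g{i}"
            bh = HitRecord(gid, "s", 80.0, 100, 1e-30, 100.0,
                           ("Bacteria", "Proteobacteria"))
            calls.append(TaxonomicCall(gid, "bacteria", bh))
            is_cand = i < n_cand
            results.append(AlienIndexResult(
                gid, 1.0, 1e-60 if is_cand else 1e-3,
                ai=100.0 if is_cand else 5.0, is_candidate=is_cand,
                donor_superkingdom="Bacteria",
                donor_phylum="Proteobacteria"))
        return results, calls

    def test_headline_fraction_546_of_5210(self):
        results, calls = self._setup(n_group=5210, n_cand=546)
        summary = summarize_lgt(results, calls)
        assert summary.n_group_matching == 5210
        assert summary.n_candidates == 546
        assert math.isclose(summary.fraction, 0.10479846449136276,
                            rel_tol=1e-12)

    def test_all_single_exon_candidates_have_no_introns(self):
        results, calls = self._setup()
        models = [GeneModel(f"g{i}", "s1", 1, 500, "+", exon_count=1)
                  for i in range(10)]
        assert summarize_lgt(results, calls, models).fraction_with_introns == 0

    def test_intron_fraction_counts_multi_exon_candidates(self):
        results, calls = self._setup(n_group=4, n_cand=4)
        models = [GeneModel(f"g{i}", "s1", 1, 500, "+",
                            exon_count=3 if i < 2 else 1) for i in range(4)]
        assert summarize_lgt(results, calls, models).fraction_with_introns \
            == 0.5

    def test_unjoinable_ids_warn_and_are_excluded(self):
        results, calls = self._setup(n_group=4, n_cand=2)
        models = [GeneModel("g0", "s1", 1, 500, "+", exon_count=2)]
        with pytest.warns(UserWarning, match="missing from gene models"):
            summary = summarize_lgt(results, calls, models)
        assert summary.fraction_with_introns == 1.0  # only g0 joinable

    def test_expression_counted_at_detection_min(self):
        results, calls = self._setup(n_group=4, n_cand=3)
        detection = SampleDetectionTable(
            {("g0", "YT48"): 5.0, ("g1", "YT48"): 0.5, ("g5", "YT48"): 9.0},
            {"YT48": "large"})
        summary = summarize_lgt(results, calls, detection=detection)
        assert summary.n_expressed == 1  # g1 below min, g5 not a candidate

    def test_donor_phylum_distribution_sums_to_one(self):
        results, calls = self._setup()
        dist = summarize_lgt(results, calls).donor_phylum_distribution
        assert math.isclose(sum(dist.values()), 1.0, rel_tol=1e-9)


class TestPlantedRecovery:
    def test_calls_match_generator_truth(self, default_bundle):
        from amoebascan.io_formats import hits_by_query
        b = default_bundle
        grouped = hits_by_query(b.gene_hits)
        ids = [m.gene_id for m in b.gene_models]
        results = call_lgt(score_genes({g: grouped.get(g, ()) for g in ids}))
        called = {r.gene_id for r in results if r.is_candidate}
        truth = set(b.truth.genes.loc[b.truth.genes.is_lgt, "gene_id"])
        assert called == truth

    def test_donor_phylum_attribution_matches_truth(self, default_bundle):
        from amoebascan.io_formats import hits_by_query
        b = default_bundle
        grouped = hits_by_query(b.gene_hits)
        truth = b.truth.genes.set_index("gene_id")
        results = call_lgt(score_genes(
            {g: grouped.get(g, ()) for g in grouped}))
        for r in results:
            if r.is_candidate:
                assert r.donor_phylum == truth.loc[r.gene_id, "donor_phylum"]
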