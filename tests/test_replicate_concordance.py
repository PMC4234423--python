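"""Replicate concordance, discordance triage and the contingency test."""

import numpy as np
import pytest

from ampliqc import datasets
from ampliqc.io_formats import AmpliQCError, VariantCall
from ampliqc.replicate_concordance import (
    Replicate,
    SiteEvidence,
    allele_fraction_difference,
    build_group,
    classify_discordance,
    genotype_concordance,
    singleton_vs_duplicate_test,
    total_allele_calls,
)


def _call(pos, sample="S", alt="T", genotype="het", ref_depth=250,
          alt_depth=250):
    return VariantCall(sample=sample, chrom="chr1", pos=pos, ref="A",
                       alt=alt, genotype=genotype, ref_depth=ref_depth,
                       alt_depth=alt_depth)


class TestBuildGroup:
    def test_identical_call_sets(self):
        calls = [_call(p) for p in (10, 20, 30)]
        g = build_group("S", [Replicate("r1", calls), Replicate("r2", calls)])
        assert g.union_count == g.intersect_count == 3
        assert g.concordant == 3 and g.discordant == 0

    def test_disjoint_call_sets(self):
        g = build_group("S", [Replicate("r1", [_call(10)]),
                              Replicate("r2", [_call(20)])])
        assert g.union_count == 2 and g.intersect_count == 0

    def test_genotype_discordance_counted(self):
        a = [_call(10), _call(20)]
        b = [_call(10), _call(20, genotype="hom_alt", ref_depth=10,
                              alt_depth=490)]
        g = build_group("S", [Replicate("r1", a), Replicate("r2", b)])
        assert g.intersect_count == 2 and g.discordant == 1
        assert g.discordant_sites == [("chr1", 20, "A", "T")]

    def test_low_depth_calls_leave_the_universe(self):
        a = [_call(10, ref_depth=5, alt_depth=4)]  # depth 9 < 20
        g = build_group("S", [Replicate("r1", a), Replicate("r2", [])])
        assert g.union_count == 0

    def test_same_position_different_alt_is_two_sites(self):
        g = build_group("S", [Replicate("r1", [_call(10, alt="T")]),
                              Replicate("r2", [_call(10, alt="G")])])
        assert g.union_count == 2 and g.intersect_count == 0

    def test_indel_bookkeeping(self):
        ind = _call(10, alt="TT")
        g = build_group("S", [Replicate("r1", [ind, _call(20)]),
                              Replicate("r2", [ind])])
        assert g.union_indels == 1 and g.intersect_indels == 1

    def test_needs_two_replicates(self):
        with pytest.raises(AmpliQCError):
            build_group("S", [Replicate("r1", [_call(10)])])

    def test_set_algebra_matches_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            sets = []
            for _r in range(int(rng.integers(2, 5))):
                positions = rng.choice(50, size=rng.integers(0, 12),
                                       replace=False)
                sets.append([_call(int(p) + 1) for p in positions])
            g = build_group("S", [Replicate(f"r{i}", cs)
                                  for i, cs in enumerate(sets)])
            keys = [{c.key for c in cs} for cs in sets]
            assert g.union_count == len(set().union(*keys))
            assert g.intersect_count == len(set.intersection(*keys))


class TestClassifyDiscordance:
    EV_OK = {"r1": SiteEvidence(500, 250, True),
             "r2": SiteEvidence(400, 8, False)}

    def test_low_coverage_wins_first(self):
        ev = {"r1": SiteEvidence(500, 250, True),
              "r2": SiteEvidence(12, 0, False)}
        # context is also a repeat: the coverage rule still wins
        r = classify_discordance(ev, "chr1", 10, "AAAAAAAAA")
        assert r.category == "coverage_issue"

    @pytest.mark.parametrize("context,expected", [
        ("AAAAAA", "repeat_region"),        # homopolymer >= 5
        ("GGACACACACGG", "repeat_region"),  # dinucleotide x >= 4 units
        ("GATTACAGT", "allelic_ratio"),     # no repeat: fallthrough
        ("AAAAGTTT", "allelic_ratio"),      # runs of 4 are below threshold
    ])
    def test_repeat_scanner(self, context, expected):
        r = classify_discordance(self.EV_OK, "chr1", 10, context,
                                 site_index=len(context) // 2)
        assert r.category == expected

    def test_allelic_ratio_fallthrough(self):
        ev = {"r1": SiteEvidence(400, 180, True),
              "r2": SiteEvidence(380, 8, False)}
        assert classify_discordance(ev, "chr1", 10,
                                    "GATC").category == "allelic_ratio"

    def test_replicate_order_is_irrelevant(self):
        ev = dict(self.EV_OK)
        r1 = classify_discordance(ev, "chr1", 10, "GATTACA")
        r2 = classify_discordance(dict(reversed(list(ev.items()))),
                                  "chr1", 10, "GATTACA")
        assert r1.category == r2.category

    def test_missing_depth_is_an_error(self):
        ev = {"r1": SiteEvidence(None, 0, False)}
        with pytest.raises(AmpliQCError, match="missing depth"):
            classify_discordance(ev, "chr1", 10, "GATC")


class TestTotalAlleleCalls:
    def test_bundled_dataset(self):
        assert total_allele_calls(datasets.load_replicate_snp_counts()) == 1228

    def test_single_group(self):
        (g,) = [g for g in datasets.load_replicate_snp_counts()
                if g.n_replicates == 2]
        assert g.union_count * 2 == total_allele_calls([g])

    def test_empty(self):
        assert total_allele_calls([]) == 0


class TestChiSquared:
    def test_study_counts_not_significant(self):
        res = singleton_vs_duplicate_test(33, 305, 21, 232)
        assert res.p_value > 0.05

    def test_identical_proportions(self):
        res = singleton_vs_duplicate_test(10, 100, 10, 100)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_statistic(self):
        # 2x2 table (50,50 / 0,100): expected fails 25 each
        res = singleton_vs_duplicate_test(50, 100, 0, 100)
        o = np.array([[50, 50], [0, 100]], dtype=float)
        row, col = o.sum(1, keepdims=True), o.sum(0, keepdims=True)
        e = row * col / o.sum()
        assert res.statistic == pytest.approx(((o - e) ** 2 / e).sum())

    def test_input_validation(self):
        with pytest.raises(AmpliQCError):
            singleton_vs_duplicate_test(5, 0, 1, 10)
        with pytest.raises(AmpliQCError):
            singleton_vs_duplicate_test(11, 10, 1, 10)


class TestPairwiseComparisons:
    def test_identical_sets_fully_concordant(self):
        calls = [_call(p) for p in (10, 20)]
        keys = [c.key for c in calls]
        assert genotype_concordance(calls, calls, keys) == 1.0
        assert allele_fraction_difference(calls, calls, keys) == (0.0, 0.0)

    def test_nineteen_of_twenty(self):
        a = [_call(p) for p in range(1, 21)]
        b = a[:-1] + [_call(20, genotype="hom_alt", ref_depth=1,
                            alt_depth=499)]
        assert genotype_concordance(a, b, [c.key for c in a]) == 0.95

    def test_one_percent_af_shift(self):
        a = [_call(10, ref_depth=50, alt_depth=50)]
        b = [_call(10, ref_depth=51, alt_depth=49)]
        mean, _ = allele_fraction_difference(a, b, [a[0].key])
        assert mean == pytest.approx(0.01)

    def test_empty_shared_sites_error(self):
        with pytest.raises(AmpliQCError):
            genotype_concordance([], [], [])
        with pytest.raises(AmpliQCError):
            allele_fraction_difference([], [], [])

    def test_af_difference_matches_half_normal_expectation(self):
        # two binomial replicates at depth 500, AF 0.5:
        # AF_a - AF_b ~ N(0, 2 * 0.25 / 500), E|diff| = sigma * sqrt(2/pi)
        rng = np.random.default_rng(77)
        n, depth = 2000, 500
        a, b, keys = [], [], []
        for i in range(n):
            xa, xb = rng.binomial(depth, 0.5, 2)
            a.append(_call(i + 1, ref_depth=depth - xa, alt_depth=xa))
            b.append(_call(i + 1, ref_depth=depth - xb, alt_depth=xb))
            keys.append(a[-1].key)
        mean, sd = allele_fraction_difference(a, b, keys)
        sigma = np.sqrt(2 * 0.25 / depth)
        expect = sigma * np.sqrt(2 / np.pi)
        se = sigma * np.sqrt((1 - 2 / np.pi) / n)
        assert abs(mean - expect) < 3 * se

    def test_clean_replicates_fully_concordant_without_caller_minimum(self):
        # deep clean replicates disagree only through the caller threshold;
        # with the minimum at zero every site is called in both
        from ampliqc.synthetic_data import (SimulationParams, generate_panel,
                                            simulate_depth, inject_variants)
        p = SimulationParams(seed=21, n_genes=1, amplicons_per_gene=4,
                             n_samples=2, noise_sd=0, amplicon_effect_sd=0,
                             sample_scale_sd=0, sample_depth_scale=500,
                             min_alt_reads=0, min_alt_frac=0.0)
        panel, _ = generate_panel(p)
        tracks, truth = simulate_depth(panel, p.sample_names, p)
        a = panel[0]
        sites = []
        for pos in range(a.region.start + 160, a.region.start + 200):
            for s in p.sample_names:
                sites.append((s, a.region.chrom, pos, "A", "T", "het"))
        calls, _ = inject_variants(panel, p.sample_names, p, tracks,
                                   truth, sites=sites)
        by = {}
        for c in calls:
            by.setdefault(c.sample, []).append(c)
        g = build_group("S", [Replicate(s, cs) for s, cs in sorted(by.items())])
        assert g.union_count == g.intersect_count == 40
        assert g.discordant == 0
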