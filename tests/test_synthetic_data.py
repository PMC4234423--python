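"""Simulator structure: determinism, panel geometry, depth/qPCR/variant
statistics, and recovery of the configured parameters."""

import numpy as np
import pytest

from ampliqc.coverage_qc import per_sample_stats
from ampliqc.io_formats import AmpliQCError, merge_regions, union_length
from ampliqc.reproducibility import (
    assay_mean_coverage,
    correlation_matrix,
    dropout_rate,
    summarize_matrix,
)
from ampliqc.synthetic_data import (
    SimulationParams,
    TruthSet,
    generate_panel,
    inject_variants,
    sample_amplicon_lengths,
    simulate_all,
    simulate_depth,
    simulate_qpcr,
    simulate_sample_metrics,
)


class TestDeterminism:
    def test_identical_params_identical_outputs(self, small_params, bundle):
        again = simulate_all(SimulationParams(**vars(small_params)))
        assert again.panel == bundle.panel
        assert again.wells == bundle.wells
        assert again.calls == bundle.calls
        assert again.truth.variants == bundle.truth.variants
        for a, b in zip(again.tracks, bundle.tracks):
            assert list(a.items()) == list(b.items())

    def test_params_round_trip(self, small_params):
        d = small_params.to_dict()
        assert SimulationParams.from_dict(d) == small_params


class TestPanel:
    def test_counts_and_length_bounds(self):
        p = SimulationParams(seed=1, n_genes=2, amplicons_per_gene=3)
        panel, exons = generate_panel(p)
        assert len(panel) == 6
        lo, hi = p.amplicon_length_bounds
        assert all(lo <= a.length <= hi for a in panel)

    def test_no_tiling_means_no_overlap(self):
        p = SimulationParams(seed=2, n_genes=2, amplicons_per_gene=8,
                             tiling_fraction=0.0)
        panel, _ = generate_panel(p)
        assert all(a.tiling_group is None for a in panel)
        regions = [a.region for a in panel]
        assert union_length(regions) == sum(r.length for r in regions)

    def test_tiling_amplicons_overlap_their_group_partner(self):
        p = SimulationParams(seed=3, n_genes=1, amplicons_per_gene=10,
                             tiling_fraction=0.4)
        panel, _ = generate_panel(p)
        groups = {}
        for a in panel:
            if a.tiling_group:
                groups.setdefault(a.tiling_group, []).append(a)
        assert groups, "tiling requested but none generated"
        for members in groups.values():
            assert len(members) == 2
            assert union_length([m.region for m in members]) < \
                sum(m.length for m in members)

    def test_exons_inside_amplicon_union(self):
        p = SimulationParams(seed=4, n_genes=2, amplicons_per_gene=5)
        panel, exons = generate_panel(p)
        union = merge_regions(a.region for a in panel)
        for e in exons:
            assert any(u.chrom == e.chrom and u.start <= e.start
                       and e.end <= u.end for u in union)

    def test_length_sampler_hits_configured_mean(self):
        p = SimulationParams(seed=5)
        rng = np.random.default_rng(5)
        lengths = sample_amplicon_lengths(p, 10_000, rng)
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - p.amplicon_length_mean) < 3 * se

    def test_incompatible_mean_rejected(self):
        with pytest.raises(AmpliQCError):
            SimulationParams(amplicon_length_mean=200.0).validate()


class TestDepth:
    def test_deleted_pair_has_near_zero_depth(self, bundle, small_params):
        cov = assay_mean_coverage(bundle.tracks, bundle.panel)
        sample, assay = small_params.deletion_assays[0]
        assert cov[(sample, assay)] < 2
        for s in bundle.samples:
            if s != sample:
                assert cov[(s, assay)] > 20

    def test_degenerate_noise_gives_flat_interiors(self):
        p = SimulationParams(seed=6, n_genes=1, amplicons_per_gene=3,
                             n_samples=2, amplicon_effect_sd=0, noise_sd=0,
                             sample_scale_sd=0, tiling_fraction=0)
        panel, _ = generate_panel(p)
        tracks, _ = simulate_depth(panel, p.sample_names, p)
        for t in tracks:
            for a in panel:
                interior = [(a.region.chrom, pos) for pos in
                            range(a.region.start + 1 + p.read_length,
                                  a.region.end - p.read_length)]
                vals = t.values_at(interior)
                assert len(set(vals)) == 1
                assert vals[0] == round(p.sample_depth_scale)

    def test_unknown_deletion_sample_rejected(self):
        p = SimulationParams(seed=7, n_genes=1, amplicons_per_gene=2,
                             n_samples=2,
                             deletion_assays=[("nope", "GENE01-1")])
        panel, _ = generate_panel(p)
        with pytest.raises(AmpliQCError, match="unknown sample"):
            simulate_depth(panel, p.sample_names, p)

    def test_sample_scale_ratios_recoverable(self):
        p = SimulationParams(seed=8, n_genes=2, amplicons_per_gene=6,
                             n_samples=4, noise_sd=0.05)
        panel, _ = generate_panel(p)
        tracks, truth = simulate_depth(panel, p.sample_names, p)
        regions = [a.region for a in panel]
        means = {t.sample: per_sample_stats(t, regions).mean_cov
                 for t in tracks}
        truth_ratio = truth.sample_scale["S01"] / truth.sample_scale["S02"]
        est_ratio = means["S01"] / means["S02"]
        assert est_ratio == pytest.approx(truth_ratio, rel=0.1)

    def test_shared_efficiency_raises_correlation(self):
        # mean pairwise Spearman under strong shared amplicon effects
        # exceeds that under weak ones (20 replicates, one-sided)
        def mean_rho(effect_sd, seed):
            p = SimulationParams(seed=seed, n_genes=1, amplicons_per_gene=8,
                                 n_samples=3, amplicon_effect_sd=effect_sd)
            panel, _ = generate_panel(p)
            tracks, _ = simulate_depth(panel, p.sample_names, p)
            m = correlation_matrix(tracks, [a.region for a in panel])
            return summarize_matrix(m).mean

        weak = [mean_rho(0.1, s) for s in range(20)]
        strong = [mean_rho(0.6, 100 + s) for s in range(20)]
        assert np.mean(strong) > np.mean(weak)


class TestQpcr:
    def _flat_truth(self, panel, samples, p):
        return TruthSet(amplicon_efficiency={a.assay_id: 1.0 for a in panel},
                        sample_scale={s: p.sample_depth_scale
                                      for s in samples})

    def test_deleted_pair_reads_the_sentinel(self, bundle, small_params):
        sample, assay = small_params.deletion_assays[0]
        wells = [w for w in bundle.wells
                 if (w.sample, w.assay_id) == (sample, assay)]
        assert wells and all(w.cq == 40.0 and w.endpoint_fluorescence == 0.0
                             for w in wells)

    def test_no_dropout_means_all_amplify(self):
        p = SimulationParams(seed=9, n_genes=1, amplicons_per_gene=10,
                             n_samples=4, dropout_rate=0.0)
        panel, _ = generate_panel(p)
        wells = simulate_qpcr(panel, p.sample_names, p,
                              self._flat_truth(panel, p.sample_names, p))
        assert all(w.cq <= 29 for w in wells)

    def test_dropout_rate_recovered(self):
        p = SimulationParams(seed=10, n_genes=4, amplicons_per_gene=25,
                             n_samples=50, dropout_rate=0.0116)
        panel, _ = generate_panel(p)
        wells = simulate_qpcr(panel, p.sample_names, p,
                              self._flat_truth(panel, p.sample_names, p))
        n = len(wells)
        assert n == 100 * 50 * p.n_qpcr_replicates
        se = np.sqrt(p.dropout_rate * (1 - p.dropout_rate) / n)
        assert abs(dropout_rate(wells) - p.dropout_rate) < 3 * se


class TestVariants:
    def test_het_allele_fraction_centred_on_half(self):
        p = SimulationParams(seed=11, n_genes=1, amplicons_per_gene=4,
                             n_samples=2, noise_sd=0, amplicon_effect_sd=0,
                             sample_scale_sd=0, sample_depth_scale=500,
                             n_variants=2000, hom_fraction=0.0,
                             indel_fraction=0.0)
        panel, _ = generate_panel(p)
        tracks, truth = simulate_depth(panel, p.sample_names, p)
        calls, _ = inject_variants(panel, p.sample_names, p, tracks, truth)
        afs = np.array([c.allele_fraction for c in calls])
        se = afs.std(ddof=1) / np.sqrt(len(afs))
        assert abs(afs.mean() - 0.5) < 3 * se

    def test_hom_site_has_near_zero_ref_depth(self):
        p = SimulationParams(seed=12, n_genes=1, amplicons_per_gene=2,
                             n_samples=1, noise_sd=0, amplicon_effect_sd=0,
                             sample_scale_sd=0, sample_depth_scale=910,
                             tiling_fraction=0)
        panel, _ = generate_panel(p)
        tracks, truth = simulate_depth(panel, p.sample_names, p)
        a = panel[0]
        site = [("S01", a.region.chrom, a.region.start + 200, "C", "T",
                 "hom_alt")]
        (call,), _ = inject_variants(panel, p.sample_names, p, tracks,
                                     truth, sites=site)
        assert call.genotype == "hom_alt"
        assert call.ref_depth < 0.1 * call.site_depth

    def test_zero_depth_site_never_emitted(self, bundle, small_params):
        sample, assay = small_params.deletion_assays[0]
        amp = next(a for a in bundle.panel if a.assay_id == assay)
        deep_zero = [(sample, amp.region.chrom,
                      (amp.region.start + amp.region.end) // 2, "A", "T",
                      "het")]
        # stray depth can be nonzero; force an exactly-zero base
        track = next(t for t in bundle.tracks if t.sample == sample)
        pos = next(p for p in amp.region.positions()
                   if track.depth(amp.region.chrom, p) == 0)
        site = [(sample, amp.region.chrom, pos, "A", "T", "het")]
        calls, _ = inject_variants(bundle.panel, bundle.samples,
                                   small_params, bundle.tracks, sites=site)
        assert calls == []

    def test_site_outside_panel_rejected(self, bundle, small_params):
        with pytest.raises(AmpliQCError, match="outside panel"):
            inject_variants(bundle.panel, bundle.samples, small_params,
                            bundle.tracks,
                            sites=[("S01", "chrZ", 5, "A", "T", "het")])

    def test_truth_records_every_planted_variant(self, bundle, small_params):
        assert len(bundle.truth.variants) == small_params.n_variants
        assert len(bundle.calls) <= small_params.n_variants


class TestSampleMetrics:
    def test_duplicate_rate_recovered(self):
        p = SimulationParams(seed=13, n_genes=2, amplicons_per_gene=6,
                             n_samples=12)
        panel, exons = generate_panel(p)
        tracks, _ = simulate_depth(panel, p.sample_names, p)
        rows = simulate_sample_metrics(panel, exons, p.sample_names, p,
                                       tracks)
        dup = np.array([r.duplicate_frac for r in rows])
        assert abs(dup.mean() - p.duplicate_rate) < 0.02

    def test_coverage_columns_match_direct_statistics(self, bundle):
        row = bundle.metrics[0]
        regions = [a.region for a in bundle.panel]
        s = per_sample_stats(bundle.tracks[0], regions)
        assert row.amplicon_mean_cov == pytest.approx(s.mean_cov)
        assert row.amplicon_sd_cov == pytest.approx(s.sd_cov)
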