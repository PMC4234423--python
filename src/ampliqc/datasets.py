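"""Bundled validation dataset: a nanowell qPCR target-enrichment study.

These small tables come from a published proof-of-concept resequencing
of 16 cancer genes in NCI-60 cell lines on a nanowell singleplex-PCR
capture platform: the per-gene panel accounting, per-sample library
metrics, the 23-sample coverage-correlation matrix, the 25 catalogued
mutations with their rediscovery evidence, the PTEN-4 qPCR/coverage
table used for homozygous-deletion calling, and the technical-replicate
SNP concordance counts. They are the acceptance surface for the
pipeline's summary operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import (
    KnownMutation,
    QpcrWell,
    SampleMetricsRow,
    VariantCall,
    read_matrix_tsv,
    read_mutation_table,
    read_sample_metrics,
)
from .panel_accounting import PanelGeneRow
from .replicate_concordance import ConcordanceGroup
from .reproducibility import CorrelationMatrix
from .variant_validation import DeletionCall, detect_deletion

_DATA = resources.files("ampliqc") / "data"


def _path(name: str):
    return _DATA / name


def load_panel_gene_table() -> list[PanelGeneRow]:
    """Per-gene exon/target/assay/capture accounting (16 genes)."""
    df = pd.read_csv(_path("panel_genes.tsv"), sep="\t")
    return [PanelGeneRow(gene=r.gene, n_exons=int(r.n_exons),
                         target_region=int(r.target_region),
                         n_primers=int(r.n_primers),
                         capture_size=int(r.capture_size))
            for r in df.itertuples()]


def load_sample_metrics() -> list[SampleMetricsRow]:
    """Per-sample read and coverage statistics (24 libraries)."""
    return read_sample_metrics(_path("sample_metrics.tsv"))


def load_coverage_correlation() -> CorrelationMatrix:
    """Pairwise Spearman coverage correlations (23 samples, 253 pairs)."""
    labels, values = read_matrix_tsv(_path("coverage_correlation.tsv"))
    return CorrelationMatrix(labels, values)


def load_known_mutations() -> pd.DataFrame:
    """The 25 catalogued cell-line mutations with rediscovery evidence
    (reference/variant depths and the qPCR amplification call)."""
    return read_mutation_table(_path("known_mutations.tsv"))


def load_pten_deletion_table() -> pd.DataFrame:
    """The 24 PTEN-4 capture reactions: end-point fluorescence, Cq and
    per-reaction amplicon coverage, joined on (chip, quadrant)."""
    wells = pd.read_csv(_path("pten_qpcr.csv"))
    cov = pd.read_csv(_path("pten_coverage.tsv"), sep="\t")
    return wells.merge(cov, on=["chip", "quadrant", "sample", "assay_id"])


def pten_deletion_calls(cq_max: float = 35.0, fluor_min: float = 100.0,
                        cov_max: float = 2.0) -> list[DeletionCall]:
    """Dual-evidence deletion call per PTEN-4 capture reaction."""
    calls = []
    for r in load_pten_deletion_table().itertuples():
        well = QpcrWell(chip=r.chip, quadrant=int(r.quadrant), sample=r.sample,
                        assay_id=r.assay_id, cq=float(r.cq),
                        endpoint_fluorescence=float(r.endpoint_fluorescence),
                        replicate_index=int(r.replicate_index))
        calls.append(detect_deletion([well], float(r.mean_cov),
                                     cq_max, fluor_min, cov_max))
    return calls


def known_mutation_evidence() -> list[tuple[KnownMutation, VariantCall | None,
                                            int, DeletionCall | None]]:
    """(mutation, call evidence, site depth, deletion call) per mutation.

    Call-evidence alleles are placeholders ("N" -> alt): the source table
    records only the per-allele depths, which is all classification uses.
    Deletion calls are looked up per sample from the PTEN-4 reactions.
    """
    del_by_sample: dict[str, DeletionCall] = {}
    for d in pten_deletion_calls():
        # a sample is deletion-called if any of its reactions is
        prev = del_by_sample.get(d.sample)
        if prev is None or (d.is_deleted and not prev.is_deleted):
            del_by_sample[d.sample] = d
    out = []
    for r in load_known_mutations().fillna("").itertuples():
        mut = KnownMutation(gene=r.gene, sample=r.sample, chrom=str(r.chrom),
                            pos=int(r.pos), cdna=r.cdna, protein=r.protein,
                            mut_class=r.mut_class, assay_id=r.assay_id)
        alt_depth = int(r.alt_depth)
        ref_depth = int(r.ref_depth)
        evidence = None
        if alt_depth > 0:
            alt = "NA" if mut.mut_class == "small_indel" else "A"
            af = alt_depth / (alt_depth + ref_depth)
            evidence = VariantCall(
                sample=mut.sample, chrom=mut.chrom, pos=mut.pos,
                ref="N", alt=alt,
                genotype="hom_alt" if af >= 0.75 else "het",
                ref_depth=ref_depth, alt_depth=alt_depth)
        deletion = del_by_sample.get(mut.sample) if mut.assay_id else None
        out.append((mut, evidence, ref_depth + alt_depth, deletion))
    return out


def load_replicate_snp_counts() -> list[ConcordanceGroup]:
    """Technical-replicate SNP concordance bookkeeping (3 replicate sets)."""
    df = pd.read_csv(_path("replicate_snp_counts.tsv"), sep="\t")
    groups = []
    for r in df.itertuples():
        groups.append(ConcordanceGroup(
            sample=r.sample,
            replicate_labels=r.replicate_labels.split(";"),
            replicate_counts=[int(x) for x in str(r.replicate_counts).split(";")],
            union_count=int(r.union), intersect_count=int(r.intersect),
            union_indels=int(r.union_indels),
            intersect_indels=int(r.intersect_indels),
            concordant=int(r.concordant), discordant=int(r.discordant)))
    return groups
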