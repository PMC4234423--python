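"""Known-mutation rediscovery and dual-evidence homozygous-deletion calls.

A homozygous deletion is only called when two independent evidence arms
agree: the qPCR reaction failed (no amplification, or negligible
end-point fluorescence) AND the sequencing depth over the amplicon is
near zero. Either arm alone is ambiguous — a failed reaction can simply
be a dropout well, and low depth can be a capture failure — so a pair
that satisfies one arm but not the other is flagged for review rather
than called.

Rediscovery classification is deliberately conservative: a known variant
whose site depth is below the callable minimum is *not* counted as
validated even when variant-supporting reads are visible, because no
reliable call could have been made at that depth. Large heterozygous
deletions are undetectable by PCR enrichment (the remaining allele
amplifies normally) and complex rearrangements surface as not_detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    Amplicon,
    AmpliQCError,
    DepthTrack,
    KnownMutation,
    QpcrWell,
    VariantCall,
)

STATUSES = ("validated_sequencing", "validated_deletion",
            "low_coverage", "not_detected")


@dataclass(frozen=True)
class DeletionCall:
    sample: str
    assay_id: str
    is_deleted: bool
    mean_cov: float
    cq: float
    endpoint_fluorescence: float
    discordant_evidence: bool = False


@dataclass(frozen=True)
class ValidationResult:
    mutation: KnownMutation
    status: str
    ref_depth: int
    alt_depth: int
    qpcr_call: str  # "ok" | "deletion"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise AmpliQCError(f"unknown validation status {self.status!r}")

    @property
    def validated(self) -> bool:
        return self.status in ("validated_sequencing", "validated_deletion")


def detect_deletion(wells: Sequence[QpcrWell], mean_cov: float,
                    cq_max: float = 35.0, fluor_min: float = 100.0,
                    cov_max: float = 2.0) -> DeletionCall:
    """Dual-evidence homozygous-deletion call for one sample x assay.

    is_deleted requires BOTH: every replicate well shows no amplification
    (Cq >= cq_max, or end-point fluorescence below fluor_min) AND the
    amplicon's mean sequencing depth is below cov_max reads. Discordant
    evidence (one arm only) is flagged but never called deleted.
    """
    if not wells:
        raise AmpliQCError("detect_deletion: need >=1 well")
    sample = wells[0].sample
    assay = wells[0].assay_id
    qpcr_dead = all(w.cq >= cq_max or w.endpoint_fluorescence < fluor_min
                    for w in wells)
    cov_dead = mean_cov < cov_max
    return DeletionCall(
        sample=sample, assay_id=assay,
        is_deleted=qpcr_dead and cov_dead, mean_cov=float(mean_cov),
        cq=float(np.mean([w.cq for w in wells])),
        endpoint_fluorescence=float(np.mean([w.endpoint_fluorescence
                                             for w in wells])),
        discordant_evidence=qpcr_dead != cov_dead,
    )


def classify_mutation(mutation: KnownMutation,
                      call_evidence: VariantCall | None,
                      site_depth: int,
                      deletion: DeletionCall | None = None,
                      min_callable_depth: int = 20) -> ValidationResult:
    """Assign exactly one rediscovery status to a known mutation.

    Ordered rules: a large deletion is judged on the dual-evidence
    deletion call (which is required for that class); otherwise a site
    below the callable depth is low_coverage; otherwise variant-supporting
    reads at callable depth validate the mutation, and their absence is
    not_detected.
    """
    if call_evidence is not None:
        ref_depth, alt_depth = call_evidence.ref_depth, call_evidence.alt_depth
    else:
        ref_depth, alt_depth = site_depth, 0
    qpcr_call = "deletion" if (deletion is not None and deletion.is_deleted) \
        else "ok"

    if mutation.mut_class == "large_deletion":
        if deletion is None:
            raise AmpliQCError(
                f"classify_mutation: large deletion {mutation.gene} in "
                f"{mutation.sample} needs qPCR evidence")
        if deletion.is_deleted:
            return ValidationResult(mutation, "validated_deletion",
                                    0, 0, "deletion")
        # deletion not confirmed: fall through to the depth rules

    if site_depth < min_callable_depth:
        return ValidationResult(mutation, "low_coverage",
                                ref_depth, alt_depth, qpcr_call)
    if alt_depth > 0:
        return ValidationResult(mutation, "validated_sequencing",
                                ref_depth, alt_depth, qpcr_call)
    return ValidationResult(mutation, "not_detected",
                            ref_depth, alt_depth, qpcr_call)


def validation_rate(results: Sequence[ValidationResult],
                    ) -> tuple[int, int, float]:
    """(validated count, total, fraction); validated means rediscovered by
    sequencing or confirmed deleted by the dual-evidence rule."""
    if not results:
        raise AmpliQCError("validation_rate: empty result list")
    validated = sum(r.validated for r in results)
    return validated, len(results), validated / len(results)


def validate_mutations(mutations: Sequence[KnownMutation],
                       calls: Sequence[VariantCall],
                       tracks: Sequence[DepthTrack],
                       wells: Sequence[QpcrWell],
                       panel: Sequence[Amplicon],
                       min_callable_depth: int = 20,
                       cq_max: float = 35.0, fluor_min: float = 100.0,
                       cov_max: float = 2.0) -> list[ValidationResult]:
    """End-to-end rediscovery: match each known mutation to its call,
    site depth, covering amplicon and qPCR wells, then classify."""
    call_ix: dict[tuple[str, str, int], VariantCall] = {}
    for c in calls:
        call_ix.setdefault((c.sample, c.chrom, c.pos), c)
    track_ix = {t.sample: t for t in tracks}
    wells_ix: dict[tuple[str, str], list[QpcrWell]] = {}
    for w in wells:
        wells_ix.setdefault((w.sample, w.assay_id), []).append(w)

    results = []
    for m in mutations:
        amp = next((a for a in panel if a.region.contains(m.chrom, m.pos)), None)
        if m.assay_id:
            amp = next((a for a in panel if a.assay_id == m.assay_id), amp)
        evidence = call_ix.get((m.sample, m.chrom, m.pos))
        track = track_ix.get(m.sample)
        if evidence is not None:
            site_depth = evidence.site_depth
        elif track is not None:
            site_depth = int(track.depth(m.chrom, m.pos))
        else:
            site_depth = 0
        deletion = None
        if amp is not None:
            pair_wells = wells_ix.get((m.sample, amp.assay_id), [])
            if pair_wells:
                if track is not None:
                    positions = [(amp.region.chrom, p)
                                 for p in amp.region.positions()]
                    mean_cov = float(np.mean(track.values_at(positions)))
                else:
                    mean_cov = float(site_depth)
                deletion = detect_deletion(pair_wells, mean_cov, cq_max,
                                           fluor_min, cov_max)
        results.append(classify_mutation(m, evidence, site_depth, deletion,
                                         min_callable_depth))
    return results
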