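"""Variant-call concordance across technical replicates of one sample.

The site universe for a replicate set is every (chrom, pos, ref, alt)
called in at least one replicate with callable depth (default >= 20) in
the replicate where it was called. Union/intersection run on full allele
identity — the same position with a different alt is a different site.
Genotype concordance compares the het vs hom_alt category at sites
called in every replicate.

Sites that fail to replicate are triaged by an ordered, exclusive rule:
(1) any replicate below callable depth -> coverage_issue; else (2) the
site sits in a homopolymer or dinucleotide repeat -> repeat_region; else
(3) allelic_ratio — the variant allele fraction drifted across
replicates, gaining or losing the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

from scipy import stats
import numpy as np

from .io_formats import AmpliQCError, DepthTrack, VariantCall

DISCORDANCE_CATEGORIES = ("coverage_issue", "repeat_region", "allelic_ratio")


class Replicate(NamedTuple):
    label: str
    calls: Sequence[VariantCall]
    track: DepthTrack | None = None


class SiteEvidence(NamedTuple):
    """One replicate's view of a site."""
    depth: float
    alt_depth: float
    called: bool


@dataclass
class ConcordanceGroup:
    sample: str
    replicate_labels: list[str]
    replicate_counts: list[int]
    union_count: int
    intersect_count: int
    union_indels: int
    intersect_indels: int
    concordant: int
    discordant: int
    discordant_sites: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intersect_count > self.union_count:
            raise AmpliQCError("intersect exceeds union")
        if self.concordant + self.discordant != self.intersect_count:
            raise AmpliQCError("concordant + discordant != intersect")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_labels)

    @property
    def intersect_fraction(self) -> float:
        return self.intersect_count / self.union_count if self.union_count else 0.0


@dataclass(frozen=True)
class DiscordanceRecord:
    chrom: str
    pos: int
    category: str
    evidence: tuple[tuple[str, SiteEvidence], ...]

    def __post_init__(self) -> None:
        if self.category not in DISCORDANCE_CATEGORIES:
            raise AmpliQCError(f"unknown discordance category {self.category!r}")


def build_group(sample: str, replicates: Sequence[Replicate],
                min_callable_depth: float = 20.0) -> ConcordanceGroup:
    """Union / intersection / genotype bookkeeping for one replicate set."""
    if len(replicates) < 2:
        raise AmpliQCError("build_group: need >=2 replicates")
    per_rep: list[dict[tuple, VariantCall]] = []
    for rep in replicates:
        per_rep.append({c.key: c for c in rep.calls})

    universe: set[tuple] = set()
    for rep, ix in zip(replicates, per_rep):
        for key, call in ix.items():
            depth = call.site_depth
            if rep.track is not None:
                depth = max(depth, rep.track.depth(call.chrom, call.pos))
            if depth >= min_callable_depth:
                universe.add(key)

    union_keys = sorted(universe)
    intersect_keys = [k for k in union_keys
                      if all(k in ix for ix in per_rep)]
    concordant = discordant = 0
    discordant_sites = []
    for k in intersect_keys:
        gts = {ix[k].genotype for ix in per_rep}
        if len(gts) == 1:
            concordant += 1
        else:
            discordant += 1
            discordant_sites.append(k)
    is_indel = lambda k: len(k[2]) != len(k[3])  # noqa: E731
    return ConcordanceGroup(
        sample=sample,
        replicate_labels=[r.label for r in replicates],
        replicate_counts=[len(r.calls) for r in replicates],
        union_count=len(union_keys),
        intersect_count=len(intersect_keys),
        union_indels=sum(is_indel(k) for k in union_keys),
        intersect_indels=sum(is_indel(k) for k in intersect_keys),
        concordant=concordant, discordant=discordant,
        discordant_sites=discordant_sites,
    )


def _in_repeat(context: str, site_index: int, homopolymer_min: int,
               dinuc_min_units: int) -> bool:
    """Whether position ``site_index`` of ``context`` lies inside a
    homopolymer run >= homopolymer_min bases or a dinucleotide repeat of
    >= dinuc_min_units units (two distinct bases)."""
    n = len(context)
    if not 0 <= site_index < n:
        raise AmpliQCError("repeat scan: site index outside context")
    # homopolymer: extend the run containing the site
    base = context[site_index]
    lo = site_index
    while lo > 0 and context[lo - 1] == base:
        lo -= 1
    hi = site_index
    while hi + 1 < n and context[hi + 1] == base:
        hi += 1
    if hi - lo + 1 >= homopolymer_min:
        return True
    # dinucleotide repeat: a maximal run alternating two distinct bases,
    # long enough and covering the site
    min_len = 2 * dinuc_min_units
    for start in range(n - 1):
        a, b = context[start], context[start + 1]
        if a == b:
            continue
        length = 0
        while (start + length < n
               and context[start + length] == (a if length % 2 == 0 else b)):
            length += 1
        if length >= min_len and start <= site_index < start + length:
            return True
    return False


def classify_discordance(evidence: Mapping[str, SiteEvidence],
                         chrom: str, pos: int,
                         repeat_context: str, site_index: int | None = None,
                         min_callable_depth: float = 20.0,
                         homopolymer_min: int = 5,
                         dinuc_min_units: int = 4) -> DiscordanceRecord:
    """Assign exactly one category to a replicate-discordant site.

    The rules are ordered and exclusive; a site meeting several criteria
    takes the earliest, so permuting replicate order never changes the
    outcome.
    """
    if not evidence:
        raise AmpliQCError("classify_discordance: no replicate evidence")
    for label, ev in evidence.items():
        if ev.depth is None:
            raise AmpliQCError(
                f"classify_discordance: missing depth for replicate {label!r}")
    if site_index is None:
        site_index = len(repeat_context) // 2
    if any(ev.depth < min_callable_depth for ev in evidence.values()):
        category = "coverage_issue"
    elif repeat_context and _in_repeat(repeat_context, site_index,
                                       homopolymer_min, dinuc_min_units):
        category = "repeat_region"
    else:
        category = "allelic_ratio"
    return DiscordanceRecord(chrom, pos, category,
                             tuple(sorted(evidence.items())))


def total_allele_calls(groups: Sequence[ConcordanceGroup]) -> int:
    """Sum over replicate sets of union-site count x replicate count —
    the denominator for per-allele-call failure rates."""
    return sum(g.union_count * g.n_replicates for g in groups)


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float
    low_expected: bool


def singleton_vs_duplicate_test(a_fail: int, a_total: int,
                                b_fail: int, b_total: int) -> ChiSquareResult:
    """Pearson chi-squared (1 df, no continuity correction) comparing
    failure proportions between two capture-replication groups."""
    if a_total <= 0 or b_total <= 0:
        raise AmpliQCError("singleton_vs_duplicate_test: totals must be > 0")
    if a_fail > a_total or b_fail > b_total:
        raise AmpliQCError("singleton_vs_duplicate_test: fails exceed totals")
    table = np.array([[a_fail, a_total - a_fail],
                      [b_fail, b_total - b_fail]], dtype=float)
    if table.sum() == 0:
        raise AmpliQCError("singleton_vs_duplicate_test: empty table")
    res = stats.chi2_contingency(table, correction=False)
    expected = res.expected_freq
    return ChiSquareResult(float(res.statistic), float(res.pvalue),
                           bool((expected < 1).any()))


def _shared_lookup(calls: Sequence[VariantCall]) -> dict[tuple, VariantCall]:
    return {c.key: c for c in calls}


def genotype_concordance(calls_a: Sequence[VariantCall],
                         calls_b: Sequence[VariantCall],
                         shared_sites: Sequence[tuple[str, int, str, str]],
                         ) -> float:
    """Fraction of shared sites with identical genotype category."""
    if not shared_sites:
        raise AmpliQCError("genotype_concordance: empty shared site list")
    a, b = _shared_lookup(calls_a), _shared_lookup(calls_b)
    matches = 0
    for key in shared_sites:
        if key not in a or key not in b:
            raise AmpliQCError(f"genotype_concordance: site {key} missing a call")
        matches += a[key].genotype == b[key].genotype
    return matches / len(shared_sites)


def allele_fraction_difference(calls_a: Sequence[VariantCall],
                               calls_b: Sequence[VariantCall],
                               shared_sites: Sequence[tuple[str, int, str, str]],
                               ) -> tuple[float, float]:
    """Mean and population SD of |AF_a - AF_b| over shared sites, where
    AF = alt / (alt + ref)."""
    if not shared_sites:
        raise AmpliQCError("allele_fraction_difference: empty shared site list")
    a, b = _shared_lookup(calls_a), _shared_lookup(calls_b)
    diffs = []
    for key in shared_sites:
        if key not in a or key not in b:
            raise AmpliQCError(
                f"allele_fraction_difference: site {key} missing a call")
        diffs.append(abs(a[key].allele_fraction - b[key].allele_fraction))
    arr = np.array(diffs)
    return float(np.mean(arr)), float(np.std(arr, ddof=0))
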