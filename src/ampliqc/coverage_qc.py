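"""Per-sample coverage statistics, mean-normalization and capture success.

All statistics run over the *base union* of the supplied targets:
overlapping targets (tiling amplicons) are flattened first so every base
counts once. The per-base SD is a population SD (the bases are a census,
not a sample); across-sample summaries of the metrics table use the
sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    Amplicon,
    AmpliQCError,
    DepthTrack,
    GenomicRegion,
    SampleMetricsRow,
    target_positions,
)


@dataclass(frozen=True)
class CoverageSummary:
    sample: str
    target_set: str  # "amplicon" | "exon"
    mean_cov: float
    sd_cov: float
    n_bases: int


@dataclass(frozen=True)
class UniformityReport:
    band_lo: float
    band_hi: float
    fraction_in_band: float
    target_set: str = ""


def per_sample_stats(track: DepthTrack, targets: Sequence[GenomicRegion],
                     target_set: str = "amplicon") -> CoverageSummary:
    """Mean and population SD of depth over every base of the flattened
    target union (in-target bases absent from the track count as 0)."""
    if not targets:
        raise AmpliQCError("per_sample_stats: empty target list")
    positions = target_positions(targets)
    vals = track.values_at(positions)
    return CoverageSummary(
        sample=track.sample, target_set=target_set,
        mean_cov=float(np.mean(vals)), sd_cov=float(np.std(vals, ddof=0)),
        n_bases=len(vals),
    )


def normalize_track(track: DepthTrack,
                    targets: Sequence[GenomicRegion]) -> DepthTrack:
    """Divide each in-target base by the sample's target mean coverage.

    The normalized track covers exactly the target union and averages 1
    by construction; a zero mean (sample failed entirely) is an error.
    """
    positions = target_positions(targets)
    vals = track.values_at(positions)
    mean = float(np.mean(vals))
    if mean <= 0:
        raise AmpliQCError(
            f"normalize_track: zero mean coverage for sample {track.sample!r}")
    norm = DepthTrack(track.sample)
    arr = vals / mean
    by_chrom: dict[str, tuple[list[int], list[float]]] = {}
    for (chrom, pos), v in zip(positions, arr):
        by_chrom.setdefault(chrom, ([], []))[0].append(pos)
        by_chrom[chrom][1].append(float(v))
    for chrom, (ps, vs) in by_chrom.items():
        norm.add_chrom(chrom, ps, vs)
    return norm


def uniformity_fraction(norm_track: DepthTrack, band_lo: float, band_hi: float,
                        targets: Sequence[GenomicRegion],
                        target_set: str = "") -> UniformityReport:
    """Fraction of target bases with band_lo <= normalized depth <= band_hi."""
    if not (0 <= band_lo < band_hi):
        raise AmpliQCError("uniformity_fraction: need 0 <= band_lo < band_hi")
    vals = norm_track.values_at(target_positions(targets))
    in_band = (vals >= band_lo) & (vals <= band_hi)
    return UniformityReport(band_lo, band_hi, float(np.mean(in_band)), target_set)


def assay_success_rates(tracks: Sequence[DepthTrack], panel: Sequence[Amplicon],
                        min_cov: float = 20.0, min_sample_frac: float = 0.8,
                        ) -> tuple[float, float, dict[str, bool]]:
    """Capture success per assay and panel-wide success fractions.

    An assay succeeds when *strictly more than* ``min_sample_frac`` of the
    samples show a mean amplicon depth *strictly above* ``min_cov``.
    Returns (success_fraction, fraction of assays with any coverage in at
    least one sample, per-assay success flags).
    """
    if not tracks or not panel:
        raise AmpliQCError("assay_success_rates: need >=1 track and >=1 assay")
    flags: dict[str, bool] = {}
    n_any = 0
    for a in panel:
        positions = [(a.region.chrom, p) for p in a.region.positions()]
        means = np.array([float(np.mean(t.values_at(positions))) for t in tracks])
        flags[a.assay_id] = float(np.mean(means > min_cov)) > min_sample_frac
        if np.any(means > 0):
            n_any += 1
    success_fraction = sum(flags.values()) / len(panel)
    return success_fraction, n_any / len(panel), flags


def summarize_sample_table(rows: Sequence[SampleMetricsRow],
                           column: str) -> tuple[float, float]:
    """Across-sample mean and sample SD of one numeric metrics column."""
    if len(rows) < 2:
        raise AmpliQCError("summarize_sample_table: need >=2 rows")
    if not hasattr(rows[0], column):
        raise AmpliQCError(f"summarize_sample_table: unknown column {column!r}")
    vals = np.array([getattr(r, column) for r in rows], dtype=float)
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def cumulative_distribution(tracks: Iterable[DepthTrack],
                            targets: Sequence[GenomicRegion],
                            mode: str = "per_base_mean",
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative distribution of normalized coverage over target bases.

    ``per_base_mean`` averages the normalized coverage across samples per
    base before ranking; ``pooled`` ranks every sample x base value.
    Returns sorted values and the fraction of bases at or below each.
    """
    positions = target_positions(targets)
    mat = np.stack([normalize_track(t, targets).values_at(positions)
                    for t in tracks])
    if mode == "per_base_mean":
        vals = mat.mean(axis=0)
    elif mode == "pooled":
        vals = mat.ravel()
    else:
        raise AmpliQCError(f"cumulative_distribution: unknown mode {mode!r}")
    vals = np.sort(vals)
    frac = np.arange(1, len(vals) + 1) / len(vals)
    return vals, frac
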