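"""Inter-sample coverage reproducibility and qPCR dropout accounting.

The headline reproducibility metric is the pairwise Spearman rank
correlation of raw per-base depths over the amplicon-base union (rank
correlation makes per-sample scaling irrelevant, so raw and
mean-normalized depths give identical values). Reaction dropout is a
Cq strictly above a threshold cycle (default 29); dropout wells are
excluded from the Cq-coverage regression because the sentinel Cq 40
would dominate the fit, but they are counted in the dropout rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    Amplicon,
    AmpliQCError,
    DepthTrack,
    GenomicRegion,
    QpcrWell,
    target_positions,
)


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise Spearman correlations; NaN marks an
    undefined pair (zero depth variance in one of the tracks)."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise AmpliQCError("correlation matrix shape mismatch")

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.samples), k=1)
        return self.values[iu]


class MatrixSummary(NamedTuple):
    mean: float
    sd: float
    n_pairs: int
    n_missing: int


def spearman_pair(track_a: DepthTrack, track_b: DepthTrack,
                  targets: Sequence[GenomicRegion]) -> float:
    """Spearman rank correlation of two depth tracks over the target union.

    Ties take average ranks. Returns NaN when either track has zero
    variance over the targets (correlation undefined).
    """
    positions = target_positions(targets)
    if len(positions) < 3:
        raise AmpliQCError("spearman_pair: need >=3 target positions")
    a = track_a.values_at(positions)
    b = track_b.values_at(positions)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def correlation_matrix(tracks: Sequence[DepthTrack],
                       targets: Sequence[GenomicRegion]) -> CorrelationMatrix:
    if len(tracks) < 2:
        raise AmpliQCError("correlation_matrix: need >=2 tracks")
    n = len(tracks)
    vals = np.eye(n)
    positions = target_positions(targets)
    depth = np.stack([t.values_at(positions) for t in tracks])
    ranks = np.stack([stats.rankdata(row) for row in depth])
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(depth[i] == depth[i][0]) or np.all(depth[j] == depth[j][0]):
                rho = float("nan")
            else:
                rho = float(np.corrcoef(ranks[i], ranks[j])[0, 1])
            vals[i, j] = vals[j, i] = rho
    return CorrelationMatrix([t.sample for t in tracks], vals)


def summarize_matrix(matrix: CorrelationMatrix) -> MatrixSummary:
    """Mean and sample SD over the n(n-1)/2 unique off-diagonal pairs;
    missing (NaN) pairs are excluded and counted."""
    if len(matrix.samples) < 2:
        raise AmpliQCError("summarize_matrix: need >=2 samples")
    off = matrix.off_diagonal()
    missing = int(np.isnan(off).sum())
    off = off[~np.isnan(off)]
    if len(off) == 0:
        raise AmpliQCError("summarize_matrix: no defined pairs")
    sd = float(np.std(off, ddof=1)) if len(off) > 1 else 0.0
    return MatrixSummary(float(np.mean(off)), sd, len(off), missing)


def cq_coverage_association(wells: Sequence[QpcrWell], panel: Sequence[Amplicon],
                            assay_mean_cov: Mapping[tuple[str, str], float],
                            exclude_tiling: bool = True,
                            cq_dropout_threshold: float = 29.0) -> float:
    """Squared Pearson correlation (R^2) of Cq vs per-assay mean coverage.

    One point per (sample, assay) pair with a usable well: dropout wells
    (Cq above the threshold) are excluded, and tiling assays are excluded
    by default because coverage in the overlap cannot be attributed to one
    assay. Replicate wells of a pair are averaged.
    """
    tiling_ids = {a.assay_id for a in panel if a.tiling_group is not None}
    cqs: dict[tuple[str, str], list[float]] = {}
    for w in wells:
        if w.cq > cq_dropout_threshold:
            continue
        if exclude_tiling and w.assay_id in tiling_ids:
            continue
        cqs.setdefault((w.sample, w.assay_id), []).append(w.cq)
    xs, ys = [], []
    for key, cq_list in cqs.items():
        if key in assay_mean_cov:
            xs.append(float(np.mean(cq_list)))
            ys.append(float(assay_mean_cov[key]))
    if len(xs) < 3:
        raise AmpliQCError("cq_coverage_association: <3 usable (sample, assay) pairs")
    r = stats.pearsonr(xs, ys).statistic
    return float(r * r) if math.isfinite(r) else float("nan")


def assay_mean_coverage(tracks: Sequence[DepthTrack], panel: Sequence[Amplicon],
                        ) -> dict[tuple[str, str], float]:
    """Mean depth per (sample, assay) over each amplicon's bases."""
    out: dict[tuple[str, str], float] = {}
    for a in panel:
        positions = [(a.region.chrom, p) for p in a.region.positions()]
        for t in tracks:
            out[(t.sample, a.assay_id)] = float(np.mean(t.values_at(positions)))
    return out


def dropout_rate(wells: Sequence[QpcrWell], cq_threshold: float = 29.0) -> float:
    """Fraction of wells with Cq strictly greater than the threshold."""
    if not wells:
        raise AmpliQCError("dropout_rate: empty well list")
    return float(np.mean([w.cq > cq_threshold for w in wells]))
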