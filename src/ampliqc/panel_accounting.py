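"""Panel-level bookkeeping: per-gene exon counts, target size, assay
counts and capture size, with a totals row recomputed by column sums.

"Number of primers" is the assay (primer-pair) count per gene — one
entry per amplicon. Capture size is the base-union of a gene's
amplicons, so tiling overlaps count once; it can exceed or fall short
of the exonic target size (primer flanks vs untiled exon ends), so no
ordering between the two columns is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import Amplicon, AmpliQCError, GenomicRegion, union_length


@dataclass(frozen=True)
class PanelGeneRow:
    gene: str
    n_exons: int
    target_region: int  # bp (exonic base-union)
    n_primers: int      # assays (primer pairs)
    capture_size: int   # bp (amplicon base-union)

    def __post_init__(self) -> None:
        if min(self.n_exons, self.target_region,
               self.n_primers, self.capture_size) < 0:
            raise AmpliQCError("panel counts must be >= 0")


@dataclass(frozen=True)
class PanelSummary:
    rows: tuple[PanelGeneRow, ...]
    totals: PanelGeneRow

    def to_dataframe(self) -> pd.DataFrame:
        recs = [vars(r) for r in self.rows] + [vars(self.totals)]
        return pd.DataFrame(recs)


def panel_totals(rows: Sequence[PanelGeneRow]) -> PanelGeneRow:
    """Totals row = column sums over the per-gene rows."""
    return PanelGeneRow(
        gene="Total",
        n_exons=sum(r.n_exons for r in rows),
        target_region=sum(r.target_region for r in rows),
        n_primers=sum(r.n_primers for r in rows),
        capture_size=sum(r.capture_size for r in rows),
    )


def summarize_panel(panel: Sequence[Amplicon],
                    exons: Sequence[GenomicRegion]) -> PanelSummary:
    """Per-gene panel accounting from interval data.

    Amplicons without a gene label are bucketed under "unassigned"."""
    if not panel:
        raise AmpliQCError("summarize_panel: empty panel")
    genes: dict[str, dict] = {}
    for a in panel:
        g = a.gene or "unassigned"
        genes.setdefault(g, {"amplicons": [], "exons": []})["amplicons"].append(a)
    for e in exons:
        g = e.gene or "unassigned"
        genes.setdefault(g, {"amplicons": [], "exons": []})["exons"].append(e)
    rows = []
    for g in sorted(genes):
        amps = genes[g]["amplicons"]
        exs = genes[g]["exons"]
        rows.append(PanelGeneRow(
            gene=g,
            n_exons=len(exs),
            target_region=union_length(exs) if exs else 0,
            n_primers=len(amps),
            capture_size=union_length(a.region for a in amps) if amps else 0,
        ))
    return PanelSummary(tuple(rows), panel_totals(rows))


def amplicon_length_stats(panel: Sequence[Amplicon],
                          ) -> tuple[float, int, int]:
    """(mean, min, max) amplicon length in bp."""
    if not panel:
        raise AmpliQCError("amplicon_length_stats: empty panel")
    lengths = np.array([a.length for a in panel])
    return float(lengths.mean()), int(lengths.min()), int(lengths.max())
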