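"""Domain records and file formats for amplicon target-enrichment QC.

The pipeline touches a handful of small, well-established text formats:
BED intervals for amplicons and exons, samtools-depth-style per-base depth
tables, a CSV of nanowell qPCR reactions, a minimal VCF subset for variant
calls, and plain TSVs for the mutation and per-sample metrics tables.
Coordinates are 0-based half-open internally (BED-native); everything a
human reads — depth-table positions, ``VariantCall.pos`` — is 1-based.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam


class AmpliQCError(Exception):
    """Base class for errors raised by this package."""


class ParseError(AmpliQCError):
    """A file could not be parsed; the message names the offending line."""


class InvariantError(AmpliQCError):
    """A domain invariant was violated by input data."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicRegion:
    """Half-open interval [start, end) on a named sequence.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, so the
    region covers ``end - start`` bases, i.e. the 1-based positions
    ``start + 1 .. end``.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvariantError("region chrom must be non-empty")
        if self.start >= self.end:
            raise InvariantError(
                f"region {self.chrom}:{self.start}-{self.end} has non-positive length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def positions(self) -> range:
        """1-based positions covered by the region."""
        return range(self.start + 1, self.end + 1)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside the region."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass(frozen=True)
class Amplicon:
    """One PCR assay: the amplified interval plus its assay identity."""

    region: GenomicRegion
    assay_id: str
    tiling_group: str | None = None

    @property
    def gene(self) -> str:
        return self.region.gene

    @property
    def length(self) -> int:
        return self.region.length


class DepthTrack:
    """Per-base sequencing depth for one sample.

    Positions are 1-based; positions absent from the track are depth 0
    (samtools depth omits zero rows, so absence is the zero convention).
    Stored per chromosome as sorted position/value arrays, which keeps
    whole-panel tracks cheap and makes vectorised lookups fast.
    """

    def __init__(self, sample: str,
                 depths: Mapping[tuple[str, int], float] | None = None):
        self.sample = sample
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}
        if depths:
            by_chrom: dict[str, list[tuple[int, float]]] = {}
            for (chrom, pos), d in depths.items():
                by_chrom.setdefault(chrom, []).append((pos, d))
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                pos = np.array([p for p, _ in pairs], dtype=np.int64)
                val = np.array([v for _, v in pairs], dtype=float)
                self._store(chrom, pos, val)

    def _store(self, chrom: str, pos: np.ndarray, val: np.ndarray) -> None:
        if np.any(val < 0):
            raise InvariantError(f"negative depth in track {self.sample!r}")
        if len(np.unique(pos)) != len(pos):
            raise InvariantError(
                f"duplicate position on {chrom} in track {self.sample!r}")
        self._pos[chrom] = pos
        self._val[chrom] = val

    @classmethod
    def from_arrays(cls, sample: str, chrom: str,
                    positions: np.ndarray, values: np.ndarray) -> "DepthTrack":
        track = cls(sample)
        track.add_chrom(chrom, positions, values)
        return track

    def add_chrom(self, chrom: str, positions: Sequence[int],
                  values: Sequence[float]) -> None:
        pos = np.asarray(positions, dtype=np.int64)
        val = np.asarray(values, dtype=float)
        order = np.argsort(pos, kind="stable")
        self._store(chrom, pos[order], val[order])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def depth(self, chrom: str, pos: int) -> float:
        """Depth at one 1-based position; 0 if the position is absent."""
        p = self._pos.get(chrom)
        if p is None or len(p) == 0:
            return 0.0
        i = np.searchsorted(p, pos)
        if i < len(p) and p[i] == pos:
            return float(self._val[chrom][i])
        return 0.0

    def values_at(self, positions: Sequence[tuple[str, int]]) -> np.ndarray:
        """Depths at 1-based (chrom, pos) pairs, 0 where absent."""
        out = np.zeros(len(positions), dtype=float)
        by_chrom: dict[str, list[int]] = {}
        for i, (chrom, pos) in enumerate(positions):
            by_chrom.setdefault(chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            p = self._pos.get(chrom)
            if p is None or len(p) == 0:
                continue
            want = np.array([positions[i][1] for i in idx], dtype=np.int64)
            j = np.searchsorted(p, want)
            j_clip = np.minimum(j, len(p) - 1)
            hit = p[j_clip] == want
            vals = np.where(hit, self._val[chrom][j_clip], 0.0)
            out[np.array(idx)] = vals
        return out

    def items(self) -> Iterator[tuple[tuple[str, int], float]]:
        for chrom in self.chroms:
            for pos, val in zip(self._pos[chrom], self._val[chrom]):
                yield (chrom, int(pos)), float(val)

    def __len__(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def __repr__(self) -> str:  # pragma: no cover
        return f"DepthTrack({self.sample!r}, {len(self)} positions)"


CQ_SENTINEL = 40.0  # no-amplification sentinel cycle


@dataclass(frozen=True)
class QpcrWell:
    """One nanowell qPCR reaction: Cq and end-point fluorescence.

    Cq is the quantitation cycle in [0, 40]; 40 is the sentinel for a
    reaction that never crossed threshold (end-point fluorescence 0).
    """

    chip: str
    quadrant: int
    sample: str
    assay_id: str
    cq: float
    endpoint_fluorescence: float
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.cq <= CQ_SENTINEL):
            raise InvariantError(f"cq {self.cq} outside [0, {CQ_SENTINEL}]")
        if self.endpoint_fluorescence < 0:
            raise InvariantError("endpoint fluorescence must be >= 0")
        if not 1 <= self.quadrant <= 4:
            raise InvariantError("quadrant must be 1-4")


@dataclass(frozen=True)
class VariantCall:
    """A non-reference call for one sample at one site, with allele depths."""

    sample: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom_alt"
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InvariantError("ref and alt alleles must differ")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise InvariantError("allele depths must be >= 0")
        if self.genotype not in ("het", "hom_alt"):
            raise InvariantError(f"unknown genotype {self.genotype!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def site_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def allele_fraction(self) -> float:
        d = self.site_depth
        return self.alt_depth / d if d else float("nan")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity: same position with different alleles is a
        different key."""
        return (self.chrom, self.pos, self.ref, self.alt)


MUTATION_CLASSES = ("snv", "small_indel", "large_deletion", "complex")


@dataclass(frozen=True)
class KnownMutation:
    """A catalogued mutation of a characterised cell line."""

    gene: str
    sample: str
    chrom: str
    pos: int
    cdna: str
    protein: str = ""
    mut_class: str = "snv"
    assay_id: str = ""

    def __post_init__(self) -> None:
        if self.mut_class not in MUTATION_CLASSES:
            raise InvariantError(f"unknown mutation class {self.mut_class!r}")
        if not self.gene or not self.sample:
            raise InvariantError("gene and sample labels must be non-empty")


@dataclass(frozen=True)
class SampleMetricsRow:
    """Per-sample library statistics: reads, mapping, duplicates, coverage."""

    sample: str
    n_pcr_replicates: int
    total_reads: int
    mapped_frac: float
    on_target_frac: float
    duplicate_frac: float
    amplicon_mean_cov: float
    amplicon_sd_cov: float
    exon_mean_cov: float
    exon_sd_cov: float

    def __post_init__(self) -> None:
        for f in ("mapped_frac", "on_target_frac", "duplicate_frac"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise InvariantError(f"{f}={v} outside [0, 1]")
        if self.total_reads < 0 or self.n_pcr_replicates < 0:
            raise InvariantError("counts must be >= 0")


# ---------------------------------------------------------------------------
# Region utilities
# ---------------------------------------------------------------------------

def merge_regions(regions: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    """Base-union of regions: merged, sorted, non-overlapping intervals.

    Bases covered by two tiling amplicons are counted once downstream.
    """
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[GenomicRegion] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(GenomicRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(GenomicRegion(chrom, cur_start, cur_end))
    return merged


def union_length(regions: Iterable[GenomicRegion]) -> int:
    """Number of distinct bases covered by the regions."""
    return sum(r.length for r in merge_regions(regions))


def target_positions(regions: Iterable[GenomicRegion]) -> list[tuple[str, int]]:
    """Sorted 1-based (chrom, pos) pairs of the base-union of ``regions``.

    A region of length L contributes exactly L positions.
    """
    out: list[tuple[str, int]] = []
    for r in merge_regions(regions):
        out.extend((r.chrom, p) for p in r.positions())
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read 3-6 column BED. Column 4 -> name, column 5 ignored (score),
    column 6 -> gene when non-numeric and not a strand symbol."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            gene = ""
            if len(fields) > 5 and fields[5] not in ("+", "-", "."):
                gene = fields[5]
            try:
                regions.append(GenomicRegion(chrom, start, end, name, gene))
            except InvariantError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end), r.name]
            if r.gene:
                fields += ["0", r.gene]
            fh.write("\t".join(fields) + "\n")


def _gene_from_assay(assay_id: str) -> str:
    return assay_id.rsplit("-", 1)[0] if "-" in assay_id else assay_id


def read_amplicon_bed(path: str | os.PathLike) -> list[Amplicon]:
    """Read an amplicon panel BED: name column holds the assay id
    (``GENE-k``); optional 7th column holds the tiling group ('.' = none)."""
    amplicons: list[Amplicon] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: amplicon BED needs >=4 fields")
            try:
                region = GenomicRegion(
                    fields[0], int(fields[1]), int(fields[2]), fields[3],
                    fields[5] if len(fields) > 5 and fields[5] not in ("+", "-", ".")
                    else _gene_from_assay(fields[3]),
                )
            except (ValueError, InvariantError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            tiling = None
            if len(fields) > 6 and fields[6] not in (".", ""):
                tiling = fields[6]
            amplicons.append(Amplicon(region, fields[3], tiling))
    ids = [a.assay_id for a in amplicons]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate assay_id in panel")
    return amplicons


def write_amplicon_bed(panel: Iterable[Amplicon], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a in panel:
            r = a.region
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), a.assay_id, "0",
                r.gene or ".", a.tiling_group or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Depth tables (samtools-depth style, one column per sample)
# ---------------------------------------------------------------------------

def read_depth_table(path: str | os.PathLike) -> list[DepthTrack]:
    """Read a multi-sample per-base depth TSV.

    Header ``#chrom<TAB>pos<TAB><sample>...``; body rows carry a 1-based
    position and one integer depth per sample. Positions absent from the
    file read back as depth 0.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [df.columns[0].lstrip("#"), *df.columns[1:]]
    if df.shape[1] < 3:
        raise ParseError(f"{path}: depth table needs chrom, pos and >=1 sample column")
    samples = list(df.columns[2:])
    if df.duplicated(subset=df.columns[:2].tolist()).any():
        raise ParseError(f"{path}: duplicate (chrom, pos) row")
    tracks = []
    for s in samples:
        vals = df[s].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ParseError(f"{path}: negative depth in column {s!r}")
        track = DepthTrack(s)
        for chrom, sub in df.groupby(df.columns[0], sort=True):
            track.add_chrom(str(chrom), sub.iloc[:, 1].to_numpy(dtype=np.int64),
                            sub[s].to_numpy(dtype=float))
        tracks.append(track)
    return tracks


def write_depth_table(tracks: Sequence[DepthTrack], path: str | os.PathLike) -> None:
    """Write tracks over the union of their positions; absent = 0 on read,
    so zero rows are kept only if some track covers the position."""
    positions = sorted({key for t in tracks for key, _ in t.items()})
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\t" + "\t".join(t.sample for t in tracks) + "\n")
        values = [t.values_at(positions) for t in tracks]
        for i, (chrom, pos) in enumerate(positions):
            row = [chrom, str(pos)]
            for v in values:
                x = v[i]
                row.append(str(int(x)) if float(x).is_integer() else repr(float(x)))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# qPCR well tables
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["chip", "quadrant", "sample", "assay_id", "cq",
                "endpoint_fluorescence", "replicate_index"]


def read_qpcr_table(path: str | os.PathLike) -> list[QpcrWell]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(QPCR_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        wells = []
        for lineno, row in enumerate(reader, start=2):
            try:
                wells.append(QpcrWell(
                    chip=row["chip"],
                    quadrant=int(row["quadrant"]),
                    sample=row["sample"],
                    assay_id=row["assay_id"],
                    cq=float(row["cq"]),
                    endpoint_fluorescence=float(row["endpoint_fluorescence"]),
                    replicate_index=int(row["replicate_index"]),
                ))
            except (ValueError, InvariantError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return wells


def write_qpcr_table(wells: Iterable[QpcrWell], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(QPCR_COLUMNS)
        for w in wells:
            writer.writerow([w.chip, w.quadrant, w.sample, w.assay_id,
                             repr(w.cq), repr(w.endpoint_fluorescence),
                             w.replicate_index])


# ---------------------------------------------------------------------------
# Variant calls (minimal VCF subset: GT + AD)
# ---------------------------------------------------------------------------

def read_variant_calls(path: str | os.PathLike) -> list[VariantCall]:
    """Read a VCF (v4.x subset) into per-sample calls.

    One ``VariantCall`` is emitted per sample x alt allele with a
    non-reference genotype; multi-allelic records are decomposed per alt.
    Hom-ref and missing genotypes yield no record. A non-ref genotype
    without allelic depths (AD) is an error.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            for s in samples:
                data = rec.samples[s]
                gt = data.get("GT")
                if gt is None or all(a in (None, 0) for a in gt):
                    continue
                ad = data.get("AD")
                if ad is None or any(a is None for a in ad):
                    raise ParseError(
                        f"{path}: {rec.chrom}:{rec.pos} sample {s}: "
                        "non-reference genotype without AD")
                called_alts = sorted({a for a in gt if a not in (None, 0)})
                for ai in called_alts:
                    alt = alts[ai - 1]
                    genotype = "het" if 0 in gt or len(called_alts) > 1 else "hom_alt"
                    calls.append(VariantCall(
                        sample=s, chrom=rec.chrom, pos=rec.pos,
                        ref=rec.ref, alt=alt, genotype=genotype,
                        ref_depth=int(ad[0]), alt_depth=int(ad[ai]),
                    ))
    return calls


def write_variant_calls(calls: Sequence[VariantCall],
                        path: str | os.PathLike,
                        samples: Sequence[str] | None = None) -> None:
    """Write calls as a minimal VCF with GT and AD; samples without a call
    at a site are emitted hom-ref with missing AD."""
    if samples is None:
        samples = sorted({c.sample for c in calls})
    sites: dict[tuple[str, int, str, str], dict[str, VariantCall]] = {}
    for c in calls:
        sites.setdefault(c.key, {})[c.sample] = c
    chrom_order = {c: i for i, c in enumerate(
        dict.fromkeys([k[0] for k in sorted(sites)]))}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for key in sorted(sites, key=lambda k: (chrom_order[k[0]], k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            row = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT:AD"]
            for s in samples:
                c = sites[key].get(s)
                if c is None:
                    row.append("0/0:.")
                else:
                    gt = "0/1" if c.genotype == "het" else "1/1"
                    row.append(f"{gt}:{c.ref_depth},{c.alt_depth}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Mutation and metrics tables
# ---------------------------------------------------------------------------

def read_mutation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a known-mutation TSV (gene, sample, chrom, pos, cdna, protein,
    mut_class, assay_id, qpcr_call, ref_depth, alt_depth) as a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene", "sample", "chrom", "pos", "cdna", "mut_class",
                "qpcr_call", "ref_depth", "alt_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def mutation_table_records(df: pd.DataFrame) -> list[KnownMutation]:
    return [
        KnownMutation(
            gene=row.gene, sample=row.sample, chrom=str(row.chrom),
            pos=int(row.pos), cdna=row.cdna,
            protein=getattr(row, "protein", "") or "",
            mut_class=row.mut_class,
            assay_id=getattr(row, "assay_id", "") or "",
        )
        for row in df.fillna("").itertuples()
    ]


METRICS_COLUMNS = ["sample", "n_pcr_replicates", "total_reads", "mapped_frac",
                   "on_target_frac", "duplicate_frac", "amplicon_mean_cov",
                   "amplicon_sd_cov", "exon_mean_cov", "exon_sd_cov"]


def read_sample_metrics(path: str | os.PathLike) -> list[SampleMetricsRow]:
    df = pd.read_csv(path, sep="\t")
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [SampleMetricsRow(
        sample=r.sample, n_pcr_replicates=int(r.n_pcr_replicates),
        total_reads=int(r.total_reads), mapped_frac=float(r.mapped_frac),
        on_target_frac=float(r.on_target_frac),
        duplicate_frac=float(r.duplicate_frac),
        amplicon_mean_cov=float(r.amplicon_mean_cov),
        amplicon_sd_cov=float(r.amplicon_sd_cov),
        exon_mean_cov=float(r.exon_mean_cov),
        exon_sd_cov=float(r.exon_sd_cov)) for r in df.itertuples()]


def write_sample_metrics(rows: Iterable[SampleMetricsRow],
                         path: str | os.PathLike) -> None:
    pd.DataFrame([{c: getattr(r, c) for c in METRICS_COLUMNS}
                  for r in rows]).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Read a square labelled matrix TSV -> (labels, values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: matrix rows and columns disagree")
    return list(df.columns), df.to_numpy(dtype=float)


def write_matrix_tsv(labels: Sequence[str], values: np.ndarray,
                     path: str | os.PathLike) -> None:
    pd.DataFrame(values, index=list(labels),
                 columns=list(labels)).to_csv(path, sep="\t")
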