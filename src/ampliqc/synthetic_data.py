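"""Synthetic nanowell-capture data with the structure the QC assumes.

The simulator emits post-mapping artefacts directly — per-base depth
tracks, qPCR wells and variant calls — not reads. Its statistical
skeleton:

* every amplicon has a log-normal *efficiency* shared by all samples
  (the same assay amplifies similarly everywhere), which is what makes
  depth profiles of different samples rank-correlate;
* every sample has a log-normal *scale* (library size) multiplying all
  its depths;
* per-sample x amplicon log-normal noise breaks the correlation by a
  controllable amount;
* depth tapers linearly over one read length at each amplicon end
  (reads must start inside the amplicon), flat in the interior;
* a homozygously deleted (sample, assay) pair loses its amplicon
  contribution entirely, leaving Poisson stray reads, and its qPCR
  wells read the no-amplification sentinel (Cq 40, fluorescence 0);
* Cq is linear in -log2(amplified quantity) plus Gaussian noise, and an
  independent fraction of wells drops out (Cq pushed above 29);
* injected variants draw their alt depth binomially from the site depth
  at the configured allele fraction, and become *calls* only past a
  caller minimum — so a truth set records what was planted, whether or
  not it surfaced.

Defaults mirror the validation study the package's bundled dataset comes
from: a 16-gene panel of ~24 assays each (amplicons 319-745 bp, mean
441), 24 libraries at a mean amplicon coverage of 537x, 15% PCR
duplicates and a 1.16% qPCR dropout rate.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .io_formats import (
    Amplicon,
    AmpliQCError,
    DepthTrack,
    GenomicRegion,
    QpcrWell,
    SampleMetricsRow,
    VariantCall,
    target_positions,
)

# fixed per-stage stream tags so any stage can be regenerated on its own
_STAGE = {"panel": 1, "depth": 2, "qpcr": 3, "variants": 4, "metrics": 5}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage]])


@dataclass
class SimulationParams:
    seed: int = 0
    n_genes: int = 16
    amplicons_per_gene: int = 24
    n_samples: int = 24
    amplicon_length_bounds: tuple[int, int] = (319, 745)
    amplicon_length_mean: float = 441.0
    tiling_fraction: float = 0.15
    primer_flank: int = 25
    sample_depth_scale: float = 537.0
    sample_scale_sd: float = 0.28
    amplicon_effect_sd: float = 0.6
    noise_sd: float = 0.25
    duplicate_rate: float = 0.15
    dropout_rate: float = 0.0116
    mapped_frac: float = 0.977
    on_target_frac: float = 0.786
    cq_intercept: float = 21.0
    cq_slope: float = 1.5
    cq_noise_sd: float = 0.8
    n_qpcr_replicates: int = 2
    n_variants: int = 120
    vaf_het: float = 0.5
    vaf_hom: float = 0.98
    hom_fraction: float = 0.2
    indel_fraction: float = 0.15
    read_length: int = 150
    stray_depth: float = 0.4
    min_alt_reads: int = 3
    min_alt_frac: float = 0.10
    deletion_assays: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        lo, hi = self.amplicon_length_bounds
        if not lo < hi:
            raise AmpliQCError("amplicon_length_bounds must be ordered")
        if not lo < self.amplicon_length_mean < hi:
            raise AmpliQCError("amplicon_length_mean outside length bounds")
        for name in ("tiling_fraction", "duplicate_rate", "dropout_rate",
                     "mapped_frac", "on_target_frac", "vaf_het", "vaf_hom",
                     "hom_fraction", "indel_fraction", "min_alt_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AmpliQCError(f"{name}={v} outside [0, 1]")
        for name in ("n_genes", "amplicons_per_gene", "n_samples",
                     "n_qpcr_replicates"):
            if getattr(self, name) < 1:
                raise AmpliQCError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplicon_length_bounds"] = list(self.amplicon_length_bounds)
        d["deletion_assays"] = [list(p) for p in self.deletion_assays]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if "amplicon_length_bounds" in d:
            d["amplicon_length_bounds"] = tuple(d["amplicon_length_bounds"])
        if "deletion_assays" in d:
            d["deletion_assays"] = [tuple(p) for p in d["deletion_assays"]]
        return cls(**d)

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class TruthSet:
    """What the simulator planted, for recovery tests."""
    variants: list[tuple[str, str, int, str, str, str]] = field(default_factory=list)
    deletions: list[tuple[str, str]] = field(default_factory=list)
    amplicon_efficiency: dict[str, float] = field(default_factory=dict)
    sample_scale: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def _length_sampler_params(lo: int, hi: int, mean: float) -> tuple[float, float]:
    """Location/scale of the log-length normal whose [ln lo, ln hi]
    truncation has the requested arithmetic mean.

    The spread is pinned by treating the printed range as a ~4-sigma
    window in log space; the location is then solved numerically.
    """
    a, b = math.log(lo), math.log(hi)
    sigma = (b - a) / 4.0

    def trunc_mean(mu: float) -> float:
        al, be = (a - mu) / sigma, (b - mu) / sigma
        z = stats.norm.cdf(be) - stats.norm.cdf(al)
        shifted = stats.norm.cdf(be - sigma) - stats.norm.cdf(al - sigma)
        return math.exp(mu + sigma ** 2 / 2) * shifted / z

    mu = optimize.brentq(lambda m: trunc_mean(m) - mean, a, b)
    return mu, sigma


def sample_amplicon_lengths(params: SimulationParams, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    lo, hi = params.amplicon_length_bounds
    mu, sigma = _length_sampler_params(lo, hi, params.amplicon_length_mean)
    a, b = (math.log(lo) - mu) / sigma, (math.log(hi) - mu) / sigma
    logs = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n,
                               random_state=rng)
    return np.clip(np.rint(np.exp(logs)).astype(int), lo, hi)


def generate_panel(params: SimulationParams,
                   ) -> tuple[list[Amplicon], list[GenomicRegion]]:
    """Amplicon panel plus the exonic targets it captures.

    Each gene sits on its own chromosome. A ``tiling_fraction`` of
    amplicons overlap a neighbour (~30% of their length) and share a
    tiling group with it; the rest are disjoint. Exons are the amplicon
    interiors minus the primer flanks, hence always inside the capture.
    """
    params.validate()
    rng = _stage_rng(params.seed, "panel")
    panel: list[Amplicon] = []
    exons: list[GenomicRegion] = []
    m = params.amplicons_per_gene
    n_pairs = int(round(params.tiling_fraction * m / 2.0))
    for g in range(params.n_genes):
        gene = f"GENE{g + 1:02d}"
        chrom = f"chr{g + 1}"
        lengths = sample_amplicon_lengths(params, m, rng)
        # pick which amplicons tile onto their predecessor, no two adjacent
        tilers: set[int] = set()
        eligible = list(range(1, m))
        rng.shuffle(eligible)
        for idx in eligible:
            if len(tilers) >= n_pairs:
                break
            if idx - 1 not in tilers and idx + 1 not in tilers:
                tilers.add(idx)
        cursor = 1000
        group_of: dict[int, str] = {}
        for i, L in enumerate(lengths):
            L = int(L)
            if i in tilers:
                overlap = min(int(round(0.3 * L)),
                              panel[-1].length - 1 if panel else 0, L - 1)
                start = cursor - overlap
                group = f"{gene}_tg{i}"
                group_of[i - 1] = group_of.get(i - 1, group)
                group_of[i] = group
            else:
                start = cursor + int(rng.integers(50, 200))
            region = GenomicRegion(chrom, start, start + L,
                                   name=f"{gene}-{i + 1}", gene=gene)
            panel.append(Amplicon(region, f"{gene}-{i + 1}", None))
            cursor = start + L
        # attach tiling groups (predecessors get theirs retroactively)
        base = len(panel) - m
        for i, group in group_of.items():
            a = panel[base + i]
            panel[base + i] = Amplicon(a.region, a.assay_id, group)
        for i in range(m):
            a = panel[base + i]
            f = params.primer_flank
            if a.length > 2 * f + 1:
                exons.append(GenomicRegion(
                    chrom, a.region.start + f, a.region.end - f,
                    name=f"{gene}_ex{i + 1}", gene=gene))
    return panel, exons


# ---------------------------------------------------------------------------
# Depth simulation
# ---------------------------------------------------------------------------

def expand_deletions(panel: Sequence[Amplicon],
                     deletion_assays: Sequence[tuple[str, str]],
                     ) -> set[tuple[str, str]]:
    """Close the deleted (sample, assay) set over tiling groups.

    A homozygous genomic deletion removes the template for every assay
    overlapping it, so deleting one member of a tiling group deletes its
    partners for that sample too.
    """
    group_of = {a.assay_id: a.tiling_group for a in panel}
    members: dict[str, list[str]] = {}
    for a in panel:
        if a.tiling_group is not None:
            members.setdefault(a.tiling_group, []).append(a.assay_id)
    expanded: set[tuple[str, str]] = set()
    for s, assay in deletion_assays:
        expanded.add((s, assay))
        g = group_of.get(assay)
        if g is not None:
            expanded.update((s, m) for m in members[g])
    return expanded


def _taper(L: int, read_length: int) -> np.ndarray:
    ramp = min(read_length, (L + 1) // 2)
    i = np.arange(1, L + 1, dtype=float)
    return np.minimum(1.0, np.minimum(i / ramp, (L - i + 1) / ramp))


def simulate_depth(panel: Sequence[Amplicon], samples: Sequence[str],
                   params: SimulationParams,
                   ) -> tuple[list[DepthTrack], TruthSet]:
    """Per-base depth for every sample over the panel, plus the truth set.

    Expected depth at a base of amplicon ``a`` for sample ``s`` is
    ``sample_scale(s) * efficiency(a) * noise(s, a) * taper(base)``;
    bases under two tiling amplicons receive the sum of both
    contributions. Deleted pairs are replaced by Poisson stray reads.
    """
    params.validate()
    rng = _stage_rng(params.seed, "depth")
    assay_ids = {a.assay_id for a in panel}
    for s, a in params.deletion_assays:
        if s not in samples:
            raise AmpliQCError(f"deletion_assays: unknown sample {s!r}")
        if a not in assay_ids:
            raise AmpliQCError(f"deletion_assays: unknown assay {a!r}")
    deleted = expand_deletions(panel, params.deletion_assays)

    sd_a = params.amplicon_effect_sd
    eff = {a.assay_id: float(np.exp(rng.normal(-sd_a ** 2 / 2, sd_a)))
           if sd_a > 0 else 1.0 for a in panel}
    sd_s = params.sample_scale_sd
    scale = {s: params.sample_depth_scale
             * (float(np.exp(rng.normal(-sd_s ** 2 / 2, sd_s)))
                if sd_s > 0 else 1.0) for s in samples}

    positions = target_positions(a.region for a in panel)
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in positions:
        pos_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    pos_by_chrom = {c: np.asarray(p, dtype=np.int64)
                    for c, p in pos_by_chrom.items()}
    accum = {s: {c: np.zeros(len(p)) for c, p in pos_by_chrom.items()}
             for s in samples}

    sd_n = params.noise_sd
    for a in panel:
        r = a.region
        chrom_pos = pos_by_chrom[r.chrom]
        lo = int(np.searchsorted(chrom_pos, r.start + 1))
        hi = lo + r.length
        w = _taper(r.length, params.read_length)
        for s in samples:
            if (s, a.assay_id) in deleted:
                accum[s][r.chrom][lo:hi] += rng.poisson(
                    params.stray_depth, r.length)
            else:
                noise = float(np.exp(rng.normal(-sd_n ** 2 / 2, sd_n))) \
                    if sd_n > 0 else 1.0
                accum[s][r.chrom][lo:hi] += scale[s] * eff[a.assay_id] \
                    * noise * w
    tracks = []
    for s in samples:
        t = DepthTrack(s)
        for chrom, pos in pos_by_chrom.items():
            t.add_chrom(chrom, pos, np.rint(accum[s][chrom]))
        tracks.append(t)
    truth = TruthSet(deletions=sorted(deleted),
                     amplicon_efficiency=eff, sample_scale=scale)
    return tracks, truth


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(panel: Sequence[Amplicon], samples: Sequence[str],
                  params: SimulationParams, truth: TruthSet,
                  ) -> list[QpcrWell]:
    """Nanowell qPCR reactions for every sample x assay x replicate.

    Cq = intercept - slope * log2(efficiency x relative sample scale)
    + Gaussian noise, clipped to [0, 40]. Deleted pairs read the
    sentinel (Cq 40, fluorescence 0); an independent ``dropout_rate``
    fraction of the remaining wells is pushed into (29, 40].
    """
    params.validate()
    rng = _stage_rng(params.seed, "qpcr")
    deleted = expand_deletions(panel, params.deletion_assays)
    wells: list[QpcrWell] = []
    lo29 = float(np.nextafter(29.0, 40.0))
    for si, s in enumerate(samples):
        chip = f"chip{si // 4 + 1}"
        quadrant = si % 4 + 1
        rel = truth.sample_scale.get(s, params.sample_depth_scale) \
            / params.sample_depth_scale
        for a in panel:
            for r in range(1, params.n_qpcr_replicates + 1):
                if (s, a.assay_id) in deleted:
                    wells.append(QpcrWell(chip, quadrant, s, a.assay_id,
                                          40.0, 0.0, r))
                    continue
                if rng.uniform() < params.dropout_rate:
                    cq = float(rng.uniform(lo29, 40.0))
                    fluor = float(rng.uniform(10.0, 500.0))
                else:
                    q = truth.amplicon_efficiency.get(a.assay_id, 1.0) * rel
                    cq = params.cq_intercept \
                        - params.cq_slope * math.log2(q) \
                        + float(rng.normal(0.0, params.cq_noise_sd))
                    cq = float(np.clip(cq, 0.0, 40.0))
                    fluor = float(max(200.0, rng.normal(3800.0, 600.0)))
                wells.append(QpcrWell(chip, quadrant, s, a.assay_id,
                                      cq, fluor, r))
    return wells


# ---------------------------------------------------------------------------
# Variant injection
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def inject_variants(panel: Sequence[Amplicon], samples: Sequence[str],
                    params: SimulationParams, tracks: Sequence[DepthTrack],
                    truth: TruthSet | None = None,
                    sites: Sequence[tuple[str, str, int, str, str, str]] | None = None,
                    ) -> tuple[list[VariantCall], TruthSet]:
    """Plant variants and emit the calls a simple caller would make.

    Each site draws ``alt_depth ~ Binomial(site depth, vaf)`` with vaf
    ``vaf_het`` or ``vaf_hom``; a call is emitted only when the alt depth
    reaches the caller minimum (>= min_alt_reads and >= min_alt_frac of
    the site depth). The called genotype follows the *observed* allele
    fraction (hom_alt above 0.75), so allelic-ratio drift can flip it.
    Explicit ``sites`` — (sample, chrom, pos, ref, alt, genotype) — must
    lie inside the panel.
    """
    params.validate()
    rng = _stage_rng(params.seed, "variants")
    if truth is None:
        truth = TruthSet()
    track_ix = {t.sample: t for t in tracks}
    covering = {}
    for a in panel:
        covering[a.region.chrom] = covering.get(a.region.chrom, [])
        covering[a.region.chrom].append(a.region)

    def inside_panel(chrom: str, pos: int) -> bool:
        return any(r.contains(chrom, pos) for r in covering.get(chrom, []))

    planted: list[tuple[str, str, int, str, str, str]] = []
    if sites is not None:
        for site in sites:
            if not inside_panel(site[1], site[2]):
                raise AmpliQCError(
                    f"inject_variants: {site[1]}:{site[2]} outside panel")
        planted = list(sites)
    else:
        used: set[tuple[str, str, int]] = set()
        guard = 0
        while len(planted) < params.n_variants and guard < 50 * params.n_variants:
            guard += 1
            a = panel[int(rng.integers(len(panel)))]
            pos = int(rng.integers(a.region.start + 1, a.region.end + 1))
            s = samples[int(rng.integers(len(samples)))]
            if (s, a.region.chrom, pos) in used:
                continue
            used.add((s, a.region.chrom, pos))
            ref = _BASES[int(rng.integers(4))]
            if rng.uniform() < params.indel_fraction:
                alt = ref + _BASES[int(rng.integers(4))]
            else:
                alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            gt = "hom_alt" if rng.uniform() < params.hom_fraction else "het"
            planted.append((s, a.region.chrom, pos, ref, alt, gt))

    calls: list[VariantCall] = []
    for s, chrom, pos, ref, alt, gt in planted:
        truth.variants.append((s, chrom, pos, ref, alt, gt))
        track = track_ix.get(s)
        d = int(track.depth(chrom, pos)) if track is not None else 0
        if d == 0:
            continue
        vaf = params.vaf_hom if gt == "hom_alt" else params.vaf_het
        alt_d = int(rng.binomial(d, vaf))
        if alt_d < params.min_alt_reads or alt_d < params.min_alt_frac * d:
            continue
        called_gt = "hom_alt" if alt_d / d >= 0.75 else "het"
        calls.append(VariantCall(sample=s, chrom=chrom, pos=pos, ref=ref,
                                 alt=alt, genotype=called_gt,
                                 ref_depth=d - alt_d, alt_depth=alt_d))
    return calls, truth


# ---------------------------------------------------------------------------
# Library metrics
# ---------------------------------------------------------------------------

def simulate_sample_metrics(panel: Sequence[Amplicon],
                            exons: Sequence[GenomicRegion],
                            samples: Sequence[str], params: SimulationParams,
                            tracks: Sequence[DepthTrack],
                            ) -> list[SampleMetricsRow]:
    """Per-sample read accounting consistent with the simulated depth.

    On-target deduplicated reads are implied by the depth (total depth /
    read length); total reads back out of the configured mapped,
    on-target and duplicate fractions, with the duplicate count drawn
    binomially so the configured rate is recoverable from the output.
    """
    from .coverage_qc import per_sample_stats  # local: avoid import cycle

    params.validate()
    rng = _stage_rng(params.seed, "metrics")
    amp_regions = [a.region for a in panel]
    rows = []
    track_ix = {t.sample: t for t in tracks}
    for s in samples:
        track = track_ix[s]
        amp = per_sample_stats(track, amp_regions, "amplicon")
        exn = per_sample_stats(track, exons, "exon") if exons else amp
        dedup_reads = amp.mean_cov * amp.n_bases / params.read_length
        mapped = float(np.clip(rng.normal(params.mapped_frac, 0.002), 0, 1))
        on_t = float(np.clip(rng.normal(params.on_target_frac, 0.03), 0, 1))
        denom = (1.0 - params.duplicate_rate) * mapped * on_t
        total = max(1, int(round(dedup_reads / denom)))
        n_on = max(1, int(round(total * mapped * on_t)))
        dup = int(rng.binomial(n_on, params.duplicate_rate))
        rows.append(SampleMetricsRow(
            sample=s, n_pcr_replicates=params.n_qpcr_replicates,
            total_reads=total, mapped_frac=mapped, on_target_frac=on_t,
            duplicate_frac=dup / n_on,
            amplicon_mean_cov=amp.mean_cov, amplicon_sd_cov=amp.sd_cov,
            exon_mean_cov=exn.mean_cov, exon_sd_cov=exn.sd_cov))
    return rows


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedBundle:
    params: SimulationParams
    panel: list[Amplicon]
    exons: list[GenomicRegion]
    samples: list[str]
    tracks: list[DepthTrack]
    wells: list[QpcrWell]
    calls: list[VariantCall]
    metrics: list[SampleMetricsRow]
    truth: TruthSet


def simulate_all(params: SimulationParams) -> SimulatedBundle:
    """Run every stage in dependency order from one parameter set."""
    params.validate()
    panel, exons = generate_panel(params)
    samples = params.sample_names
    tracks, truth = simulate_depth(panel, samples, params)
    wells = simulate_qpcr(panel, samples, params, truth)
    calls, truth = inject_variants(panel, samples, params, tracks, truth)
    metrics = simulate_sample_metrics(panel, exons, samples, params, tracks)
    return SimulatedBundle(params, panel, exons, samples, tracks, wells,
                           calls, metrics, truth)
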