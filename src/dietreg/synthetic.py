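"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the shape of a liver regulatory-genomics study: a
random genome with controllable GC content, spaced multi-exon gene models,
accessible-region peaks placed so that their true annotation category is
known by construction, transcription-factor motif instances planted into a
known fraction of peak windows, sequencing reads piled around peak summits,
and a two-contrast expression table whose differential genes fall into four
direction categories (up/up, down/down, up/down, down/up versus a common
reference).

Default parameters are the study conditions the pipeline is validated
under: 100 bp peak windows, a 0.5 planting rate, 50 reads per peak, the
direction counts (255, 183, 186, 71) with a 12,000-gene universe, and the
eight-category mix observed for accessible chromatin (41% intron, 12%
proximal promoter, 9% distal promoter, 8% downstream, 3% coding exon,
3% 5'UTR, 1% 3'UTR, 23% distal intergenic).

Determinism contract: the same :class:`SyntheticConfig` yields byte-identical
output files. Every operation derives its RNG from ``(config.seed, salt)``
with a distinct salt, so stages are independently reproducible.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import RegionAnnotator, RegionCategory
from .intervals import GeneModel, GenomicInterval, Peak, ReadTag
from . import io as dio
from .motifs import PSSM, write_transfac

#: accessible-chromatin category mix used as the default peak placement truth
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "intron": 0.41,
    "proximal_promoter": 0.12,
    "distal_promoter": 0.09,
    "downstream": 0.08,
    "coding_exon": 0.03,
    "utr5": 0.03,
    "utr3": 0.01,
    "distal_intergenic": 0.23,
}

_GENE_MARGIN = 13_000  # free flank per gene slot; keeps 5 kb windows disjoint
_MAX_GENE_LEN = 8_000
_INTERGENIC_CLEARANCE = 6_000  # > 5 kb flank, so placement is unambiguous


class PlacementError(RuntimeError):
    """Raised when genes or peaks cannot be placed under the constraints."""


@dataclass
class SyntheticConfig:
    seed: int = 0
    genome_length: int = 800_000
    gc_fraction: float = 0.5
    n_genes: int = 20
    n_peaks: int = 100
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    planting_rate: float = 0.5
    read_depth: int = 50
    direction_counts: tuple[int, int, int, int] = (255, 183, 186, 71)
    universe_size: int = 12_000
    peak_width: int = 100
    read_sd: float = 100.0
    read_truncation: int = 300
    contig_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be strictly between 0 and 1")
        if not (0.0 <= self.planting_rate <= 1.0):
            raise ValueError("planting_rate must be in [0, 1]")
        for name in ("n_genes", "n_peaks", "read_depth", "universe_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(c < 0 for c in self.direction_counts):
            raise ValueError("direction_counts must be non-negative")
        if sum(self.direction_counts) > self.universe_size:
            raise ValueError("direction_counts exceed the universe size")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1 (got {total})")
        for key, frac in self.category_mix.items():
            RegionCategory(key)  # raises on unknown category
            if frac < 0:
                raise ValueError(f"negative fraction for {key}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "direction_counts" in data:
            data["direction_counts"] = tuple(data["direction_counts"])
        return cls(**data)


def _rng(config: SyntheticConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


# ---------------------------------------------------------------- genome

def generate_genome(config: SyntheticConfig) -> dict[str, str]:
    """I.i.d. random genome: P(G) = P(C) = gc_fraction / 2."""
    rng = _rng(config, 0)
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.genome_length, p=p)
    return {config.contig_name: bases.tobytes().decode("ascii")}


# ---------------------------------------------------------------- genes

def _gene_segments(rng: np.random.Generator) -> list[tuple[str, int]]:
    """Transcript-order (feature, length) segments of one gene."""
    return [
        ("utr5", int(rng.integers(700, 901))),
        ("cds", int(rng.integers(300, 501))),
        ("intron", int(rng.integers(1400, 2001))),
        ("cds", int(rng.integers(300, 501))),
        ("intron", int(rng.integers(1400, 2001))),
        ("cds", int(rng.integers(300, 501))),
        ("utr3", int(rng.integers(400, 601))),
    ]


def generate_gene_models(
    config: SyntheticConfig, genome: dict[str, str]
) -> list[GeneModel]:
    """Non-overlapping multi-exon genes, one per slot, random strand.

    Slots keep >= 2 * 13 kb between neighbouring genes so that promoter /
    downstream flanks and the +/-10 kb TSS windows of different genes never
    collide.
    """
    if config.n_genes == 0:
        return []
    rng = _rng(config, 1)
    contig = config.contig_name
    length = len(genome[contig])
    slot = length // config.n_genes
    if slot < 2 * _GENE_MARGIN + _MAX_GENE_LEN:
        raise PlacementError(
            f"genome too short for {config.n_genes} genes: slot {slot} bp < "
            f"{2 * _GENE_MARGIN + _MAX_GENE_LEN} bp required"
        )
    genes = []
    for i in range(config.n_genes):
        segments = _gene_segments(rng)
        gene_len = sum(l for _, l in segments)
        strand = "+" if rng.integers(2) == 0 else "-"
        if strand == "-":
            segments = segments[::-1]
        slack = slot - 2 * _GENE_MARGIN - gene_len
        start = i * slot + _GENE_MARGIN + int(rng.integers(0, slack + 1))
        # walk genomic coordinates; merge contiguous exonic segments
        exons: list[tuple[int, int]] = []
        cds_spans: list[tuple[int, int]] = []
        pos = start
        for feat, seg_len in segments:
            span = (pos, pos + seg_len)
            if feat != "intron":
                if exons and exons[-1][1] == span[0]:
                    exons[-1] = (exons[-1][0], span[1])
                else:
                    exons.append(span)
                if feat == "cds":
                    cds_spans.append(span)
            pos += seg_len
        genes.append(
            GeneModel(
                gene_id=f"gene_{i:04d}",
                chrom=contig,
                start=start,
                end=pos,
                strand=strand,
                exons=exons,
                cds_start=min(s for s, _ in cds_spans),
                cds_end=max(e for _, e in cds_spans),
            )
        )
    return genes


# ---------------------------------------------------------------- peaks

def allocate_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Integer allocation of n peaks to categories (largest remainder)."""
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: math.floor(v) for k, v in raw.items()}
    leftover = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def _allowed_starts(
    ranges: list[tuple[int, int]], forbidden: tuple[int, int] | None
) -> list[tuple[int, int]]:
    """Subtract a closed forbidden start range from closed candidate ranges."""
    if forbidden is None:
        return [r for r in ranges if r[0] <= r[1]]
    flo, fhi = forbidden
    out = []
    for lo, hi in ranges:
        if hi < flo or lo > fhi:
            out.append((lo, hi))
        else:
            if lo <= flo - 1:
                out.append((lo, flo - 1))
            if fhi + 1 <= hi:
                out.append((fhi + 1, hi))
    return [r for r in out if r[0] <= r[1]]


def _pick_start(rng: np.random.Generator, ranges: list[tuple[int, int]]) -> int:
    widths = np.array([hi - lo + 1 for lo, hi in ranges], dtype=float)
    if len(ranges) == 0 or widths.sum() <= 0:
        raise PlacementError("no admissible placement for peak")
    idx = int(rng.choice(len(ranges), p=widths / widths.sum()))
    lo, hi = ranges[idx]
    return int(rng.integers(lo, hi + 1))


def _start_ranges_for_category(
    category: RegionCategory,
    gene: GeneModel,
    genes: list[GeneModel],
    width: int,
    proximal_bp: int = 200,
    flank_bp: int = 5000,
) -> list[tuple[int, int]]:
    """Closed ranges of admissible peak starts for a category on one gene."""
    tss = gene.tss
    # starts whose peak [s, s+width) intersects the proximal window around TSS
    forbidden = (tss - proximal_bp - width + 1, tss + proximal_bp)
    W = width

    def spans_to_ranges(spans):
        return [(s, e - W) for s, e in spans if e - s >= W]

    if category == RegionCategory.proximal_promoter:
        # peak center within +/-(proximal - width/2) of TSS: always proximal
        half = proximal_bp - W // 2 - 1
        return [(tss - half - W // 2, tss + half - W // 2)]
    if category == RegionCategory.utr5:
        return _allowed_starts(spans_to_ranges(gene.utr5), forbidden)
    if category == RegionCategory.utr3:
        return _allowed_starts(spans_to_ranges(gene.utr3), forbidden)
    if category == RegionCategory.coding_exon:
        return _allowed_starts(spans_to_ranges(gene.coding_exons), forbidden)
    if category == RegionCategory.intron:
        return _allowed_starts(spans_to_ranges(gene.introns), forbidden)
    if category == RegionCategory.distal_promoter:
        if gene.strand == "+":
            up = (max(0, tss - flank_bp), tss)
        else:
            up = (tss + 1, tss + 1 + flank_bp)
        return _allowed_starts(spans_to_ranges([up]), forbidden)
    if category == RegionCategory.downstream:
        if gene.strand == "+":
            down = (gene.end, gene.end + flank_bp)
        else:
            down = (max(0, gene.start - flank_bp), gene.start)
        return _allowed_starts(spans_to_ranges([down]), forbidden)
    raise ValueError(f"category {category} is not gene-anchored")


def _intergenic_ranges(
    genes: list[GeneModel], genome_length: int, width: int
) -> list[tuple[int, int]]:
    bounds = sorted((g.start, g.end) for g in genes)
    gaps = []
    prev_end = 0
    first = True
    for s, e in bounds:
        lo = 0 if first else prev_end + _INTERGENIC_CLEARANCE
        hi = s - _INTERGENIC_CLEARANCE - width
        if hi >= lo:
            gaps.append((lo, hi))
        prev_end = e
        first = False
    lo = (prev_end + _INTERGENIC_CLEARANCE) if bounds else 0
    hi = genome_length - width
    if hi >= lo:
        gaps.append((lo, hi))
    return gaps


def generate_peaks(
    config: SyntheticConfig, genes: list[GeneModel]
) -> list[Peak]:
    """Peaks whose true category (retained on ``Peak.label``) is guaranteed
    to equal the annotation module's call, verified at construction."""
    rng = _rng(config, 2)
    counts = allocate_counts(config.category_mix, config.n_peaks)
    W = config.peak_width
    contig = config.contig_name
    annotator = RegionAnnotator().fit(genes)
    gene_anchored = [c for c, n in counts.items() if n > 0 and c != "distal_intergenic"]
    if gene_anchored and not genes:
        raise PlacementError(
            f"categories {gene_anchored} require gene models, but none were given"
        )
    peaks: list[Peak] = []
    for cat_name in sorted(counts):
        category = RegionCategory(cat_name)
        for _ in range(counts[cat_name]):
            if category == RegionCategory.distal_intergenic:
                ranges = _intergenic_ranges(genes, config.genome_length, W)
                if not ranges:
                    raise PlacementError("no intergenic space for distal peaks")
                start = _pick_start(rng, ranges)
            else:
                gene = genes[int(rng.integers(len(genes)))]
                ranges = _start_ranges_for_category(category, gene, genes, W)
                if not ranges:
                    raise PlacementError(
                        f"gene {gene.gene_id} cannot host a {category.value} peak"
                    )
                start = _pick_start(rng, ranges)
            iv = GenomicInterval(contig, start, start + W, ".")
            got = annotator.annotate_one(iv).category
            if got != category:
                raise PlacementError(
                    f"constructed {category.value} peak at {start} classifies as {got.value}"
                )
            peaks.append(
                Peak(interval=iv, summit=start + W // 2, label=category.value)
            )
    order = rng.permutation(len(peaks))
    return [
        replace(peaks[i], name=f"peak_{j:05d}") for j, i in enumerate(order)
    ]


# ---------------------------------------------------------------- motifs & planting

def make_random_pssm(
    name: str, length: int = 8, p_dominant: float = 0.85, seed: int = 0
) -> PSSM:
    """A sharp random motif: one dominant base per column."""
    rng = np.random.default_rng(seed)
    probs = np.full((length, 4), (1.0 - p_dominant) / 3.0)
    dom = rng.integers(0, 4, size=length)
    probs[np.arange(length), dom] = p_dominant
    return PSSM(name, probs)


def make_motif_library(
    n_decoys: int = 20,
    length: int = 8,
    seed: int = 0,
    planted_name: str = "PLANTED",
) -> tuple[PSSM, list[PSSM]]:
    """(planted motif, decoy list); the planted motif is sharper so its
    consensus is unambiguous."""
    planted = make_random_pssm(planted_name, length=length, p_dominant=0.91, seed=seed)
    decoys = [
        make_random_pssm(f"decoy_{i:02d}", length=length, seed=seed + 1 + i)
        for i in range(n_decoys)
    ]
    return planted, decoys


def plant_motif_instances(
    peaks: list[Peak],
    pssm: PSSM,
    config: SyntheticConfig,
    genome: dict[str, str],
    sample: bool = False,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write motif instances into a ``planting_rate`` fraction of peak
    windows; returns the edited genome and a truth table.

    Exactly ``round(planting_rate * n_peaks)`` peaks receive one instance,
    written at a random offset within the ``peak_width`` window centered on
    the summit. By default the consensus is written (deterministic LLR_norm
    maximum); with ``sample=True`` a sequence is drawn from the PSSM.
    """
    k = len(pssm)
    W = config.peak_width
    if k >= W:
        raise ValueError(f"motif length {k} must be < window width {W}")
    rng = _rng(config, 3)
    n_plant = int(round(config.planting_rate * len(peaks)))
    chosen = sorted(rng.choice(len(peaks), size=n_plant, replace=False)) if n_plant else []
    edited = {c: bytearray(s, "ascii") for c, s in genome.items()}
    rows = []
    chosen_set = set(int(i) for i in chosen)
    for i, peak in enumerate(peaks):
        planted = i in chosen_set
        position = offset = None
        if planted:
            win_start = peak.summit - W // 2
            offset = int(rng.integers(0, W - k + 1))
            position = win_start + offset
            if sample:
                instance = "".join(
                    "ACGT"[rng.choice(4, p=pssm.probs[j])] for j in range(k)
                )
            else:
                instance = pssm.consensus
            edited[peak.interval.chrom][position : position + k] = instance.encode()
        rows.append(
            {"peak": peak.name, "planted": planted, "position": position, "offset": offset}
        )
    truth = pd.DataFrame(rows)
    return {c: bytes(b).decode("ascii") for c, b in edited.items()}, truth


# ---------------------------------------------------------------- reads

def generate_reads(peaks: list[Peak], config: SyntheticConfig) -> list[ReadTag]:
    """``read_depth`` single-base 5' tags per peak, normally scattered around
    the summit and truncated (clipped) to +/- ``read_truncation`` bp."""
    rng = _rng(config, 4)
    reads = []
    for peak in peaks:
        offsets = np.clip(
            rng.normal(0.0, config.read_sd, size=config.read_depth),
            -config.read_truncation,
            config.read_truncation,
        )
        strands = rng.choice(["+", "-"], size=config.read_depth)
        for off, strand in zip(offsets, strands):
            pos = int(np.clip(peak.summit + round(off), 0, config.genome_length - 1))
            reads.append(ReadTag(peak.interval.chrom, pos, str(strand)))
    return reads


# ---------------------------------------------------------------- expression

def generate_expression_table(config: SyntheticConfig) -> pd.DataFrame:
    """Two-contrast expression table with the configured direction counts.

    The four differential groups satisfy the differential filter in both
    contrasts with the configured fold-change sign pattern; every other gene
    fails the filter in both contrasts (small fold-change, large q; a tenth
    of them are additionally below the 0.1 FPKM detection floor).
    """
    rng = _rng(config, 5)
    n = config.universe_size
    up_up, down_down, up_down, down_up = config.direction_counts
    n_diff = up_up + down_down + up_down + down_up

    signs = np.zeros((n, 2))
    signs[:up_up] = (1, 1)
    signs[up_up : up_up + down_down] = (-1, -1)
    signs[up_up + down_down : up_up + down_down + up_down] = (1, -1)
    signs[up_up + down_down + up_down : n_diff] = (-1, 1)

    lfc = np.empty((n, 2))
    q = np.empty((n, 2))
    lfc[:n_diff] = rng.uniform(0.6, 3.0, size=(n_diff, 2)) * signs[:n_diff]
    q[:n_diff] = rng.uniform(1e-6, 0.04, size=(n_diff, 2))
    lfc[n_diff:] = rng.uniform(-0.45, 0.45, size=(n - n_diff, 2))
    q[n_diff:] = rng.uniform(0.5, 1.0, size=(n - n_diff, 2))

    fpkm = rng.uniform(1.0, 50.0, size=(n, 3))
    n_null = n - n_diff
    silent = rng.random(n_null) < 0.1  # nulls below the detection floor
    fpkm[n_diff:][silent] = rng.uniform(0.0, 0.09, size=(int(silent.sum()), 3))

    perm = rng.permutation(n)  # scatter groups across gene ids
    df = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(n)],
            "log2fc_A": lfc[perm, 0],
            "q_A": q[perm, 0],
            "log2fc_B": lfc[perm, 1],
            "q_B": q[perm, 1],
            "fpkm_cd": fpkm[perm, 0],
            "fpkm_a": fpkm[perm, 1],
            "fpkm_b": fpkm[perm, 2],
        }
    )
    return df


# ---------------------------------------------------------------- orchestration

def simulate(config: SyntheticConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Generate and write every pipeline input; returns the file map."""
    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(outdir, name)  # noqa: E731

    genome = generate_genome(config)
    genes = generate_gene_models(config, genome)
    peaks = generate_peaks(config, genes)
    planted, decoys = make_motif_library(seed=config.seed)
    genome, planted_truth = plant_motif_instances(peaks, planted, config, genome)
    reads = generate_reads(peaks, config)
    expr = generate_expression_table(config)

    dio.write_fasta(genome, out("genome.fa"))
    dio.write_bed12(genes, out("genes.bed12"))
    dio.write_peaks_bed(peaks, out("peaks.bed"))
    pd.DataFrame(
        {"peak": [p.name for p in peaks], "category": [p.label for p in peaks]}
    ).to_csv(out("peaks_truth.tsv"), sep="\t", index=False)
    write_transfac([planted] + decoys, out("motifs.transfac"))
    planted_truth.to_csv(out("planted_truth.tsv"), sep="\t", index=False)
    dio.write_reads_bed(reads, out("reads.bed"))
    dio.write_expression_table(expr, out("expression.tsv"))
    return {
        "genome": out("genome.fa"),
        "genes": out("genes.bed12"),
        "peaks": out("peaks.bed"),
        "peaks_truth": out("peaks_truth.tsv"),
        "motifs": out("motifs.transfac"),
        "planted_truth": out("planted_truth.tsv"),
        "reads": out("reads.bed"),
        "expression": out("expression.tsv"),
    }
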