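"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA is read through :mod:`pyfaidx`; GTF through :mod:`gffutils`; BED and
the expression TSV schema are thin pandas round-trips. All writers are
deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .intervals import GeneModel, GenomicInterval, Peak, ReadTag

EXPRESSION_COLUMNS = [
    "gene_id",
    "log2fc_A",
    "q_A",
    "log2fc_B",
    "q_B",
    "fpkm_cd",
    "fpkm_a",
    "fpkm_b",
]


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------- BED

def write_bed6(
    records: Iterable[tuple[str, int, int, str, int | float, str]],
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return df


def write_peaks_bed(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    """BED6 dialect for peaks: the score column holds the summit offset
    (``summit - start``), so ``summit = start + score``."""
    rows = []
    for p in peaks:
        iv = p.interval
        rows.append((iv.chrom, iv.start, iv.end, p.name or ".", p.summit - iv.start, iv.strand))
    write_bed6(rows, path)


def read_peaks_bed(path: str | os.PathLike) -> list[Peak]:
    df = read_bed6(path)
    peaks = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        peaks.append(Peak(interval=iv, summit=int(row.start) + int(row.score), name=row.name))
    return peaks


def write_reads_bed(reads: Iterable[ReadTag], path: str | os.PathLike) -> None:
    """BED6 dialect for read tags: one-base records at the read 5' end."""
    rows = [
        (r.chrom, r.five_prime, r.five_prime + 1, f"read_{i}", 0, r.strand)
        for i, r in enumerate(reads)
    ]
    write_bed6(rows, path)


def read_reads_bed(path: str | os.PathLike) -> list[ReadTag]:
    df = read_bed6(path)
    return [ReadTag(row.chrom, int(row.start), row.strand) for row in df.itertuples(index=False)]


# ---------------------------------------------------------------- BED12 gene models

def write_bed12(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, e in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.cds_start}\t{g.cds_end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            cds_start, cds_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return genes


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Build gene models from a GTF file (1-based inclusive -> half-open here).

    Requires ``exon`` features carrying a ``gene_id`` attribute; ``CDS``
    features, when present, set the coding span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        span = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            exons.setdefault(gid, []).append((feat.seqid, feat.strand, *span))
        elif feat.featuretype == "CDS":
            cds.setdefault(gid, []).append(span)
    genes = []
    for gid, ex in sorted(exons.items()):
        chrom, strand = ex[0][0], ex[0][1]
        spans = sorted((s, e) for _, _, s, e in ex)
        cspans = cds.get(gid)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                start=spans[0][0],
                end=spans[-1][1],
                strand=strand,
                exons=spans,
                cds_start=min(s for s, _ in cspans) if cspans else None,
                cds_end=max(e for _, e in cspans) if cspans else None,
            )
        )
    return genes


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Dispatch on extension: .gtf/.gff -> GTF reader, otherwise BED12."""
    p = str(path).lower()
    if p.endswith((".gtf", ".gff", ".gff3")):
        return read_gtf(path)
    return read_bed12(path)


# ---------------------------------------------------------------- TSV / tracks

def write_expression_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read gene sets from GMT (term <tab> description <tab> gene...)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            out[fields[0]] = set(g for g in fields[2:] if g)
    return out


def write_bedgraph(
    chrom: str, start: int, values, path: str | os.PathLike
) -> None:
    """Write per-base values as a run-length-collapsed bedGraph."""
    with open(path, "w") as fh:
        run_start = 0
        n = len(values)
        for i in range(1, n + 1):
            if i == n or values[i] != values[run_start]:
                v = float(values[run_start])
                fh.write(f"{chrom}\t{start + run_start}\t{start + i}\t{v:.6g}\n")
                run_start = i
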