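"""Genomic coordinate primitives.

All coordinates are 0-based, half-open (BED convention) throughout the
package; conversion to/from 1-based happens only at GTF boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a contig.

    Parameters
    ----------
    chrom : str
        Contig identifier.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        One of ``"+"``, ``"-"``, ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlaps_span(self, start: int, end: int) -> bool:
        """Any-overlap (>= 1 shared base) with the half-open span [start, end)."""
        return self.start < end and start < self.end

    def distance_to_point(self, pos: int) -> int:
        """Minimum distance from any base of the interval to a point (0 if inside)."""
        if self.start <= pos < self.end:
            return 0
        return min(abs(self.start - pos), abs(self.end - 1 - pos))


@dataclass
class GeneModel:
    """A gene/transcript model with exon and CDS substructure.

    ``exons`` are genomic half-open spans, sorted, non-overlapping.
    ``cds_start < cds_end`` are genomic coordinates independent of strand.
    The TSS is the first transcribed base: ``start`` on the + strand,
    ``end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        if self.cds_start is None:
            self.cds_start = self.start
        if self.cds_end is None:
            self.cds_end = self.end

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return out

    def _exon_overlap(self, lo: int, hi: int) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                out.append((a, b))
        return out

    @property
    def coding_exons(self) -> list[tuple[int, int]]:
        return self._exon_overlap(self.cds_start, self.cds_end)

    @property
    def utr5(self) -> list[tuple[int, int]]:
        """Exonic spans 5' of the CDS in transcription order (genomic coords)."""
        if self.strand == "+":
            return self._exon_overlap(self.start, self.cds_start)
        return self._exon_overlap(self.cds_end, self.end)

    @property
    def utr3(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return self._exon_overlap(self.cds_end, self.end)
        return self._exon_overlap(self.start, self.cds_start)


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval with a single-base summit inside it."""

    interval: GenomicInterval
    summit: int
    name: str = ""
    enrichment_p: float | None = None
    label: str | None = None  # ground-truth category for synthetic peaks

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )


@dataclass(frozen=True)
class ReadTag:
    """An aligned sequencing read reduced to its 5' base and strand."""

    chrom: str
    five_prime: int
    strand: str

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError("negative 5' coordinate")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be +/-, got {self.strand!r}")
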