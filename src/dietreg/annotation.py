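"""Annotation of accessible-chromatin regions relative to gene models.

Each region receives exactly one of eight categories:

* ``proximal_promoter`` — within 200 bp of a TSS (either side, inclusive);
* ``distal_promoter``  — within 5 kb upstream of a gene (beyond the proximal
  window, by precedence);
* ``downstream``       — within 5 kb downstream of the gene end;
* ``utr5`` / ``utr3`` / ``coding_exon`` / ``intron`` — the region intersects
  (>= 1 shared base) that transcript feature;
* ``distal_intergenic`` — none of the above for any gene.

The category listing order above is not the precedence. When several rules
fire, precedence is: proximal_promoter > utr5 > utr3 > coding_exon > intron >
distal_promoter > downstream > distal_intergenic — transcribed-feature
identity wins over flanking windows. Among genes yielding the same category,
the gene whose TSS is nearest (by unsigned distance to the region midpoint)
is reported. All window boundaries are inclusive.

Region-to-gene TSS mapping (the +/-10 kb association used to pool regions
near differential gene sets) uses the region midpoint, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator

from .intervals import GeneModel, GenomicInterval


class RegionCategory(str, Enum):
    proximal_promoter = "proximal_promoter"
    distal_promoter = "distal_promoter"
    downstream = "downstream"
    coding_exon = "coding_exon"
    intron = "intron"
    utr5 = "utr5"
    utr3 = "utr3"
    distal_intergenic = "distal_intergenic"


#: Rank used to resolve regions hit by multiple rules (lower wins).
CATEGORY_PRECEDENCE: dict[RegionCategory, int] = {
    RegionCategory.proximal_promoter: 0,
    RegionCategory.utr5: 1,
    RegionCategory.utr3: 2,
    RegionCategory.coding_exon: 3,
    RegionCategory.intron: 4,
    RegionCategory.distal_promoter: 5,
    RegionCategory.downstream: 6,
    RegionCategory.distal_intergenic: 7,
}


@dataclass(frozen=True)
class AnnotatedRegion:
    region: GenomicInterval
    category: RegionCategory
    gene: str | None
    tss_distance: int | None
    """Signed midpoint-to-TSS offset in transcription orientation
    (positive = downstream of the TSS)."""


def _categories_for_gene(
    region: GenomicInterval,
    gene: GeneModel,
    proximal_bp: int,
    flank_bp: int,
) -> list[RegionCategory]:
    """All rule hits of one region against one gene (unordered)."""
    if region.chrom != gene.chrom:
        return []
    hits = []
    tss = gene.tss
    if region.distance_to_point(tss) <= proximal_bp:
        hits.append(RegionCategory.proximal_promoter)
    # upstream flank: [tss - flank, tss) on +, (tss, tss + flank] on -
    if gene.strand == "+":
        up = (max(0, tss - flank_bp), tss)
        down = (gene.end, gene.end + flank_bp)
    else:
        up = (tss + 1, tss + 1 + flank_bp)
        down = (max(0, gene.start - flank_bp), gene.start)
    if up[0] < up[1] and region.overlaps_span(*up):
        hits.append(RegionCategory.distal_promoter)
    if down[0] < down[1] and region.overlaps_span(*down):
        hits.append(RegionCategory.downstream)
    for s, e in gene.utr5:
        if region.overlaps_span(s, e):
            hits.append(RegionCategory.utr5)
            break
    for s, e in gene.utr3:
        if region.overlaps_span(s, e):
            hits.append(RegionCategory.utr3)
            break
    for s, e in gene.coding_exons:
        if region.overlaps_span(s, e):
            hits.append(RegionCategory.coding_exon)
            break
    for s, e in gene.introns:
        if region.overlaps_span(s, e):
            hits.append(RegionCategory.intron)
            break
    return hits


def _signed_tss_distance(region: GenomicInterval, gene: GeneModel) -> int:
    d = region.midpoint - gene.tss
    return d if gene.strand == "+" else -d


class RegionAnnotator(BaseEstimator):
    """Classify regions against a fixed set of gene models.

    Parameters
    ----------
    proximal_bp : int
        Half-width of the proximal-promoter window around the TSS (default
        200 bp, both sides, inclusive).
    flank_bp : int
        Extent of the distal-promoter / downstream flanks (default 5 kb).
    tss_window : int
        Half-width for midpoint-based region-to-TSS association (default
        10 kb, inclusive).

    Attributes
    ----------
    genes_ : list[GeneModel]
        Gene models seen by :meth:`fit`.
    """

    def __init__(self, proximal_bp: int = 200, flank_bp: int = 5000, tss_window: int = 10000):
        self.proximal_bp = proximal_bp
        self.flank_bp = flank_bp
        self.tss_window = tss_window

    def fit(self, genes: list[GeneModel], y=None) -> "RegionAnnotator":
        self.genes_ = list(genes)
        # candidate prefilter arrays: any rule can only fire within
        # flank + proximal of the gene span
        self._starts = np.array([g.start for g in self.genes_], dtype=np.int64)
        self._ends = np.array([g.end for g in self.genes_], dtype=np.int64)
        self._chroms = np.array([g.chrom for g in self.genes_])
        self._tss = np.array([g.tss for g in self.genes_], dtype=np.int64)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "genes_"):
            raise RuntimeError("RegionAnnotator is not fitted; call fit(genes) first")

    def annotate_one(self, region: GenomicInterval) -> AnnotatedRegion:
        self._check_fitted()
        best: tuple[int, int, int] | None = None  # (rank, |tss dist|, gene idx)
        if len(self.genes_) > 0:
            margin = self.flank_bp + self.proximal_bp
            mask = (
                (self._chroms == region.chrom)
                & (self._starts - margin < region.end)
                & (region.start < self._ends + margin)
            )
            for idx in np.nonzero(mask)[0]:
                gene = self.genes_[idx]
                for cat in _categories_for_gene(region, gene, self.proximal_bp, self.flank_bp):
                    key = (
                        CATEGORY_PRECEDENCE[cat],
                        abs(region.midpoint - gene.tss),
                        int(idx),
                    )
                    if best is None or key < best:
                        best = key
        if best is None:
            return AnnotatedRegion(region, RegionCategory.distal_intergenic, None, None)
        rank, _, idx = best
        gene = self.genes_[idx]
        cat = next(c for c, r in CATEGORY_PRECEDENCE.items() if r == rank)
        return AnnotatedRegion(region, cat, gene.gene_id, _signed_tss_distance(region, gene))

    def predict(self, regions: list[GenomicInterval]) -> list[RegionCategory]:
        return [self.annotate_one(r).category for r in regions]

    def transform(self, regions: list[GenomicInterval]) -> list[AnnotatedRegion]:
        return [self.annotate_one(r) for r in regions]

    def map_to_tss(
        self, regions: list[GenomicInterval]
    ) -> list[tuple[int, str, int]]:
        """All (region index, gene id, signed distance) pairs with the region
        midpoint within ``tss_window`` of the gene TSS (inclusive). A region
        may map to several genes and vice versa."""
        self._check_fitted()
        out = []
        for i, region in enumerate(regions):
            mid = region.midpoint
            mask = (self._chroms == region.chrom) & (
                np.abs(self._tss - mid) <= self.tss_window
            )
            for idx in np.nonzero(mask)[0]:
                gene = self.genes_[idx]
                out.append((i, gene.gene_id, _signed_tss_distance(region, gene)))
        return out


def classify_region(
    region: GenomicInterval,
    genes: list[GeneModel],
    proximal_bp: int = 200,
    flank_bp: int = 5000,
) -> AnnotatedRegion:
    """One-shot classification of a single region (thin estimator wrapper)."""
    return (
        RegionAnnotator(proximal_bp=proximal_bp, flank_bp=flank_bp)
        .fit(genes)
        .annotate_one(region)
    )


def map_regions_to_tss(
    regions: list[GenomicInterval],
    genes: list[GeneModel],
    window: int = 10000,
) -> list[tuple[int, str, int]]:
    return RegionAnnotator(tss_window=window).fit(genes).map_to_tss(regions)


def summarize_category_fractions(
    annotated: list[AnnotatedRegion],
) -> dict[RegionCategory, float]:
    """Fraction of regions in each category (over all eight categories).

    Fractions sum to 1; rounding to whole percent is a reporting concern.
    """
    if not annotated:
        raise ValueError("cannot summarize an empty annotation list")
    n = len(annotated)
    counts = {cat: 0 for cat in RegionCategory}
    for a in annotated:
        counts[a.category] += 1
    return {cat: c / n for cat, c in counts.items()}
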