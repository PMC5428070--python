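"""ChIP-Seq summit pairing and read-pileup track construction.

Co-binding of two factors (e.g. a nuclear-receptor heterodimer) is called
when peak summits from the two experiments fall within +/-100 bp (inclusive);
pairing is greedy one-to-one by smallest summit distance.

Pileup tracks reproduce a standard visualization transform: reads pooled
across replicates, duplicates at the exact same (position, strand) capped at
two to limit PCR bias, each read extended 3' to a 200 bp fragment, per-base
coverage summed over the query window, scaled to reads-per-million retained
reads, and smoothed with a 120 bp centered moving average (edges averaged
over the truncated in-window span).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator

from .intervals import GenomicInterval, Peak, ReadTag


@dataclass
class PileupTrack:
    window: GenomicInterval
    values: np.ndarray
    library_size: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.window):
            raise ValueError("track length must equal window length")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")


def pair_peaks_by_summit(
    peaks_a: list[Peak], peaks_b: list[Peak], max_dist: int = 100
) -> list[tuple[Peak, Peak]]:
    """Greedy one-to-one pairing of peaks whose summits are within
    ``max_dist`` bp (inclusive) on the same contig.

    Candidate pairs are taken in order of increasing summit distance, ties
    broken by coordinate, and each peak joins at most one pair. The result
    is symmetric in the argument order (pairs are returned as (a, b)).
    """
    candidates = []
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            if pa.interval.chrom != pb.interval.chrom:
                continue
            d = abs(pa.summit - pb.summit)
            if d <= max_dist:
                key = (d, min(pa.summit, pb.summit), max(pa.summit, pb.summit))
                candidates.append((key, i, j))
    candidates.sort(key=lambda c: c[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((peaks_a[i], peaks_b[j]))
    return pairs


def deduplicate_reads(reads: list[ReadTag], dup_cap: int = 2) -> list[ReadTag]:
    """Cap reads at the exact same (chrom, 5' position, strand) at dup_cap."""
    if dup_cap < 1:
        raise ValueError("dup_cap must be >= 1")
    counts: Counter = Counter()
    out = []
    for r in sorted(reads, key=lambda r: (r.chrom, r.five_prime, r.strand)):
        key = (r.chrom, r.five_prime, r.strand)
        if counts[key] < dup_cap:
            counts[key] += 1
            out.append(r)
    return out


def build_pileup(
    reads: list[ReadTag],
    window: GenomicInterval,
    extension: int = 200,
    dup_cap: int = 2,
    library_size: float | None = None,
) -> PileupTrack:
    """Deduplicated, 3'-extended, depth-normalized per-base coverage.

    A + read at 5' position p covers ``[p, p + extension)``; a - read covers
    ``(p - extension, p]``. Coverage is scaled by ``1e6 / library_size``
    (reads per million); ``library_size`` defaults to the number of retained
    reads. Input read order never affects the result.
    """
    if extension < 1:
        raise ValueError("extension must be >= 1")
    retained = deduplicate_reads(reads, dup_cap=dup_cap)
    if library_size is None:
        library_size = len(retained)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    n = len(window)
    diff = np.zeros(n + 1)
    for r in retained:
        if r.chrom != window.chrom:
            continue
        if r.strand == "+":
            s, e = r.five_prime, r.five_prime + extension
        else:
            s, e = r.five_prime - extension + 1, r.five_prime + 1
        s = max(s, window.start) - window.start
        e = min(e, window.end) - window.start
        if s < e:
            diff[s] += 1
            diff[e] -= 1
    values = np.cumsum(diff[:-1]) * (1e6 / library_size)
    return PileupTrack(window=window, values=values, library_size=float(library_size))


def smooth_track(track: PileupTrack, smooth_window: int = 120) -> PileupTrack:
    """Centered moving average; edges are averaged over the in-window span."""
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    kernel = np.ones(smooth_window)
    num = np.convolve(track.values, kernel, mode="same")
    den = np.convolve(np.ones_like(track.values), kernel, mode="same")
    return replace(track, values=num / den, smoothed=True)


class PileupBuilder(BaseEstimator):
    """Transformer bundling the pileup parameters (extension, duplicate cap,
    normalization library size, smoothing window)."""

    def __init__(
        self,
        extension: int = 200,
        dup_cap: int = 2,
        smooth_window: int = 120,
        library_size: float | None = None,
        smooth: bool = True,
    ):
        self.extension = extension
        self.dup_cap = dup_cap
        self.smooth_window = smooth_window
        self.library_size = library_size
        self.smooth = smooth

    def fit(self, reads: list[ReadTag], y=None) -> "PileupBuilder":
        self.retained_reads_ = deduplicate_reads(reads, dup_cap=self.dup_cap)
        self.library_size_ = (
            self.library_size if self.library_size is not None else len(self.retained_reads_)
        )
        return self

    def transform(self, window: GenomicInterval) -> PileupTrack:
        if not hasattr(self, "retained_reads_"):
            raise RuntimeError("PileupBuilder is not fitted; call fit(reads) first")
        track = build_pileup(
            self.retained_reads_,
            window,
            extension=self.extension,
            dup_cap=self.dup_cap,  # already applied; idempotent
            library_size=self.library_size_,
        )
        if self.smooth:
            track = smooth_track(track, smooth_window=self.smooth_window)
        return track
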