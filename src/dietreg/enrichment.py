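"""CpG stratification and motif enrichment against GC-matched backgrounds.

Accessible-site sequences are taken as fixed-width windows (default 100 bp)
centered on single-base event coordinates. Each window carries its GC
fraction and a normalized CpG score

    normalized_cpg = observed CpG / [ (GC/2)^2 * (L - 1) ],

i.e. the observed count of overlapping CG dinucleotides over the count
expected from the GC content alone (the (L-1) factor counts dinucleotide
positions, making the ratio scale-free). Windows split into low (<= 0.5)
and high (> 0.5) CpG sets; promoter-like sequence is CpG-rich, most distal
regulatory sequence CpG-poor.

Enrichment of a motif in a foreground window set versus an equally-sized,
GC-matched random background is a hypergeometric upper tail on per-window
binary match counts, BH-corrected across the motif library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .motifs import PSSM, MotifScanner


@dataclass
class SequenceWindow:
    """An extracted sequence window with CpG statistics."""

    chrom: str
    start: int
    end: int
    sequence: str
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        s = self.sequence.upper()
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0

    @property
    def normalized_cpg(self) -> float:
        return normalized_cpg(self.sequence)


def normalized_cpg(sequence: str) -> float:
    """Observed/expected CpG ratio of a sequence (0 when GC fraction is 0)."""
    L = len(sequence)
    if L < 2:
        raise ValueError("normalized CpG needs a sequence of length >= 2")
    s = sequence.upper()
    observed = s.count("CG")
    gc = (s.count("G") + s.count("C")) / L
    if gc == 0.0:
        return 0.0
    expected = (gc / 2.0) ** 2 * (L - 1)
    return observed / expected


def extract_windows(
    sites: list[tuple[str, int]],
    genome: dict[str, str],
    width: int = 100,
) -> list[SequenceWindow]:
    """Windows of ``width`` bp centered on single-base sites, clipped at
    contig ends (clipped windows are flagged)."""
    half = width // 2
    out = []
    for chrom, pos in sites:
        if chrom not in genome:
            raise KeyError(f"site on unknown contig {chrom!r}")
        L = len(genome[chrom])
        if not (0 <= pos < L):
            raise ValueError(f"site {chrom}:{pos} outside contig of length {L}")
        start, end = pos - half, pos - half + width
        cstart, cend = max(0, start), min(L, end)
        out.append(
            SequenceWindow(
                chrom=chrom,
                start=cstart,
                end=cend,
                sequence=genome[chrom][cstart:cend],
                clipped=(cstart != start or cend != end),
            )
        )
    return out


def stratify_by_cpg(
    windows: list[SequenceWindow], threshold: float = 0.5
) -> tuple[list[SequenceWindow], list[SequenceWindow]]:
    """Split windows into (low, high) CpG sets; scores exactly at the
    threshold go to the low set."""
    low = [w for w in windows if w.normalized_cpg <= threshold]
    high = [w for w in windows if w.normalized_cpg > threshold]
    return low, high


def sample_matched_background(
    fg_windows: list[SequenceWindow],
    genome: dict[str, str],
    gc_bin_width: float = 0.05,
    seed: int = 0,
    max_tries: int = 10000,
) -> list[SequenceWindow]:
    """One random genome window per foreground window, equal length, with GC
    fraction in the same ``gc_bin_width`` bin (rejection sampling)."""
    if not fg_windows:
        raise ValueError("empty foreground window set")
    rng = np.random.default_rng(seed)
    names = sorted(genome)
    out = []
    for w in fg_windows:
        width = len(w)
        lengths = np.array([max(0, len(genome[c]) - width) for c in names], dtype=float)
        if lengths.sum() == 0:
            raise ValueError("genome contigs shorter than the window width")
        probs = lengths / lengths.sum()
        target_bin = int(w.gc_fraction // gc_bin_width)
        for _ in range(max_tries):
            ci = int(rng.choice(len(names), p=probs))
            seq = genome[names[ci]]
            start = int(rng.integers(0, len(seq) - width + 1))
            cand = seq[start : start + width]
            gc = (cand.upper().count("G") + cand.upper().count("C")) / width
            if int(gc // gc_bin_width) == target_bin:
                out.append(SequenceWindow(names[ci], start, start + width, cand))
                break
        else:
            lo, hi = target_bin * gc_bin_width, (target_bin + 1) * gc_bin_width
            raise RuntimeError(
                f"could not sample a background window in GC bin "
                f"[{lo:.2f}, {hi:.2f}) after {max_tries} tries"
            )
    return out


# ------------------------------------------------------------ statistics

@dataclass
class EnrichmentResult:
    motif: str
    fg_matches: int
    fg_total: int
    bg_matches: int
    bg_total: int
    p_value: float
    q_value: float | None = None
    cluster_id: int | None = None


def hypergeometric_enrichment_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) drawing n from a population of N with K successes."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up q-values (monotone, clipped to [0, 1])."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def motif_enrichment(
    fg_windows: list[SequenceWindow],
    bg_windows: list[SequenceWindow],
    pssms: list[PSSM],
) -> list[EnrichmentResult]:
    """Per-motif hypergeometric enrichment of foreground vs background.

    Matching is per-window binary (a window either has >= 1 match or none).
    Requires calibrated ``match_threshold`` on every motif.
    """
    if not fg_windows or not bg_windows:
        raise ValueError("foreground and background window sets must be non-empty")
    for p in pssms:
        if p.match_threshold is None:
            raise ValueError(f"motif {p.name} has no calibrated match_threshold")
    n_fg, n_bg = len(fg_windows), len(bg_windows)
    results = []
    for pssm in pssms:
        fg_k = sum(pssm.score_sequence(w.sequence).is_match for w in fg_windows)
        bg_k = sum(pssm.score_sequence(w.sequence).is_match for w in bg_windows)
        p = hypergeometric_enrichment_p(fg_k, n_fg + n_bg, fg_k + bg_k, n_fg)
        results.append(
            EnrichmentResult(
                motif=pssm.name,
                fg_matches=fg_k,
                fg_total=n_fg,
                bg_matches=bg_k,
                bg_total=n_bg,
                p_value=p,
            )
        )
    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


class MotifEnrichment(BaseEstimator):
    """End-to-end enrichment stage: calibrate thresholds on a genome, sample a
    GC-matched background, count matches, and test.

    Parameters mirror the pipeline knobs: ``fp_rate`` for threshold
    calibration, ``n_calibration`` null samples per motif, ``gc_bin_width``
    for background matching.

    Attributes (after ``fit``): ``results_`` (list of
    :class:`EnrichmentResult`), ``results_frame_`` (DataFrame),
    ``bg_windows_``.
    """

    def __init__(
        self,
        pssms=None,
        fp_rate: float = 0.001,
        n_calibration: int = 5000,
        gc_bin_width: float = 0.05,
    ):
        self.pssms = pssms
        self.fp_rate = fp_rate
        self.n_calibration = n_calibration
        self.gc_bin_width = gc_bin_width

    def fit(
        self,
        fg_windows: list[SequenceWindow],
        genome: dict[str, str] = None,
        bg_windows: list[SequenceWindow] | None = None,
        seed: int = 0,
    ) -> "MotifEnrichment":
        if genome is None and bg_windows is None:
            raise ValueError("provide a genome (for background sampling) or bg_windows")
        if genome is not None:
            MotifScanner(
                self.pssms, fp_rate=self.fp_rate, n_calibration=self.n_calibration
            ).fit(genome, seed=seed)
        if bg_windows is None:
            bg_windows = sample_matched_background(
                fg_windows, genome, gc_bin_width=self.gc_bin_width, seed=seed + 1
            )
        self.bg_windows_ = bg_windows
        self.results_ = motif_enrichment(fg_windows, bg_windows, self.pssms)
        self.results_frame_ = results_to_frame(self.results_)
        return self
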