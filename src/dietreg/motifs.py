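"""Position-specific scoring matrices and normalized log-likelihood scanning.

A motif match score for a k-mer *s* is the log-likelihood ratio
``LLR(s) = sum_i log(p_i(s_i) / q(s_i))`` normalized to [0, 1] by the
motif's attainable extrema: ``LLR_norm = (LLR - LLR_min) / (LLR_max -
LLR_min)``. Both strands are scanned and the best (position, strand)
retained. A match is called when the best score reaches the motif's
``match_threshold``; thresholds are calibrated empirically as a
(1 - fp_rate) quantile of the null score distribution on random genomic
k-mers, playing the role of a database-provided minimum-false-positive
cutoff.

Information content (bits, summed over positions against the background)
is computed on the raw probability matrix; a pseudocount (default 1e-3)
enters only the log-ratio scoring matrix so that ``LLR_min`` is finite.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as integer codes A=0,C=1,G=2,T=3; anything else 4."""
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class MotifMatch:
    motif: str
    best_llr_norm: float
    position: int
    strand: str
    is_match: bool

    @property
    def score(self) -> float:
        """Retained score: best LLR_norm if matched, else 0."""
        return self.best_llr_norm if self.is_match else 0.0


class PSSM:
    """A probability motif model over {A, C, G, T} with a background.

    Parameters
    ----------
    name : str
        Motif identifier.
    probs : array (length, 4)
        Per-position base probabilities; each row must sum to 1.
    background : array (4,), optional
        Background base probabilities (default uniform).
    pseudocount : float
        Added to probabilities (then renormalized) before taking log ratios.
    """

    def __init__(self, name, probs, background=None, pseudocount=1e-3):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] == 0:
            raise ValueError("probs must be a non-empty (length, 4) matrix")
        if np.any(probs < 0):
            raise ValueError("negative probabilities")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PSSM column must sum to 1 (+/- 1e-9)")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        if np.any(background <= 0):
            raise ValueError("background probabilities must be positive")

        self.name = name
        self.probs = probs
        self.background = background
        self.pseudocount = float(pseudocount)
        self.match_threshold: float | None = None

        scoring = (probs + pseudocount) / (1.0 + 4.0 * pseudocount)
        self.scoring_probs = scoring  # strictly positive; used for KL too
        lods = np.log(scoring / background)  # natural log; base cancels in LLR_norm
        # column 4: ambiguous base contributes the background, i.e. log ratio 0
        self._lods = np.hstack([lods, np.zeros((len(self), 1))])
        self.llr_max = float(lods.max(axis=1).sum())
        self.llr_min = float(lods.min(axis=1).sum())
        self._rc_lods = self._lods[::-1][:, _COMPLEMENT_IDX]

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name, counts, background=None, pseudocount=1e-3) -> "PSSM":
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("every motif position needs a positive count total")
        return cls(name, counts / totals, background=background, pseudocount=pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    @property
    def information_content(self) -> float:
        """Total bits: sum over positions of sum_b p log2(p / q_b), on raw probs."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / self.background), 0.0)
        return float(terms.sum())

    # ------------------------------------------------------------ scoring

    def _offset_scores(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-offset LLR_norm on + and - strands for an encoded sequence."""
        k = len(self)
        if codes.size < k:
            raise ValueError(
                f"sequence length {codes.size} shorter than motif {self.name} ({k})"
            )
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        idx = np.arange(k)
        fwd = self._lods[idx, win].sum(axis=1)
        rev = self._rc_lods[idx, win].sum(axis=1)
        span = self.llr_max - self.llr_min
        return (fwd - self.llr_min) / span, (rev - self.llr_min) / span

    def scores_for_kmers(self, codes: np.ndarray) -> np.ndarray:
        """Best two-strand LLR_norm for a batch of encoded k-mers (n, k)."""
        codes = np.atleast_2d(codes)
        k = len(self)
        if codes.shape[1] != k:
            raise ValueError(f"k-mer batch width {codes.shape[1]} != motif length {k}")
        idx = np.arange(k)[None, :]
        fwd = self._lods[idx, codes].sum(axis=1)
        rev = self._rc_lods[idx, codes].sum(axis=1)
        span = self.llr_max - self.llr_min
        return (np.maximum(fwd, rev) - self.llr_min) / span

    def score_sequence(self, seq: str) -> MotifMatch:
        """Best LLR_norm over all offsets and both strands of ``seq``."""
        fwd, rev = self._offset_scores(encode(seq))
        i_f, i_r = int(fwd.argmax()), int(rev.argmax())
        if fwd[i_f] >= rev[i_r]:
            best, pos, strand = float(fwd[i_f]), i_f, "+"
        else:
            best, pos, strand = float(rev[i_r]), i_r, "-"
        matched = self.match_threshold is not None and best >= self.match_threshold
        return MotifMatch(self.name, best, pos, strand, matched)


def score_window(pssm: PSSM, window) -> MotifMatch:
    """Score a :class:`~dietreg.enrichment.SequenceWindow` (or raw string)."""
    seq = window if isinstance(window, str) else window.sequence
    return pssm.score_sequence(seq)


def information_content(pssm: PSSM) -> float:
    return pssm.information_content


def filter_motifs(pssms: list[PSSM], min_bits: float = 8.0) -> list[PSSM]:
    """Keep motifs with total information content strictly above ``min_bits``."""
    return [p for p in pssms if p.information_content > min_bits]


def calibrate_match_threshold(
    pssm: PSSM,
    genome: dict[str, str],
    fp_rate: float = 0.001,
    n_samples: int = 5000,
    seed: int = 0,
) -> float:
    """Set ``pssm.match_threshold`` to the (1 - fp_rate) quantile of the best
    two-strand LLR_norm over random genomic k-mers (k = motif length).

    The quantile is the empirical analogue of a database minimum-false-positive
    similarity cutoff: a random k-mer exceeds it with probability ~fp_rate.
    """
    if not (0 < fp_rate < 1):
        raise ValueError("fp_rate must be in (0, 1)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples < 1.0 / fp_rate:
        warnings.warn(
            f"n_samples={n_samples} < 1/fp_rate={1 / fp_rate:.0f}: "
            "the calibration quantile is unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    k = len(pssm)
    names = sorted(genome)
    lengths = np.array([len(genome[c]) - k for c in names], dtype=float)
    if np.all(lengths < 0):
        raise ValueError("genome contigs shorter than the motif")
    lengths = np.clip(lengths, 0, None)
    probs = lengths / lengths.sum()
    contig_idx = rng.choice(len(names), size=n_samples, p=probs)
    scores = np.empty(n_samples)
    for ci in np.unique(contig_idx):
        codes = encode(genome[names[ci]])
        kmers = np.lib.stride_tricks.sliding_window_view(codes, k)
        sel = contig_idx == ci
        starts = rng.integers(0, len(kmers), size=int(sel.sum()))
        scores[sel] = pssm.scores_for_kmers(kmers[starts])
    threshold = float(np.quantile(scores, 1.0 - fp_rate))
    pssm.match_threshold = threshold
    return threshold


class MotifScanner(BaseEstimator):
    """Calibrate match thresholds on a genome, then score window sets.

    ``fit(genome)`` calibrates every motif's threshold; ``transform(windows)``
    returns the retained-score matrix (best matching LLR_norm per window and
    motif, 0 where the window has no match).
    """

    def __init__(self, pssms=None, fp_rate: float = 0.001, n_calibration: int = 5000):
        self.pssms = pssms
        self.fp_rate = fp_rate
        self.n_calibration = n_calibration

    def fit(self, genome: dict[str, str], y=None, seed: int = 0) -> "MotifScanner":
        if not self.pssms:
            raise ValueError("no motifs supplied")
        self.thresholds_ = {}
        for i, pssm in enumerate(self.pssms):
            self.thresholds_[pssm.name] = calibrate_match_threshold(
                pssm,
                genome,
                fp_rate=self.fp_rate,
                n_samples=self.n_calibration,
                seed=seed + i,
            )
        return self

    def transform(self, windows) -> "np.ndarray":
        import pandas as pd

        if not hasattr(self, "thresholds_"):
            raise RuntimeError("MotifScanner is not fitted; call fit(genome) first")
        rows = {}
        for pssm in self.pssms:
            rows[pssm.name] = [score_window(pssm, w).score for w in windows]
        return pd.DataFrame(rows)

    def match_matrix(self, windows):
        """Boolean (window x motif) match indicator DataFrame."""
        return self.transform(windows) > 0


# ------------------------------------------------------------ file formats

def _from_biopython(motifs, pseudocount: float = 1e-3) -> list[PSSM]:
    out = []
    for m in motifs:
        counts = np.array([[m.counts[b][i] for b in ALPHABET] for i in range(m.length)])
        name = m.name
        if not name and hasattr(m, "get"):  # TRANSFAC records are dict-like
            name = m.get("ID") or m.get("AC")
        name = name or f"motif_{len(out)}"
        out.append(PSSM.from_counts(str(name), counts, pseudocount=pseudocount))
    return out


def read_transfac(path_or_text: str, pseudocount: float = 1e-3) -> list[PSSM]:
    """Read TRANSFAC-style plain-text matrices (ID / P0 count rows)."""
    from Bio import motifs as bio_motifs

    handle = _open_text(path_or_text)
    with handle:
        records = bio_motifs.parse(handle, "transfac", strict=False)
    return _from_biopython(records, pseudocount)


def read_meme_minimal(path_or_text: str, pseudocount: float = 1e-3) -> list[PSSM]:
    """Read MEME minimal-format motifs."""
    from Bio import motifs as bio_motifs

    handle = _open_text(path_or_text)
    with handle:
        records = bio_motifs.parse(handle, "minimal")
    return _from_biopython(records, pseudocount)


def write_transfac(pssms: list[PSSM], path, counts_scale: int = 100) -> None:
    """Write motifs as TRANSFAC matrices (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for p in pssms:
            fh.write(f"ID {p.name}\nBF undefined\nP0      A      C      G      T\n")
            for i, row in enumerate(p.probs, start=1):
                counts = np.round(row * counts_scale).astype(int)
                fh.write(
                    f"{i:02d} {counts[0]:6d} {counts[1]:6d} {counts[2]:6d} {counts[3]:6d}\n"
                )
            fh.write("XX\n//\n")


def _open_text(path_or_text: str):
    if "\n" in path_or_text:
        return _io.StringIO(path_or_text)
    return open(path_or_text)
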