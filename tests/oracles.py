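"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, exact rational
arithmetic, literal rule checks) and shares no code path with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

from dietreg.annotation import RegionCategory


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact rational summation of the hypergeometric pmf."""
    denom = math.comb(N, n)
    lo, hi = max(k, max(0, n - (N - K))), min(K, n)
    total = Fraction(0)
    for j in range(lo, hi + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


def hypergeom_upper_tail_lgamma(k: int, N: int, K: int, n: int) -> float:
    """Independent log-space tail sum (for populations too large to enumerate
    exactly in rational arithmetic at reasonable cost)."""

    def logpmf(j: int) -> float:
        def lchoose(a, b):
            return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

        return lchoose(K, j) + lchoose(N - K, n - j) - lchoose(N, n)

    lo, hi = max(k, max(0, n - (N - K))), min(K, n)
    if lo > hi:
        return 0.0
    logs = [logpmf(j) for j in range(lo, hi + 1)]
    m = max(logs)
    return math.exp(m) * sum(math.exp(x - m) for x in logs)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by complete enumeration of tables with the
    observed margins, summing those no more probable than observed
    (exact rational comparison)."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    denom = math.comb(N, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    total = Fraction(0)
    for j in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_j = Fraction(math.comb(r1, j) * math.comb(r2, c1 - j), denom)
        if p_j <= p_obs:
            total += p_j
    return float(min(total, Fraction(1)))


def llr_norm_brute(pssm, seq: str) -> float:
    """Best normalized LLR by scoring every offset on both strands with
    plain Python loops against the motif's (pseudocounted) probabilities."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    k = len(pssm)
    probs = pssm.scoring_probs
    bg = pssm.background
    lmin = sum(min(math.log(probs[i][b] / bg[b]) for b in range(4)) for i in range(k))
    lmax = sum(max(math.log(probs[i][b] / bg[b]) for b in range(4)) for i in range(k))
    best = -math.inf
    seq = seq.upper()
    rc = "".join(comp.get(ch, "N") for ch in reversed(seq))
    for strand_seq in (seq, rc):
        for off in range(len(strand_seq) - k + 1):
            llr = 0.0
            for i, ch in enumerate(strand_seq[off : off + k]):
                if ch in codes:
                    llr += math.log(probs[i][codes[ch]] / bg[codes[ch]])
            best = max(best, llr)
    return (best - lmin) / (lmax - lmin)


_BRUTE_PRECEDENCE = [
    RegionCategory.proximal_promoter,
    RegionCategory.utr5,
    RegionCategory.utr3,
    RegionCategory.coding_exon,
    RegionCategory.intron,
    RegionCategory.distal_promoter,
    RegionCategory.downstream,
]


def classify_brute(region, genes, proximal=200, flank=5000) -> RegionCategory:
    """Literal rule-by-rule classifier: walk the categories in precedence
    order and return the first whose rule fires for any gene."""

    def touches(lo, hi):  # closed base range [lo, hi]
        return region.start <= hi and lo <= region.end - 1

    def rule_fires(cat, g) -> bool:
        if g.chrom != region.chrom:
            return False
        tss = g.tss
        if cat == RegionCategory.proximal_promoter:
            return touches(tss - proximal, tss + proximal)
        if cat == RegionCategory.utr5:
            return any(touches(s, e - 1) for s, e in g.utr5)
        if cat == RegionCategory.utr3:
            return any(touches(s, e - 1) for s, e in g.utr3)
        if cat == RegionCategory.coding_exon:
            return any(touches(s, e - 1) for s, e in g.coding_exons)
        if cat == RegionCategory.intron:
            return any(touches(s, e - 1) for s, e in g.introns)
        if cat == RegionCategory.distal_promoter:
            if g.strand == "+":
                return touches(tss - flank, tss - 1)
            return touches(tss + 1, tss + flank)
        if cat == RegionCategory.downstream:
            if g.strand == "+":
                return touches(g.end, g.end + flank - 1)
            return touches(g.start - flank, g.start - 1)
        raise AssertionError(cat)

    for cat in _BRUTE_PRECEDENCE:
        if any(rule_fires(cat, g) for g in genes):
            return cat
    return RegionCategory.distal_intergenic


def moving_average_brute(values, window: int):
    """Centered moving average with truncated edges; for even windows the
    span is [i - window//2, i + (window-1)//2], matching centered 'same'
    convolution."""
    n = len(values)
    left = window // 2
    right = (window - 1) // 2
    out = []
    for i in range(n):
        lo, hi = max(0, i - left), min(n, i + right + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out
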