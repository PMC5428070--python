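"""Collapse redundant motifs by affinity propagation on KL similarity.

Motif libraries are highly redundant (many near-identical matrices for the
same factor family). Pairwise dissimilarity between two matrices is a
symmetrized, per-column-averaged Kullback-Leibler divergence minimized over
all ungapped offset alignments and over reverse complementation; overhanging
columns are compared against the background. Similarity is the negated
divergence, so identical motifs have similarity 0 and everything else is
negative; the affinity-propagation preference (self-similarity, default
-0.4) is therefore on the divergence scale and controls how readily a motif
becomes its own exemplar.

Affinity propagation is implemented here directly (responsibility /
availability message passing with damping) so that tie-breaking and the
convergence flag are deterministic and explicit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .enrichment import EnrichmentResult, benjamini_hochberg
from .motifs import PSSM


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * np.log(p / q)))


def _sym_kl(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * (_kl(p, q) + _kl(q, p))


def pssm_kl_divergence(a: PSSM, b: PSSM) -> float:
    """Symmetrized per-column mean KL divergence between two motifs.

    Minimized over every ungapped offset alignment with >= 1 overlapping
    column and over the reverse complement of ``b``; columns without a
    partner are compared to the background distribution. Natural log.
    """
    pa = a.scoring_probs
    bg_a, bg_b = a.background, b.background
    la, lb = len(a), len(b)
    best = np.inf
    b_variants = (b.scoring_probs, b.scoring_probs[::-1, [3, 2, 1, 0]])
    for pb in b_variants:
        for offset in range(-(lb - 1), la):
            lo = min(0, offset)
            hi = max(la, offset + lb)
            total = 0.0
            for u in range(lo, hi):
                col_a = pa[u] if 0 <= u < la else bg_a
                col_b = pb[u - offset] if 0 <= u - offset < lb else bg_b
                total += _sym_kl(col_a, col_b)
            best = min(best, total / (hi - lo))
    return best


@dataclass
class MotifSimilarityMatrix:
    """Negated pairwise divergences with the AP preference on the diagonal."""

    motif_ids: list[str]
    similarity: np.ndarray
    preference: float = -0.4


def build_similarity_matrix(
    pssms: list[PSSM], preference: float = -0.4
) -> MotifSimilarityMatrix:
    n = len(pssms)
    if n == 0:
        raise ValueError("no motifs to compare")
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = -pssm_kl_divergence(pssms[i], pssms[j])
    np.fill_diagonal(S, preference)
    return MotifSimilarityMatrix([p.name for p in pssms], S, preference)


def affinity_propagation(
    sim: MotifSimilarityMatrix | np.ndarray,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_window: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Standard AP message passing; returns (labels, exemplar indices,
    converged flag).

    Deterministic: a tiny index-ordered perturbation breaks exact symmetry
    (duplicate motifs) instead of random noise, and argmax ties resolve to
    the lowest index. Non-convergence within ``max_iter`` returns the
    current labels with ``converged=False``.
    """
    S = sim.similarity if isinstance(sim, MotifSimilarityMatrix) else np.asarray(sim)
    if not np.all(np.isfinite(S)):
        raise ValueError("similarities must be finite")
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if n == 1:
        return np.array([0]), np.array([0]), True
    span = float(S.max() - S.min()) or 1.0
    S = S + 1e-10 * span * np.arange(n * n).reshape(n, n) / (n * n)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    ii = np.arange(n)
    last_exemplars: tuple | None = None
    stable = 0
    converged = False
    for _ in range(max_iter):
        AS = A + S
        top = AS.argmax(axis=1)
        first = AS[ii, top]
        AS[ii, top] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[ii, top] = S[ii, top] - second
        R = damping * R + (1.0 - damping) * Rnew

        Rp = np.maximum(R, 0.0)
        Rp[ii, ii] = R[ii, ii]
        col = Rp.sum(axis=0)
        Anew = col[None, :] - Rp
        diag = Anew[ii, ii].copy()
        Anew = np.minimum(Anew, 0.0)
        Anew[ii, ii] = diag
        A = damping * A + (1.0 - damping) * Anew

        exemplars = tuple(np.flatnonzero((A + R).diagonal() > 0))
        if exemplars and exemplars == last_exemplars:
            stable += 1
            if stable >= conv_window:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    ex = np.flatnonzero((A + R).diagonal() > 0)
    if ex.size == 0:  # degenerate: pick the best single exemplar
        ex = np.array([int((A + R).diagonal().argmax())])
    # Deterministic resolution of duplicate-motif stalls: exact copies leave
    # each other's self-responsibility pinned at 0, so none elects itself and
    # the whole group drifts to a distant exemplar. Promote (lowest index
    # first) any point whose assigned exemplar is less similar than its own
    # preference until the assignment is stable.
    ex_list = sorted(int(e) for e in ex)
    while True:
        ex_arr = np.array(ex_list)
        labels = ex_arr[S[:, ex_arr].argmax(axis=1)]
        labels[ex_arr] = ex_arr  # exemplars always belong to their own cluster
        defector = next(
            (
                i
                for i in range(n)
                if i not in ex_list and S[i, labels[i]] < S[i, i]
            ),
            None,
        )
        if defector is None:
            break
        ex_list = sorted(ex_list + [defector])
    remap = {e: i for i, e in enumerate(ex_list)}
    return np.array([remap[int(l)] for l in labels]), np.array(ex_list), converged


class MotifAffinityPropagation(BaseEstimator):
    """Cluster motifs by AP over KL similarity (exemplar-based).

    Attributes after ``fit(pssms)``: ``similarity_``, ``labels_``,
    ``exemplar_indices_``, ``exemplar_names_``, ``converged_``,
    ``n_clusters_``.
    """

    def __init__(
        self,
        preference: float = -0.4,
        damping: float = 0.9,
        max_iter: int = 1000,
        conv_window: int = 50,
    ):
        self.preference = preference
        self.damping = damping
        self.max_iter = max_iter
        self.conv_window = conv_window

    def fit(self, pssms: list[PSSM], y=None) -> "MotifAffinityPropagation":
        self.similarity_ = build_similarity_matrix(pssms, preference=self.preference)
        self.labels_, self.exemplar_indices_, self.converged_ = affinity_propagation(
            self.similarity_,
            damping=self.damping,
            max_iter=self.max_iter,
            conv_window=self.conv_window,
        )
        self.exemplar_names_ = [self.similarity_.motif_ids[i] for i in self.exemplar_indices_]
        self.n_clusters_ = len(self.exemplar_indices_)
        return self

    def fit_predict(self, pssms: list[PSSM], y=None) -> np.ndarray:
        return self.fit(pssms).labels_


def collapse_by_cluster(
    results: list[EnrichmentResult], labels
) -> list[EnrichmentResult]:
    """Retain the most significant enrichment result per motif cluster and
    re-apply BH across the collapsed family.

    ``labels[i]`` is the cluster of ``results[i]``. Ties on raw p go to the
    larger foreground match count, then the lexicographically smaller motif
    id. Idempotent: collapsing an already-collapsed set is a no-op.
    """
    labels = np.asarray(labels)
    if len(labels) != len(results):
        raise ValueError("labels and results must align")
    retained: dict[int, EnrichmentResult] = {}
    for res, lab in zip(results, labels):
        lab = int(lab)
        cur = retained.get(lab)
        key = (res.p_value, -res.fg_matches, res.motif)
        if cur is None or key < (cur.p_value, -cur.fg_matches, cur.motif):
            retained[lab] = res
    out = []
    for lab in sorted(retained):
        r = copy.copy(retained[lab])
        r.cluster_id = lab
        out.append(r)
    qs = benjamini_hochberg([r.p_value for r in out])
    for r, q in zip(out, qs):
        r.q_value = float(q)
    return out
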