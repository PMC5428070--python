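"""Motif KL divergence, affinity propagation, and per-cluster collapsing."""

import numpy as np
import pytest

from dietreg.clustering import (
    MotifAffinityPropagation,
    affinity_propagation,
    build_similarity_matrix,
    collapse_by_cluster,
    pssm_kl_divergence,
)
from dietreg.enrichment import EnrichmentResult
from dietreg.motifs import PSSM
from dietreg.synthetic import make_random_pssm


def test_kl_identical_motifs_is_zero():
    a = make_random_pssm("a", length=6, seed=1)
    b = PSSM("b", a.probs.copy())
    assert pssm_kl_divergence(a, b) == pytest.approx(0.0, abs=1e-12)


def test_kl_symmetry_on_random_pairs():
    for i in range(20):
        a = make_random_pssm("a", length=5 + i % 4, seed=2 * i)
        b = make_random_pssm("b", length=5 + (i + 2) % 4, seed=2 * i + 1)
        assert pssm_kl_divergence(a, b) == pytest.approx(pssm_kl_divergence(b, a), abs=1e-12)


def test_kl_one_column_hand_value():
    # p=(0.7,0.1,0.1,0.1) vs q=(0.1,0.7,0.1,0.1): 0.5[KL(p||q)+KL(q||p)]
    # = 0.6 ln 7 ~ 1.1675; the 1e-3 pseudocount shifts it by < 1%
    a = PSSM("a", [[0.7, 0.1, 0.1, 0.1]])
    b = PSSM("b", [[0.1, 0.7, 0.1, 0.1]])
    assert pssm_kl_divergence(a, b) == pytest.approx(0.6 * np.log(7), rel=0.01)


def test_kl_reverse_complement_invariance():
    a = make_random_pssm("a", length=7, seed=9)
    rc = PSSM("rc", a.probs[::-1, [3, 2, 1, 0]])
    assert pssm_kl_divergence(a, rc) == pytest.approx(0.0, abs=1e-12)


def test_kl_nonnegative_and_zero_only_for_identical():
    rng = np.random.default_rng(4)
    for i in range(20):
        a = make_random_pssm("a", length=int(rng.integers(4, 9)), seed=50 + i)
        b = make_random_pssm("b", length=int(rng.integers(4, 9)), seed=80 + i)
        d = pssm_kl_divergence(a, b)
        assert d >= 0
        if not np.array_equal(a.probs, b.probs):
            assert d > 0


def test_ap_duplicates_cluster_together_away_from_distant_motif():
    # three exact copies plus one distant motif: two clusters, copies together
    S = np.array(
        [
            [-0.4, 0.0, 0.0, -5.0],
            [0.0, -0.4, 0.0, -5.0],
            [0.0, 0.0, -0.4, -5.0],
            [-5.0, -5.0, -5.0, -0.4],
        ]
    )
    labels, exemplars, _ = affinity_propagation(S)
    assert len(set(labels)) == 2
    assert labels[0] == labels[1] == labels[2] != labels[3]


def test_ap_on_real_motif_copies():
    copies = [
        PSSM(f"c{i}", [[0.9, 0.03, 0.03, 0.04], [0.03, 0.9, 0.04, 0.03]]) for i in range(3)
    ]
    far = PSSM("far", [[0.03, 0.03, 0.04, 0.9]] * 2)
    ap = MotifAffinityPropagation().fit(copies + [far])
    assert ap.n_clusters_ == 2
    assert ap.labels_[0] == ap.labels_[1] == ap.labels_[2] != ap.labels_[3]


def test_ap_single_motif_self_exemplar():
    labels, exemplars, converged = affinity_propagation(np.array([[-0.4]]))
    assert list(labels) == [0] and list(exemplars) == [0] and converged


def test_ap_matches_sklearn_on_separated_groups():
    from sklearn.cluster import AffinityPropagation as SkAP

    rng = np.random.default_rng(0)
    n1, n2 = 3, 4
    S = -3.0 + 0.2 * rng.random((n1 + n2, n1 + n2))
    S = (S + S.T) / 2
    for grp in (range(n1), range(n1, n1 + n2)):
        for i in grp:
            for j in grp:
                S[i, j] = -0.05 + 0.02 * rng.random()
    S = (S + S.T) / 2
    np.fill_diagonal(S, -0.4)
    labels, exemplars, converged = affinity_propagation(S)
    sk = SkAP(
        affinity="precomputed", damping=0.9, preference=-0.4, random_state=0, max_iter=2000
    ).fit(S)
    assert converged
    # identical partitions (label values may differ)
    ours = [tuple(np.flatnonzero(labels == k)) for k in sorted(set(labels))]
    theirs = [tuple(np.flatnonzero(sk.labels_ == k)) for k in sorted(set(sk.labels_))]
    assert sorted(ours) == sorted(theirs)


def test_ap_partition_and_exemplar_membership():
    motifs = [make_random_pssm(f"m{i}", length=6, seed=200 + i) for i in range(8)]
    ap = MotifAffinityPropagation().fit(motifs)
    assert len(ap.labels_) == 8
    assert set(ap.labels_) == set(range(ap.n_clusters_))
    for k, ex in enumerate(ap.exemplar_indices_):
        assert ap.labels_[ex] == k


def test_preference_monotone_in_cluster_count():
    motifs = [make_random_pssm(f"m{i}", length=6, seed=300 + i) for i in range(10)]
    sim = build_similarity_matrix(motifs)
    counts = []
    for pref in (-50.0, -5.0, -0.4, -0.05, -0.005):
        S = sim.similarity.copy()
        np.fill_diagonal(S, pref)
        labels, exemplars, _ = affinity_propagation(S)
        counts.append(len(exemplars))
    assert counts == sorted(counts)
    assert counts[0] >= 1 and counts[-1] <= 10


def _res(motif, p, fg=10):
    return EnrichmentResult(
        motif=motif, fg_matches=fg, fg_total=20, bg_matches=2, bg_total=20, p_value=p
    )


def test_collapse_keeps_minimum_p_and_reapplies_bh():
    results = [_res("a", 0.001), _res("b", 0.5), _res("c", 0.02)]
    collapsed = collapse_by_cluster(results, [0, 0, 1])
    assert [r.motif for r in collapsed] == ["a", "c"]
    assert [r.p_value for r in collapsed] == [0.001, 0.02]
    assert [r.q_value for r in collapsed] == pytest.approx([0.002, 0.02])


def test_collapse_tie_breaks_and_single_cluster():
    tie = [_res("b", 0.01, fg=5), _res("a", 0.01, fg=5), _res("c", 0.01, fg=9)]
    best = collapse_by_cluster(tie, [0, 0, 0])
    assert [r.motif for r in best] == ["c"]  # larger fg_matches wins
    alpha = collapse_by_cluster(tie[:2], [0, 0])
    assert [r.motif for r in alpha] == ["a"]  # then lexicographic id


def test_collapse_is_idempotent():
    results = [_res("a", 0.001), _res("b", 0.5), _res("c", 0.02), _res("d", 0.9)]
    once = collapse_by_cluster(results, [0, 0, 1, 1])
    twice = collapse_by_cluster(once, [r.cluster_id for r in once])
    assert [(r.motif, r.p_value, r.q_value) for r in once] == [
        (r.motif, r.p_value, r.q_value) for r in twice
    ]
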