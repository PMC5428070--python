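"""PSSM scoring, information content, threshold calibration, and parsing."""

import numpy as np
import pytest

from dietreg.motifs import (
    PSSM,
    MotifScanner,
    calibrate_match_threshold,
    filter_motifs,
    read_meme_minimal,
    read_transfac,
    reverse_complement,
    write_transfac,
)
from dietreg.synthetic import make_random_pssm

from oracles import llr_norm_brute


def _deterministic_pssm(bases: str) -> PSSM:
    rows = []
    for b in bases:
        row = [0.0] * 4
        row["ACGT".index(b)] = 1.0
        rows.append(row)
    return PSSM("det_" + bases, rows)


def test_information_content_of_deterministic_columns():
    assert _deterministic_pssm("ACGTA").information_content == pytest.approx(10.0)
    uniform = PSSM("uni", [[0.25] * 4] * 5)
    assert uniform.information_content == pytest.approx(0.0)


def test_information_filter_is_strict():
    five = _deterministic_pssm("ACGTA")  # 10 bits
    four = _deterministic_pssm("ACGT")  # exactly 8 bits
    uniform = PSSM("uni", [[0.25] * 4] * 5)
    kept = filter_motifs([five, four, uniform], min_bits=8)
    assert [p.name for p in kept] == [five.name]


def test_consensus_scores_one_and_anticonsensus_zero():
    # alternating least-likely bases C/G make the anti-consensus CGCGCG a
    # reverse-complement palindrome, so both strands sit at the minimum
    even = [0.6, 0.05, 0.25, 0.1]
    odd = [0.6, 0.25, 0.05, 0.1]
    pssm = PSSM("skew", [even, odd] * 3)
    assert pssm.score_sequence("A" * 6).best_llr_norm == pytest.approx(1.0)
    assert pssm.score_sequence("CGCGCG").best_llr_norm == pytest.approx(0.0, abs=1e-12)


def test_two_position_hand_example():
    # {A:0.7, others 0.1} x 2 scanned over "AC": one maximum column plus one
    # minimum column, so LLR_norm = (max + min - 2 min) / (2 (max - min)) = 1/2
    # in any log base.
    pssm = PSSM("hand", [[0.7, 0.1, 0.1, 0.1]] * 2)
    m = pssm.score_sequence("AC")
    assert m.best_llr_norm == pytest.approx(0.5, abs=1e-12)
    assert m.best_llr_norm == pytest.approx(llr_norm_brute(pssm, "AC"), abs=1e-12)


def test_ambiguous_bases_contribute_background():
    pssm = PSSM("amb", [[0.7, 0.1, 0.1, 0.1]] * 2)
    # N columns add log(q/q) = 0, i.e. the score of an all-N k-mer sits at
    # the normalized position of LLR = 0
    expected = (0.0 - pssm.llr_min) / (pssm.llr_max - pssm.llr_min)
    assert pssm.score_sequence("NN").best_llr_norm == pytest.approx(expected)


def test_strand_symmetry_of_best_score():
    rng = np.random.default_rng(3)
    for i in range(50):
        pssm = make_random_pssm(f"m{i}", length=int(rng.integers(4, 11)), seed=100 + i)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        fwd = pssm.score_sequence(seq).best_llr_norm
        rev = pssm.score_sequence(reverse_complement(seq)).best_llr_norm
        assert fwd == pytest.approx(rev, abs=1e-12)


def test_scores_match_bruteforce_scorer():
    rng = np.random.default_rng(5)
    for i in range(100):
        pssm = make_random_pssm(f"m{i}", length=int(rng.integers(4, 13)), seed=i)
        seq = "".join(rng.choice(list("ACGTN"), size=60, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        got = pssm.score_sequence(seq).best_llr_norm
        assert got == pytest.approx(llr_norm_brute(pssm, seq), abs=1e-12)


def test_scores_bounded_in_unit_interval():
    rng = np.random.default_rng(8)
    pssm = make_random_pssm("b", length=8, seed=1)
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        s = pssm.score_sequence(seq).best_llr_norm
        assert 0.0 <= s <= 1.0


def test_calibration_median_and_determinism(genome):
    pssm = make_random_pssm("cal", length=8, seed=2)
    t1 = calibrate_match_threshold(pssm, genome, fp_rate=0.5, n_samples=2000, seed=9)
    t2 = calibrate_match_threshold(pssm, genome, fp_rate=0.5, n_samples=2000, seed=9)
    assert t1 == t2
    # fp_rate 0.5 is the null median; well inside (0, 1) for a sharp motif
    assert 0.1 < t1 < 0.9
    # a stricter fp rate can only raise the threshold
    t_strict = calibrate_match_threshold(pssm, genome, fp_rate=0.001, n_samples=2000, seed=9)
    assert t_strict >= t1
    assert pssm.score_sequence(pssm.consensus).best_llr_norm == pytest.approx(1.0)


def test_calibration_warns_on_unstable_quantile(genome):
    pssm = make_random_pssm("warn", length=8, seed=3)
    with pytest.warns(UserWarning, match="unstable"):
        calibrate_match_threshold(pssm, genome, fp_rate=0.001, n_samples=100, seed=0)


def test_scanner_zeroes_non_matches(genome):
    pssm = make_random_pssm("scan", length=8, seed=4)
    scanner = MotifScanner([pssm], fp_rate=0.01, n_calibration=2000).fit(genome, seed=0)
    from dietreg.enrichment import SequenceWindow

    windows = [
        SequenceWindow("chr1", 0, 100, genome["chr1"][:100]),
        SequenceWindow("chr1", 0, 100, genome["chr1"][:46] + pssm.consensus + genome["chr1"][54:100]),
    ]
    scores = scanner.transform(windows)
    assert scores.iloc[1, 0] == pytest.approx(1.0)  # planted consensus
    raw = pssm.score_sequence(windows[0].sequence)
    if not raw.is_match:
        assert scores.iloc[0, 0] == 0.0


def test_transfac_roundtrip(tmp_path):
    motifs = [make_random_pssm(f"mot_{i}", length=8, seed=i) for i in range(3)]
    path = tmp_path / "m.transfac"
    write_transfac(motifs, path)
    back = read_transfac(str(path))
    assert [b.name for b in back] == [m.name for m in motifs]
    for m, b in zip(motifs, back):
        assert b.consensus == m.consensus
        assert np.allclose(b.probs, m.probs, atol=0.01)  # count quantization


def test_meme_minimal_parsing():
    text = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF toy
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.8 0.1 0.05 0.05
0.05 0.8 0.1 0.05
0.05 0.05 0.1 0.8
"""
    pssms = read_meme_minimal(text)
    assert len(pssms) == 1
    assert pssms[0].consensus == "ACT"
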