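"""Generator contracts: determinism, placement truth, and recoverable counts."""

import numpy as np
import pandas as pd
import pytest

from dietreg import io as dio
from dietreg.annotation import RegionAnnotator
from dietreg.expression import filter_differential
from dietreg.synthetic import (
    PlacementError,
    SyntheticConfig,
    generate_expression_table,
    generate_gene_models,
    generate_genome,
    generate_peaks,
    generate_reads,
    make_motif_library,
    plant_motif_instances,
)


def test_genome_gc_within_sampling_error():
    cfg = SyntheticConfig(seed=1, genome_length=10000)
    seq = generate_genome(cfg)[cfg.contig_name]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    sd = np.sqrt(0.5 * 0.5 / len(seq))
    assert abs(gc - 0.5) < 3 * sd


@pytest.mark.parametrize("bad_gc", [0.0, 1.0, -0.2])
def test_degenerate_gc_rejected(bad_gc):
    with pytest.raises(ValueError):
        SyntheticConfig(gc_fraction=bad_gc)


def test_same_config_gives_byte_identical_fasta(tmp_path):
    cfg = SyntheticConfig(seed=5, genome_length=20000)
    paths = []
    for i in range(2):
        p = tmp_path / f"g{i}.fa"
        dio.write_fasta(generate_genome(cfg), p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_gene_models_are_nonoverlapping_and_stranded(genes):
    spans = sorted((g.start, g.end) for g in genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2
    for g in genes:
        assert g.introns, "every synthetic gene is multi-exon"
        if g.strand == "-":
            assert g.tss == g.end - 1
        else:
            assert g.tss == g.start
    assert {g.strand for g in genes} == {"+", "-"}


def test_bed12_roundtrip_preserves_structure(genes, tmp_path):
    path = tmp_path / "genes.bed12"
    dio.write_bed12(genes, path)
    back = dio.read_bed12(path)
    assert len(back) == len(genes)
    for a, b in zip(genes, back):
        assert (a.gene_id, a.start, a.end, a.strand) == (b.gene_id, b.start, b.end, b.strand)
        assert a.exons == b.exons
        assert (a.cds_start, a.cds_end) == (b.cds_start, b.cds_end)


def test_insufficient_space_raises():
    cfg = SyntheticConfig(seed=0, genome_length=50000, n_genes=10)
    with pytest.raises(PlacementError):
        generate_gene_models(cfg, generate_genome(cfg))


def test_single_category_mix_classifies_as_constructed(genes):
    cfg = SyntheticConfig(seed=3, n_peaks=10, category_mix={"proximal_promoter": 1.0})
    peaks = generate_peaks(cfg, genes)
    annot = RegionAnnotator().fit(genes)
    assert all(
        annot.annotate_one(p.interval).category.value == "proximal_promoter" for p in peaks
    )


def test_even_mix_recovered_exactly(genes):
    cfg = SyntheticConfig(
        seed=4, n_peaks=40, category_mix={"intron": 0.5, "distal_intergenic": 0.5}
    )
    peaks = generate_peaks(cfg, genes)
    labels = [p.label for p in peaks]
    assert labels.count("intron") == 20
    assert labels.count("distal_intergenic") == 20


def test_gene_anchored_category_without_genes_raises():
    cfg = SyntheticConfig(seed=0, n_genes=0, n_peaks=5, category_mix={"proximal_promoter": 1.0})
    with pytest.raises(PlacementError):
        generate_peaks(cfg, [])


def test_planting_consensus_scores_maximal(genes, genome):
    cfg = SyntheticConfig(seed=6, n_peaks=20, planting_rate=1.0)
    peaks = generate_peaks(cfg, genes)
    planted, _ = make_motif_library(seed=6)
    edited, truth = plant_motif_instances(peaks, planted, cfg, genome)
    assert truth.planted.all()
    W = cfg.peak_width
    for p in peaks:
        win = edited[p.interval.chrom][p.summit - W // 2 : p.summit + W // 2]
        assert planted.score_sequence(win).best_llr_norm == pytest.approx(1.0)


def test_planting_rate_counts_and_zero(genes, genome):
    planted, _ = make_motif_library(seed=7)
    cfg = SyntheticConfig(seed=7, n_peaks=100, planting_rate=0.6)
    peaks = generate_peaks(cfg, genes)
    _, truth = plant_motif_instances(peaks, planted, cfg, genome)
    assert int(truth.planted.sum()) == 60
    cfg0 = SyntheticConfig(seed=7, n_peaks=100, planting_rate=0.0)
    _, truth0 = plant_motif_instances(peaks, planted, cfg0, genome)
    assert int(truth0.planted.sum()) == 0


def test_planted_instances_inside_their_windows(genes, genome):
    cfg = SyntheticConfig(seed=8, n_peaks=30, planting_rate=0.5)
    peaks = generate_peaks(cfg, genes)
    planted, _ = make_motif_library(seed=8)
    _, truth = plant_motif_instances(peaks, planted, cfg, genome)
    W, k = cfg.peak_width, len(planted)
    by_name = {p.name: p for p in peaks}
    hits = truth[truth.planted]
    assert len(hits) == 15
    for row in hits.itertuples(index=False):
        peak = by_name[row.peak]
        lo, hi = peak.summit - W // 2, peak.summit + W // 2
        assert lo <= row.position and row.position + k <= hi


def test_reads_count_spread_and_determinism(peaks, base_config):
    reads = generate_reads(peaks[:3], base_config)
    assert len(reads) == 3 * base_config.read_depth
    for i, peak in enumerate(peaks[:3]):
        chunk = reads[i * 50 : (i + 1) * 50]
        assert all(
            abs(r.five_prime - peak.summit) <= base_config.read_truncation + 1 for r in chunk
        )
    assert reads == generate_reads(peaks[:3], base_config)


def test_expression_table_recovers_direction_counts():
    cfg = SyntheticConfig(seed=9, direction_counts=(25, 18, 12, 7), universe_size=500)
    df = generate_expression_table(cfg)
    assert len(df) == 500
    set_a = filter_differential(df, "A")
    set_b = filter_differential(df, "B")
    overlap = set_a & set_b
    assert len(set_a) == len(set_b) == len(overlap) == 25 + 18 + 12 + 7
    sub = df[df.gene_id.isin(overlap)]
    up_a, up_b = sub.log2fc_A > 0, sub.log2fc_B > 0
    assert int((up_a & up_b).sum()) == 25
    assert int((~up_a & ~up_b).sum()) == 18
    assert int((up_a & ~up_b).sum()) == 12
    assert int((~up_a & up_b).sum()) == 7


def test_all_null_expression_table_has_no_differential_genes():
    cfg = SyntheticConfig(seed=10, direction_counts=(0, 0, 0, 0), universe_size=300)
    df = generate_expression_table(cfg)
    assert filter_differential(df, "A") == set()
    assert filter_differential(df, "B") == set()


def test_expression_tsv_roundtrip(tmp_path):
    cfg = SyntheticConfig(seed=11, direction_counts=(5, 4, 3, 2), universe_size=100)
    df = generate_expression_table(cfg)
    path = tmp_path / "expr.tsv"
    dio.write_expression_table(df, path)
    back = dio.read_expression_table(path)
    assert list(back.columns) == list(df.columns)
    pd.testing.assert_series_equal(back.gene_id, df.gene_id)
    assert filter_differential(back, "A") == filter_differential(df, "A")
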