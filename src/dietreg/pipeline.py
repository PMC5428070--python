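"""Composed pipeline runs used for validation and reporting.

The planted-motif recovery experiment is the package's own positive
control for the whole enrichment stage: plant one known motif into half of
a set of accessible-site windows on a small random genome, scan a library
of that motif plus random decoys with empirically calibrated thresholds,
test against a GC-matched background, collapse by affinity-propagation
clusters, and ask whether the planted motif comes out with the smallest
BH q-value.
"""

from __future__ import annotations

import numpy as np

from .clustering import MotifAffinityPropagation, collapse_by_cluster
from .enrichment import extract_windows, motif_enrichment, sample_matched_background
from .intervals import GenomicInterval, Peak
from .motifs import MotifScanner
from .synthetic import (
    SyntheticConfig,
    generate_genome,
    make_motif_library,
    plant_motif_instances,
)


def planted_motif_recovery(
    seed: int,
    genome_length: int = 10_000,
    n_windows: int = 200,
    planting_rate: float = 0.5,
    n_decoys: int = 20,
    motif_length: int = 8,
    fp_rate: float = 0.001,
    n_calibration: int = 2000,
) -> dict:
    """One seeded replicate of the planted-motif recovery experiment.

    Returns a dict with the winning motif after cluster collapsing, its
    q-value, and whether it is the planted one.
    """
    cfg = SyntheticConfig(
        seed=seed,
        genome_length=genome_length,
        n_genes=0,
        n_peaks=n_windows,
        planting_rate=planting_rate,
        category_mix={"distal_intergenic": 1.0},
    )
    genome = generate_genome(cfg)
    W = cfg.peak_width
    rng = np.random.default_rng([seed, 6])
    starts = rng.integers(0, genome_length - W, size=n_windows)
    peaks = [
        Peak(GenomicInterval(cfg.contig_name, int(s), int(s) + W), int(s) + W // 2,
             name=f"w{i:04d}")
        for i, s in enumerate(starts)
    ]
    planted, decoys = make_motif_library(
        n_decoys=n_decoys, length=motif_length, seed=seed
    )
    genome, truth = plant_motif_instances(peaks, planted, cfg, genome)
    pssms = [planted] + decoys

    windows = extract_windows([(p.interval.chrom, p.summit) for p in peaks], genome)
    MotifScanner(pssms, fp_rate=fp_rate, n_calibration=n_calibration).fit(
        genome, seed=seed
    )
    background = sample_matched_background(windows, genome, seed=seed + 1)
    results = motif_enrichment(windows, background, pssms)
    clusters = MotifAffinityPropagation().fit(pssms)
    collapsed = collapse_by_cluster(results, clusters.labels_)
    best = min(collapsed, key=lambda r: (r.q_value, r.p_value, r.motif))
    return {
        "best_motif": best.motif,
        "recovered": best.motif == planted.name,
        "q_value": best.q_value,
        "p_value": best.p_value,
        "n_planted": int(truth.planted.sum()),
        "n_clusters": clusters.n_clusters_,
    }
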