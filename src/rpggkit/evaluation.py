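"""End-to-end evaluation experiments on synthetic cohorts.

These harnesses wire the generator, graph builder, aligner and genotyper
together the way the method is evaluated: error-free paired-end reads
tiled over every VNTR region plus flanks are aligned back to the RPGG to
measure alignment fidelity, and a leave-one-out experiment with planted
per-run sampling biases measures length-prediction accuracy against the
naive read-depth baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aligner import AlignParams, align_sample, threading_threshold
from .genotyper import evaluate_predictions, leave_one_out, read_depth_baseline
from .graph import build_rpgg
from .simulate import (
    SimConfig,
    diploid_lengths,
    gen_depth_bias,
    gen_kms,
    gen_population,
    locus_regions,
    sim_reads,
)


def alignment_fidelity(
    n_loci: int = 200,
    n_genomes: int = 10,
    copy_number_range: tuple[int, int] = (5, 100),
    seed: int = 0,
    step: int = 25,
    k: int = 21,
    identity_regime: float = 0.9,
) -> dict:
    """Align error-free tiling read pairs from all VNTR regions (plus
    flanks) back to the RPGG built from the same genomes.

    Reads are 150 bp pairs with 600 bp insert, tiled every ``step`` bases
    (still error-free exhaustively overlapping templates; ``step`` only
    thins the redundant start positions).  The threading threshold is set
    to ceil((read_len - k + 1) * identity_regime) so that every feasible
    pair meets the identity floor by construction, and the fraction of
    aligned pairs at >= 90% identity is reported as a percentage.
    """
    cfg = SimConfig(
        n_loci=n_loci,
        n_genomes=n_genomes,
        copy_number_range=copy_number_range,
        seed=seed,
    )
    haps, truth, catalog = gen_population(cfg)
    rpgg = build_rpgg(catalog.regions(haps), k=k)
    pairs = sim_reads(
        haps, cfg, mode="tiling", regions=locus_regions(truth, cfg.flank_len), step=step
    )
    params = AlignParams(
        k=k, thcth=threading_threshold(cfg.read_len, k, identity_regime)
    )
    kms, _, stats = align_sample(pairs, rpgg, params)
    aligned = stats.feasible
    pct = 100.0 * stats.identity_ge_90 / aligned if aligned else 0.0
    return {
        "pct_identity_ge_90": pct,
        "pairs": stats.pairs,
        "assigned": stats.assigned,
        "aligned": aligned,
        "threading_threshold": params.thcth,
        "kms": kms,
        "rpgg_vertices": rpgg.n_vertices(),
    }


def locus_assignment_accuracy(
    n_loci: int = 30,
    n_genomes: int = 4,
    seed: int = 0,
    step: int = 11,
    k: int = 21,
) -> dict:
    """Fraction of VNTR-origin tiling pairs assigned to their true locus
    (read names carry the template locus)."""
    cfg = SimConfig(
        n_loci=n_loci, n_genomes=n_genomes, copy_number_range=(5, 40), seed=seed
    )
    haps, truth, catalog = gen_population(cfg)
    rpgg = build_rpgg(catalog.regions(haps), k=k)
    pairs = sim_reads(
        haps, cfg, mode="tiling", regions=locus_regions(truth, cfg.flank_len), step=step
    )
    from .aligner import align_pair

    params = AlignParams(k=k)
    total = correct = 0
    for name, s1, s2 in pairs:
        true_locus = int(name.rsplit("|", 1)[1])
        aln = align_pair(s1, s2, rpgg, params)
        total += 1
        if aln.locus == true_locus and aln.feasible:
            correct += 1
    return {"total": total, "correct": correct, "fraction": correct / total}


def length_prediction_experiment(
    n_loci: int = 50,
    n_genomes: int = 12,
    n_runs: int = 2,
    coverage: float = 30.0,
    bias_range: tuple[float, float] = (1.5, 2.0),
    noise_sd: float = 0.01,
    seed: int = 0,
) -> dict:
    """Leave-one-out length prediction on a cohort with planted per-run
    locus-specific sampling biases, against the read-depth baseline.

    Truth lengths come from a generated population; kms matrices follow
    the generative model kms = cov * bias * length with Poisson noise.
    The baseline divides per-locus aligned bases (cov * bias * length) by
    the global depth, so planted bias propagates into its estimate —
    exactly the failure mode the borrowed-bias correction removes.
    """
    cfg = SimConfig(
        n_loci=n_loci,
        n_genomes=n_genomes,
        copy_number_range=(5, 100),
        coverage=coverage,
        seed=seed,
    )
    _, truth, _ = gen_population(cfg)
    lengths = diploid_lengths(truth)  # genome x locus
    samples = list(lengths.index)
    run_labels = {s: f"run{i % n_runs}" for i, s in enumerate(samples)}
    bias, rd = gen_depth_bias(
        samples,
        run_labels,
        n_loci=n_loci,
        bias_range=bias_range,
        noise_sd=noise_sd,
        seed=seed + 1,
    )
    bias.columns = lengths.columns
    rng = np.random.default_rng(seed + 2)
    cov = pd.Series(rng.uniform(0.8, 1.2, size=len(samples)) * coverage, index=samples)
    kms = gen_kms(lengths, cov, bias, seed=seed + 3)

    preds = leave_one_out(kms, cov, rd, lengths, run_labels)
    rpgg_eval = evaluate_predictions(preds, lengths)

    aligned_bases = kms  # error-free: every sampled VNTR base yields a counted k-mer
    baseline = pd.DataFrame(
        {s: read_depth_baseline(aligned_bases.loc[s], float(cov[s])) for s in samples}
    ).T
    base_eval = evaluate_predictions(baseline, lengths)
    return {
        "rpgg": rpgg_eval,
        "baseline": base_eval,
        "rpgg_mape": rpgg_eval["mape"],
        "baseline_mape": base_eval["mape"],
        "rpgg_accuracy_min": float(rpgg_eval["accuracy"].min()),
    }
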