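"""VNTR length genotyping with locus-specific sampling-bias correction.

The model: if a sample s were sequenced uniformly at global depth cov_s,
the summed VNTR k-mer count kms_{s,l} of locus l would equal cov_s times
the diploid mean locus length L_{g,l}.  Real sampling deviates by a
locus-specific bias (LSB)

    b_{s,l} = kms_{s,l} / (cov_s * L_{g,l}),

estimable only for samples with assembly ground truth.  For a new sample
the bias vector is borrowed from the nearest reference sample — the one
whose control-region read-depth profile RD has the highest squared Pearson
correlation with the query's, restricted to the same sequencing run when
run labels exist — and the length is predicted as

    L_{s,l} = kms_{s,l} / (cov_s * bhat_l).

Loci are screened beforehand by alignment quality: the r^2 of regressing
assembly k-mer counts on read-derived k-mer counts, averaged over samples,
must be at least 0.96.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALN_R2_CUTOFF = 0.96


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either side is degenerate
    (fewer than 2 points or zero variance).  Note perfect anticorrelation
    scores 1 — r^2 measures linear fit, not direction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = stats.pearsonr(x, y)[0]
    return float(r * r)


def compute_aln_r2(
    assembly_counts: pd.DataFrame, read_counts: pd.DataFrame
) -> pd.Series:
    """Per-locus alignment-quality score across samples.

    Both inputs are tidy frames with columns (sample, locus, kmer, count)
    or, more simply, mappings provided via :func:`aln_r2_one`; this
    convenience form expects matching (sample, locus) groups.
    """
    merged = assembly_counts.merge(
        read_counts, on=["sample", "locus", "kmer"], how="outer", suffixes=("_asm", "_read")
    ).fillna(0.0)
    per = (
        merged.groupby(["locus", "sample"])
        .apply(
            lambda g: pearson_r2(g["count_asm"].values, g["count_read"].values),
            include_groups=False,
        )
        .rename("aln_r2")
    )
    return per.groupby("locus").mean()


def aln_r2_one(assembly_counts: dict, read_counts: dict) -> float:
    """Alignment quality for one (sample, locus): r^2 over the union of
    k-mers (the assembly's k-mer set; absent read counts are zero)."""
    keys = sorted(assembly_counts)
    a = np.array([assembly_counts[k] for k in keys], dtype=float)
    r = np.array([read_counts.get(k, 0) for k in keys], dtype=float)
    return pearson_r2(a, r)


def valid_locus_mask(mean_aln_r2: pd.Series, cutoff: float = ALN_R2_CUTOFF) -> pd.Series:
    """Loci whose mean alignment quality reaches the cutoff (>= 0.96)."""
    return mean_aln_r2 >= cutoff


@dataclass
class SampleBias:
    sample: str
    cov: float
    rd: pd.Series  # control-region depths
    b: pd.Series  # per-locus bias


def estimate_lsb(
    kms: pd.Series, cov: float, truth_lengths: pd.Series
) -> pd.Series:
    """Locus-specific sampling bias b = kms / (cov * L) for a sample with
    known truth lengths; loci with zero/undefined truth get NaN."""
    L = truth_lengths.reindex(kms.index).astype(float)
    b = kms.astype(float) / (cov * L)
    b[~(L > 0)] = np.nan
    return b


def nearest_reference_sample(
    query_rd: pd.Series,
    reference_rd: pd.DataFrame,
    run_labels: dict | None = None,
    query_run: str | None = None,
) -> str:
    """Eq.-4 style reference selection: the reference sample whose
    control-region depth vector maximizes r^2 with the query's, restricted
    to the query's sequencing run when labels are given.  Deterministic
    tie-break on sample id."""
    refs = list(reference_rd.index)
    if run_labels is not None and query_run is not None:
        refs = [s for s in refs if run_labels.get(s) == query_run]
    if not refs:
        raise ValueError("no reference sample available")
    scored = sorted(
        ((-pearson_r2(query_rd.values, reference_rd.loc[s].values), s) for s in refs)
    )
    return scored[0][1]


def predict_lengths(kms: pd.Series, cov: float, bhat: pd.Series) -> pd.Series:
    """Length prediction L = kms / (cov * bhat); loci with zero or missing
    bias are reported missing (NaN), never infinite."""
    if cov <= 0:
        raise ValueError("cov must be positive")
    b = bhat.reindex(kms.index).astype(float)
    out = kms.astype(float) / (cov * b)
    out[~(b > 0)] = np.nan
    return out


def read_depth_baseline(
    aligned_bases: pd.Series, global_depth: float
) -> pd.Series:
    """Naive baseline: total aligned bases in each reference interval
    divided by the global read depth.  Local sampling bias propagates
    directly into the estimate (the failure mode bias correction fixes)."""
    return aligned_bases.astype(float) / global_depth


def evaluate_predictions(
    estimates: pd.DataFrame, truth: pd.DataFrame
) -> dict:
    """Accuracy (per-genome r^2 of estimate vs truth across loci) and MAPE
    per genome and per locus.  Zero-truth loci are excluded from MAPE and
    counted."""
    est, tru = estimates.align(truth, join="inner")
    ape = (est - tru).abs() / tru.where(tru > 0)
    n_zero = int((~(tru > 0)).sum().sum())
    acc = {
        g: pearson_r2(est.loc[g].values, tru.loc[g].values) for g in est.index
    }
    return {
        "accuracy": pd.Series(acc),
        "mape_per_genome": ape.mean(axis=1),
        "mape_per_locus": ape.mean(axis=0),
        "mape": float(np.nanmean(ape.values)),
        "n_zero_truth": n_zero,
    }


def leave_one_out(
    kms: pd.DataFrame,
    cov: pd.Series,
    rd: pd.DataFrame,
    truth_lengths: pd.DataFrame,
    run_labels: dict,
) -> pd.DataFrame:
    """Leave-one-out length prediction over a cohort with assembly truth.

    For each sample, the bias vector is re-estimated from the remaining
    samples' truths and borrowed from the nearest same-run reference; the
    held-out sample's own truth is never used.
    """
    preds = {}
    for s in kms.index:
        refs = [x for x in kms.index if x != s]
        ref_b = pd.DataFrame(
            {
                x: estimate_lsb(kms.loc[x], float(cov[x]), truth_lengths.loc[x])
                for x in refs
            }
        ).T
        shat = nearest_reference_sample(
            rd.loc[s], rd.loc[refs], run_labels=run_labels, query_run=run_labels[s]
        )
        preds[s] = predict_lengths(kms.loc[s], float(cov[s]), ref_b.loc[shat])
    return pd.DataFrame(preds).T.reindex(kms.index)
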