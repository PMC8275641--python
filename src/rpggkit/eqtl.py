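"""cis-association of VNTR dosage with gene expression.

Expression is residualized against a covariate matrix C (intercept, sex,
platform, expression factors, genotype PCs — all consumed as columns) by
projection, Y = (I - H) Y' with H = C (C^T C)^{-1} C^T, then z-scored per
gene.  Genotype is depth- and ploidy-adjusted dosage, z-scored per locus.
Each (gene, VNTR) pair within a 100 kb window is tested by simple linear
regression with a two-sided t-test on the slope; within a gene, p-values
are Bonferroni-adjusted over that gene's tested VNTRs, the lead VNTR is
the smallest adjusted p, and gene-level FDR is controlled by
Benjamini-Hochberg over lead adjusted p-values (at most one causal VNTR
per gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

WINDOW = 100_000


def adjust_dosage(kms: pd.DataFrame, cov: pd.Series, ploidy: int = 2) -> pd.DataFrame:
    """Depth- and ploidy-adjusted genotype values, then z-scored per locus.
    Zero-variance loci are left as NaN columns (skipped downstream)."""
    d = kms.div(cov.reindex(kms.index), axis=0) / ploidy
    sd = d.std(ddof=0)
    with np.errstate(invalid="ignore"):
        z = (d - d.mean()) / sd.replace(0, np.nan)
    return z


def residualize_expression(Yp: pd.DataFrame, C: pd.DataFrame) -> pd.DataFrame:
    """Project out covariates and z-score per gene.

    C must contain an intercept column and be full column rank; collinear
    columns are named in the error.  Genes whose residual is numerically
    zero (expression lies in the covariate span) are dropped with a
    warning.
    """
    C = C.loc[Yp.index]
    Cv = C.values.astype(float)
    rank = np.linalg.matrix_rank(Cv)
    if rank < Cv.shape[1]:
        bad = []
        cols = list(C.columns)
        base_rank = 0
        kept: list[int] = []
        for j in range(Cv.shape[1]):
            r = np.linalg.matrix_rank(Cv[:, kept + [j]])
            if r > base_rank:
                kept.append(j)
                base_rank = r
            else:
                bad.append(cols[j])
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")
    # residuals via least squares (numerically equivalent to (I-H)Y')
    beta, *_ = np.linalg.lstsq(Cv, Yp.values.astype(float), rcond=None)
    R = Yp.values - Cv @ beta
    out = pd.DataFrame(R, index=Yp.index, columns=Yp.columns)
    sd = out.std(ddof=0)
    dead = sd[sd < 1e-12].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} gene(s) with zero residual variance: {list(dead)[:5]}")
        out = out.drop(columns=dead)
        sd = sd.drop(dead)
    return (out - out.mean()) / sd


def interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two intervals on the same contig; 0 when overlapping."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


@dataclass
class Association:
    gene: object
    locus: object
    beta: float
    t: float
    p: float
    n: int
    distance: int
    p_adj: float = np.nan
    lead: bool = False
    fdr_pass: bool = False


def association_scan(
    genotype: pd.DataFrame,
    expression: pd.DataFrame,
    vntr_intervals: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    window: int = WINDOW,
) -> list[Association]:
    """Simple linear regression of expression on dosage for every
    (gene, VNTR) pair whose intervals are within ``window`` bases
    (closest-edge distance; intervals are (contig, start, end) frames
    indexed by gene/locus id).  Zero-variance genotypes are skipped.

    With z-scored inputs the slope equals the Pearson correlation.
    """
    out: list[Association] = []
    samples = genotype.index.intersection(expression.index)
    G = genotype.loc[samples]
    E = expression.loc[samples]
    for gene in expression.columns:
        if gene not in gene_intervals.index:
            continue
        grow = gene_intervals.loc[gene]
        for locus in genotype.columns:
            if locus not in vntr_intervals.index:
                continue
            vrow = vntr_intervals.loc[locus]
            if vrow["contig"] != grow["contig"]:
                continue
            dist = interval_distance(
                (int(grow["start"]), int(grow["end"])),
                (int(vrow["start"]), int(vrow["end"])),
            )
            if dist > window:
                continue
            x = G[locus].values.astype(float)
            y = E[gene].values.astype(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            n = len(x)
            if n < 3 or x.std() == 0:
                continue
            res = stats.linregress(x, y)
            t = res.slope / res.stderr if res.stderr > 0 else np.inf
            out.append(
                Association(
                    gene=gene,
                    locus=locus,
                    beta=float(res.slope),
                    t=float(t),
                    p=float(res.pvalue),
                    n=n,
                    distance=dist,
                )
            )
    return out


def gene_level_fdr(results: list[Association], q: float = 0.05) -> list[Association]:
    """Two-level multiple-testing procedure.

    Per gene: Bonferroni-adjust nominal p over that gene's tested VNTRs
    and mark the lead VNTR (smallest adjusted p; ties by smaller distance,
    then lower locus id).  Across genes: Benjamini-Hochberg at ``q`` on
    the lead adjusted p-values; lead VNTRs of passing genes are eVNTRs.
    """
    by_gene: dict = {}
    for r in results:
        by_gene.setdefault(r.gene, []).append(r)
    leads = []
    for gene, rs in by_gene.items():
        m = len(rs)
        for r in rs:
            r.p_adj = min(1.0, r.p * m)
            r.lead = False
            r.fdr_pass = False
        lead = min(rs, key=lambda r: (r.p_adj, r.distance, str(r.locus)))
        lead.lead = True
        leads.append(lead)
    if leads:
        rejected, _ = fdrcorrection([l.p_adj for l in leads], alpha=q)
        for l, rej in zip(leads, rejected):
            l.fdr_pass = bool(rej)
    return results


def results_frame(results: list[Association]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "locus": r.locus,
                "beta": r.beta,
                "t": r.t,
                "p": r.p,
                "p_adj": r.p_adj,
                "distance": r.distance,
                "n": r.n,
                "lead": r.lead,
                "fdr_pass": r.fdr_pass,
            }
            for r in results
        ]
    )
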