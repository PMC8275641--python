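"""Population analyses on k-mer dosage.

k-mer dosage (kms / cov) is a depth-normalized proxy for VNTR length.
This module provides:

* V_ST — the variance-partitioning stratification statistic for
  quantitative copy-number values: the fraction of total dosage variance
  not explained by within-population variance, clipped at 0.  Population
  variances use denominator n (not n-1) so the between-population form
  sum n_i (mu_i - mu_T)^2 / (n_T sigma_T^2) is an exact algebraic
  identity.
* an unstable-locus screen flagging individuals more than six standard
  deviations above a population/locus mean, gated on strong unimodality
  (Hartigan dip p > 0.9) after discarding dosages below 10, with a
  blacklist for individuals that are outliers at four or more other loci.
* differential motif usage/expansion between two populations via the
  lasso-selected most informative k-mer (mi-kmer) and bootstrap nulls.
* DBSCAN-based sample outlier removal on control-region depth plus dosage
  features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.linear_model import Lasso
from sklearn.neighbors import NearestNeighbors

from ._dip import dip_pvalue


def kmer_dosage(kms: pd.DataFrame, cov: pd.Series) -> pd.DataFrame:
    """Dosage = kms / cov, per sample (rows) and locus (columns)."""
    cov = cov.reindex(kms.index)
    if (cov <= 0).any():
        raise ValueError("cov must be positive for all samples")
    return kms.div(cov, axis=0)


@dataclass
class VstResult:
    vst: float
    var_all: float
    var_within: float  # (1/n_T) sum n_i var_i
    n_total: int
    pop_n: dict
    pop_mean: dict
    pop_var: dict
    mean_total: float


def compute_vst(values, labels) -> VstResult:
    """V_ST of one locus' dosage values given population labels.

    V_ST = max(0, (var_all - (1/n) sum_p var_p n_p) / var_all) with
    population variances on denominator n; var_all = 0 yields V_ST = 0.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    pops = sorted(set(lab.tolist()))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    n_t = len(x)
    var_all = float(np.var(x))
    pop_n, pop_mean, pop_var = {}, {}, {}
    within = 0.0
    for p in pops:
        xi = x[lab == p]
        if len(xi) < 2:
            raise ValueError(f"population {p} has fewer than 2 samples")
        pop_n[p] = len(xi)
        pop_mean[p] = float(np.mean(xi))
        pop_var[p] = float(np.var(xi))
        within += pop_var[p] * len(xi)
    within /= n_t
    vst = 0.0 if var_all == 0 else max(0.0, (var_all - within) / var_all)
    return VstResult(
        vst=vst,
        var_all=var_all,
        var_within=within,
        n_total=n_t,
        pop_n=pop_n,
        pop_mean=pop_mean,
        pop_var=pop_var,
        mean_total=float(np.mean(x)),
    )


def vst_between_form(values, labels) -> float:
    """Equivalent between-population form:
    sum_i n_i (mu_i - mu_T)^2 / (n_T * sigma_T^2), clipped at 0."""
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    var_all = float(np.var(x))
    if var_all == 0:
        return 0.0
    mu_t = float(np.mean(x))
    num = 0.0
    for p in set(lab.tolist()):
        xi = x[lab == p]
        num += len(xi) * (float(np.mean(xi)) - mu_t) ** 2
    return max(0.0, num / (len(x) * var_all))


def vst_table(dosage: pd.DataFrame, labels: pd.Series, sd_flag: float = 3.0) -> pd.DataFrame:
    """Per-locus V_ST with a top-locus flag at mean + ``sd_flag``*SD over loci."""
    lab = labels.reindex(dosage.index)
    rows = {}
    for locus in dosage.columns:
        rows[locus] = compute_vst(dosage[locus].values, lab.values).vst
    out = pd.DataFrame({"vst": pd.Series(rows)})
    mu, sd = out["vst"].mean(), out["vst"].std()
    out["top"] = out["vst"] >= mu + sd_flag * sd
    return out


# ---------------------------------------------------------------------------
# unstable loci


def detect_unstable_loci(
    dosage: pd.DataFrame,
    labels: pd.Series,
    sd_thresh: float = 6.0,
    min_dosage: float = 10.0,
    dip_p_gate: float = 0.9,
    blacklist_loci: int = 4,
    min_retained: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen for loci with rare dosage hyper-expansion.

    Per (population, locus): discard individuals with dosage below
    ``min_dosage``; require at least ``min_retained`` individuals and a
    strongly unimodal distribution (dip p > ``dip_p_gate``); flag
    individuals at or above mean + ``sd_thresh`` SD.  A candidate locus is
    then removed if any of its outlier individuals is an outlier at
    ``blacklist_loci`` or more other loci (systematically aberrant
    genomes, not locus instability).

    Returns a DataFrame (locus, sample, population, dosage, zscore,
    removed_by_blacklist).
    """
    rng = np.random.default_rng(seed)
    lab = labels.reindex(dosage.index)
    hits = []
    for locus in dosage.columns:
        for pop, idx in lab.groupby(lab).groups.items():
            vals = dosage.loc[idx, locus]
            vals = vals[vals >= min_dosage]
            if len(vals) < min_retained:
                continue
            _, p = dip_pvalue(vals.values, rng=rng)
            if not p > dip_p_gate:
                continue
            mu, sd = vals.mean(), vals.std(ddof=0)
            if sd == 0:
                continue
            z = (vals - mu) / sd
            for s, zz in z[z >= sd_thresh].items():
                hits.append(
                    {
                        "locus": locus,
                        "sample": s,
                        "population": pop,
                        "dosage": float(vals[s]),
                        "zscore": float(zz),
                    }
                )
    out = pd.DataFrame(hits, columns=["locus", "sample", "population", "dosage", "zscore"])
    if out.empty:
        out["removed_by_blacklist"] = pd.Series(dtype=bool)
        return out
    per_sample = out.groupby("sample")["locus"].nunique()
    bad_samples = set(per_sample[per_sample >= blacklist_loci + 1].index)
    bad_loci = set(out.loc[out["sample"].isin(bad_samples), "locus"])
    out["removed_by_blacklist"] = out["locus"].isin(bad_loci)
    return out


# ---------------------------------------------------------------------------
# differential motif usage / expansion


@dataclass
class MiKmer:
    kmer: object
    weight: float
    alpha: float
    vex: float  # proportion of length variance explained in the reference pop


def _simple_r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0 or len(x) < 2:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def find_mi_kmer(
    X: pd.DataFrame, y: pd.Series, alphas=None
) -> MiKmer | None:
    """Most informative k-mer: lasso of length on per-k-mer dosage.

    Predictors and response are z-scored; the penalty weight is scanned
    0.9, 0.8, ... down to 0.1 until at least one coefficient is positive.
    The k-mer with the highest weight wins (ties to the lowest k-mer id);
    returns None when no positive weight exists at the smallest penalty
    (locus untestable).
    """
    if alphas is None:
        alphas = np.round(np.arange(0.9, 0.09, -0.1), 10)
    ysd = y.std(ddof=0)
    if ysd == 0:
        return None
    yz = (y - y.mean()) / ysd
    X = X[sorted(X.columns, key=str)]  # id order: deterministic tie behaviour
    Xsd = X.std(axis=0, ddof=0)
    cols = Xsd[Xsd > 0].index
    if len(cols) == 0:
        return None
    Xz = (X[cols] - X[cols].mean()) / Xsd[cols]
    for alpha in alphas:
        model = Lasso(alpha=float(alpha), fit_intercept=False, max_iter=5000)
        model.fit(Xz.values, yz.values)
        coef = pd.Series(model.coef_, index=cols)
        pos = coef[coef > 0]
        if len(pos):
            top = pos[pos == pos.max()].index.min()
            vex = _simple_r2(X[top].values.astype(float), y.values.astype(float))
            return MiKmer(kmer=top, weight=float(coef[top]), alpha=float(alpha), vex=vex)
    return None


@dataclass
class MotifTestResult:
    kmer: object
    alpha: float
    kmc_d: float  # median mi-kmer count difference, pop A - pop B
    r2_d: float  # difference in proportion of variance explained
    p_kmc: float
    p_r2: float


def bootstrap_motif_test(
    x_a: np.ndarray,
    y_a: np.ndarray,
    x_b: np.ndarray,
    y_b: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    kmer=None,
    alpha: float = np.nan,
) -> MotifTestResult:
    """Two-sided bootstrap test of differential mi-kmer usage/expansion.

    Observed statistics: kmc_d = median(x_A) - median(x_B) and
    r2_d = VEX_A - VEX_B (VEX = r^2 of length on the mi-kmer within a
    population).  The null resamples population A with replacement
    N_A + N_B times; the first N_A resamples play pseudo-A and the last
    N_B pseudo-B.  p = (1 + #{|T*| >= |T|}) / (1 + B).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x_a, y_a = np.asarray(x_a, float), np.asarray(y_a, float)
    x_b, y_b = np.asarray(x_b, float), np.asarray(y_b, float)
    na, nb = len(x_a), len(x_b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per population")
    kmc_d = float(np.median(x_a) - np.median(x_b))
    r2_d = _simple_r2(x_a, y_a) - _simple_r2(x_b, y_b)

    idx = rng.integers(0, na, size=(n_boot, na + nb))
    xs, ys = x_a[idx], y_a[idx]
    xa_s, xb_s = xs[:, :na], xs[:, na:]
    ya_s, yb_s = ys[:, :na], ys[:, na:]
    kmc_null = np.median(xa_s, axis=1) - np.median(xb_s, axis=1)

    def _row_r2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        um = u - u.mean(axis=1, keepdims=True)
        vm = v - v.mean(axis=1, keepdims=True)
        num = (um * vm).sum(axis=1)
        den = np.sqrt((um**2).sum(axis=1) * (vm**2).sum(axis=1))
        out = np.zeros(len(u))
        ok = den > 0
        out[ok] = (num[ok] / den[ok]) ** 2
        return out

    r2_null = _row_r2(xa_s, ya_s) - _row_r2(xb_s, yb_s)
    p_kmc = (1.0 + np.sum(np.abs(kmc_null) >= abs(kmc_d))) / (1.0 + n_boot)
    p_r2 = (1.0 + np.sum(np.abs(r2_null) >= abs(r2_d))) / (1.0 + n_boot)
    return MotifTestResult(
        kmer=kmer, alpha=alpha, kmc_d=kmc_d, r2_d=float(r2_d), p_kmc=float(p_kmc), p_r2=float(p_r2)
    )


# ---------------------------------------------------------------------------
# sample outliers


def filter_sample_outliers(
    rd: pd.DataFrame,
    dosage: pd.DataFrame,
    min_samples: int = 5,
    eps: float | None = None,
) -> list:
    """Density-based sample outlier removal (DBSCAN) on standardized
    control-region depths concatenated with VNTR dosages.

    ``eps`` defaults to twice the median distance to the
    ``min_samples``-th nearest neighbour (adaptive, deterministic).
    Samples labelled noise are dropped; raises if nothing survives.
    """
    feats = pd.concat([rd, dosage.reindex(rd.index)], axis=1)
    z = (feats - feats.mean()) / feats.std(ddof=0).replace(0, 1.0)
    Xz = z.fillna(0.0).values
    if eps is None:
        nn = NearestNeighbors(n_neighbors=min(min_samples + 1, len(Xz)))
        nn.fit(Xz)
        dist, _ = nn.kneighbors(Xz)
        eps = 2.0 * float(np.median(dist[:, -1]))
        if eps <= 0:
            eps = 0.5
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(Xz)
    kept = [s for s, l in zip(rd.index, labels) if l != -1]
    if not kept:
        raise ValueError("DBSCAN flagged every sample; parameterization rejected")
    return kept
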