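"""V_ST, dip/unstable-locus screen, mi-kmer tests, sample outliers."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from rpggkit._dip import dip_pvalue, dip_statistic
from rpggkit.popstats import (
    bootstrap_motif_test,
    compute_vst,
    detect_unstable_loci,
    filter_sample_outliers,
    find_mi_kmer,
    kmer_dosage,
    vst_between_form,
    vst_table,
)


def test_dosage_is_kms_over_cov():
    kms = pd.DataFrame({0: [100.0, 50.0]}, index=["a", "b"])
    cov = pd.Series({"a": 10.0, "b": 5.0})
    d = kmer_dosage(kms, cov)
    assert d[0].tolist() == [10.0, 10.0]
    assert kmer_dosage(kms, cov / 2)[0].tolist() == [20.0, 20.0]
    with pytest.raises(ValueError):
        kmer_dosage(kms, pd.Series({"a": 0.0, "b": 5.0}))


# ---------------------------------------------------------------------------
# V_ST


def test_vst_extremes():
    r = compute_vst([1.0, 1.0, 3.0, 3.0], ["p1", "p1", "p2", "p2"])
    assert r.vst == 1.0 and r.var_all == 1.0 and r.var_within == 0.0
    r0 = compute_vst([0.0, 2.0, 0.0, 2.0], ["p1", "p1", "p2", "p2"])
    assert r0.vst == 0.0
    rc = compute_vst([5.0, 5.0, 5.0, 5.0], ["p1", "p1", "p2", "p2"])
    assert rc.vst == 0.0  # no variance to partition


def test_vst_input_validation():
    with pytest.raises(ValueError):
        compute_vst([1.0, 2.0], ["p1", "p1"])
    with pytest.raises(ValueError):
        compute_vst([1.0, 2.0, 3.0], ["p1", "p1", "p2"])


def _random_config(rng):
    pops = rng.integers(2, 5)
    vals, labs = [], []
    for p in range(pops):
        n = int(rng.integers(2, 30))
        vals.append(rng.normal(rng.uniform(0, 10), rng.uniform(0.1, 5), n))
        labs += [f"p{p}"] * n
    return np.concatenate(vals), np.array(labs)


def test_vst_forms_agree_and_bounded():
    rng = np.random.default_rng(12)
    for _ in range(300):
        vals, labs = _random_config(rng)
        a = compute_vst(vals, labs).vst
        b = vst_between_form(vals, labs)
        assert abs(a - b) < 1e-12
        assert 0.0 <= a <= 1.0


def test_vst_decreases_as_within_variance_inflates():
    rng = np.random.default_rng(3)
    base = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
    labs = np.array(["a"] * 50 + ["b"] * 50)
    prev = 1.1
    for scale in (1.0, 2.0, 4.0, 8.0):
        x = base.copy()
        for p in ("a", "b"):
            m = x[labs == p].mean()
            x[labs == p] = m + (x[labs == p] - m) * scale
        v = compute_vst(x, labs).vst
        assert v < prev
        prev = v


def test_vst_permutation_null_is_small():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
    labs = np.array(["a"] * 40 + ["b"] * 40)
    vs = []
    for _ in range(200):
        vs.append(compute_vst(x, rng.permutation(labs)).vst)
    assert np.mean(vs) < 0.05  # ~0 in expectation under label permutation


def test_vst_table_flags_three_sd_outliers():
    rng = np.random.default_rng(5)
    n = 40
    labs = pd.Series(["a"] * n + ["b"] * n, index=range(2 * n))
    cols = {i: rng.normal(10, 1, 2 * n) for i in range(30)}
    cols[99] = np.concatenate([rng.normal(5, 0.2, n), rng.normal(15, 0.2, n)])
    dosage = pd.DataFrame(cols, index=range(2 * n))
    out = vst_table(dosage, labs)
    assert out.loc[99, "top"]
    assert out["top"].sum() == 1


# ---------------------------------------------------------------------------
# dip statistic


def dip_lp_oracle(x):
    """Brute-force dip via linear programming over unimodal cdfs evaluated
    at the (distinct) sample points, scanning the mode position."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    dx = np.diff(x)
    best = np.inf
    for split in range(n - 1):
        A, b = [], []

        def con(coefs, rhs):
            row = np.zeros(n + 1)
            for j, c in coefs:
                row[j] += c
            row[-1] = -1
            A.append(row)
            b.append(rhs)

        for i in range(n):
            con([(i, 1)], (i + 1) / n)
            con([(i, -1)], -(i + 1) / n)
            con([(i, 1)], i / n)
            con([(i, -1)], -i / n)
        con([(n - 1, -1)], -1.0)
        con([(0, 1)], 0.0)
        for i in range(n - 1):  # monotone
            row = np.zeros(n + 1)
            row[i], row[i + 1] = 1, -1
            A.append(row)
            b.append(0.0)
        for i in range(n - 2):  # slopes rise until the mode, then fall
            row = np.zeros(n + 1)
            s = 1.0 if i < split else -1.0
            row[i] += -s / dx[i]
            row[i + 1] += s / dx[i] + s / dx[i + 1]
            row[i + 2] += -s / dx[i + 1]
            A.append(row)
            b.append(0.0)
        c = np.zeros(n + 1)
        c[-1] = 1
        res = linprog(
            c, A_ub=np.array(A), b_ub=np.array(b), bounds=[(0, 1)] * n + [(0, 1)],
            method="highs",
        )
        if res.success and res.fun < best:
            best = res.fun
    return best


def test_dip_two_point_mixture_is_quarter():
    assert dip_statistic([0, 0, 1, 1]) == pytest.approx(0.25)
    assert dip_statistic([0] * 50 + [1] * 50) == pytest.approx(0.25)


def test_dip_bounds_and_degenerate():
    assert dip_statistic([3.0, 3.0, 3.0]) == 0.0
    rng = np.random.default_rng(0)
    for n in (10, 50, 200):
        d = dip_statistic(rng.normal(size=n))
        assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12


def test_dip_matches_lp_oracle():
    rng = np.random.default_rng(7)
    for trial in range(12):
        n = int(rng.integers(5, 18))
        if trial % 2:
            x = rng.normal(size=n)
        else:
            x = np.concatenate(
                [rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n - n // 2)]
            )
        x = np.unique(x)
        assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-8)


def test_dip_pvalue_separates_modality():
    rng = np.random.default_rng(1)
    bimodal = np.concatenate([rng.normal(0, 0.2, 60), rng.normal(5, 0.2, 60)])
    _, p_bi = dip_pvalue(bimodal, rng=np.random.default_rng(2))
    assert p_bi < 0.05
    _, p_uni = dip_pvalue(np.append(rng.normal(50, 5, 99), 90), rng=np.random.default_rng(2))
    assert p_uni > 0.5


# ---------------------------------------------------------------------------
# unstable loci


def _cohort(rng, n=400, loci=6):
    labs = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2), index=[f"s{i}" for i in range(n)])
    dosage = pd.DataFrame(
        rng.normal(50, 5, size=(n, loci)), index=labs.index, columns=range(loci)
    )
    return dosage, labs


def test_no_candidates_when_all_equal():
    dosage = pd.DataFrame(50.0, index=[f"s{i}" for i in range(30)], columns=range(3))
    labs = pd.Series(["a"] * 15 + ["b"] * 15, index=dosage.index)
    out = detect_unstable_loci(dosage, labs)
    assert out.empty


def test_planted_expansion_carrier_recovered():
    rng = np.random.default_rng(8)
    dosage, labs = _cohort(rng)
    dosage.loc["s3", 2] = 50 + 8 * 5  # 8 SD above the population mean
    out = detect_unstable_loci(dosage, labs)
    hits = out[~out.removed_by_blacklist]
    assert set(hits["locus"]) == {2}
    assert "s3" in set(hits["sample"])


def test_recurrent_outlier_sample_blacklists_its_loci():
    rng = np.random.default_rng(9)
    dosage, labs = _cohort(rng, loci=7)
    for l in range(5):
        dosage.loc["s7", l] = 50 + 9 * 5  # outlier at 5 loci (4 others each)
    # gate disabled: this test isolates the recurrent-outlier blacklist rule
    out = detect_unstable_loci(dosage, labs, dip_p_gate=0.0)
    flagged = out[out["sample"] == "s7"]
    assert len(flagged) == 5
    assert flagged["removed_by_blacklist"].all()


def test_low_dosage_individuals_discarded_before_stats():
    rng = np.random.default_rng(10)
    dosage, labs = _cohort(rng, n=40, loci=2)
    dosage.loc["s0", 0] = 2.0  # below the dosage-10 floor: excluded, not flagged
    out = detect_unstable_loci(dosage, labs)
    assert "s0" not in set(out["sample"])


# ---------------------------------------------------------------------------
# mi-kmer and bootstrap


def test_mi_kmer_perfect_column_and_tie():
    rng = np.random.default_rng(11)
    y = pd.Series(rng.uniform(100, 500, 60))
    X = pd.DataFrame(
        {
            "k2": y.values.copy(),
            "k1": y.values.copy(),  # duplicate perfect column
            "k3": rng.uniform(0, 1, 60),
        }
    )
    mi = find_mi_kmer(X, y)
    assert mi.kmer == "k1"  # deterministic: lowest k-mer id among ties
    assert mi.vex == pytest.approx(1.0)
    assert 0.1 <= mi.alpha <= 0.9


def test_mi_kmer_constant_length_untestable():
    X = pd.DataFrame({"k1": np.arange(10.0)})
    assert find_mi_kmer(X, pd.Series(np.ones(10))) is None


def test_bootstrap_trivial_median_difference():
    rng = np.random.default_rng(12)
    xa = np.full(30, 5.0) + rng.normal(0, 0.01, 30)
    xb = np.full(30, 3.0) + rng.normal(0, 0.01, 30)
    ya, yb = xa * 2, xb * 2
    r = bootstrap_motif_test(xa, ya, xb, yb, n_boot=200, rng=np.random.default_rng(0))
    assert r.kmc_d == pytest.approx(2.0, abs=0.05)
    assert r.p_kmc == pytest.approx(1 / 201)


def test_bootstrap_identical_populations_p_one():
    x = np.arange(20.0)
    y = x * 3 + 1
    r = bootstrap_motif_test(x, y, x, y, n_boot=100, rng=np.random.default_rng(0))
    assert r.kmc_d == 0.0 and r.r2_d == 0.0
    assert r.p_kmc == 1.0 and r.p_r2 == 1.0


# ---------------------------------------------------------------------------
# sample outliers


def test_homogeneous_cohort_keeps_everyone():
    rng = np.random.default_rng(13)
    rd = pd.DataFrame(rng.normal(1, 0.02, (30, 10)), index=[f"s{i}" for i in range(30)])
    dosage = pd.DataFrame(rng.normal(20, 1, (30, 8)), index=rd.index)
    kept = filter_sample_outliers(rd, dosage)
    assert kept == list(rd.index)


def test_depth_distorted_sample_removed_duplicate_kept():
    rng = np.random.default_rng(14)
    idx = [f"s{i}" for i in range(30)]
    rd = pd.DataFrame(rng.normal(1, 0.02, (30, 10)), index=idx)
    dosage = pd.DataFrame(rng.normal(20, 1, (30, 8)), index=idx)
    rd.loc["s5"] *= 10  # gross depth distortion
    dosage.loc["s29"] = dosage.loc["s4"]  # duplicate of a normal sample
    rd.loc["s29"] = rd.loc["s4"]
    kept = filter_sample_outliers(rd, dosage)
    assert "s5" not in kept
    assert "s29" in kept and "s4" in kept
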