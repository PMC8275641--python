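"""Interval filtering, liftover, boundary expansion, QC/merging."""

import numpy as np
import pandas as pd
import pytest

from rpggkit.annotation import (
    STATUS_AMBIGUOUS,
    STATUS_FAILED_EXPANSION,
    STATUS_OK,
    LocusCatalog,
    RawRepeatInterval,
    check_flank_invariant,
    expand_boundaries,
    filter_vntr_intervals,
    lift_loci,
    merge_and_qc,
    read_repeat_bed,
    read_trf_dat,
)
from rpggkit.simulate import SimConfig, gen_population


def iv(motif_len, total_len):
    return RawRepeatInterval("c", 0, total_len, "A" * motif_len)


@pytest.mark.parametrize(
    "motif_len,total_len,kept",
    [
        (7, 200, True),
        (6, 500, False),  # motif must exceed 6 bp
        (10, 10000, False),  # strict upper bound
        (10, 150, False),  # strict lower bound
        (10, 151, True),
        (30, 9999, True),
    ],
)
def test_vntr_filter_boundaries(motif_len, total_len, kept):
    out = filter_vntr_intervals([iv(motif_len, total_len)])
    assert (len(out) == 1) == kept


def test_filter_preserves_order_and_rejects_malformed():
    a, b = iv(8, 300), iv(9, 400)
    assert filter_vntr_intervals([a, b]) == [a, b]
    with pytest.raises(ValueError):
        filter_vntr_intervals([RawRepeatInterval("c", 10, 10, "AAAAAAA")])


def test_trf_dat_reader_converts_coordinates(tmp_path):
    dat = tmp_path / "x.dat"
    dat.write_text(
        "Tandem Repeats Finder Program\n\n"
        "Sequence: chr1\n\n"
        "Parameters: 2 7 7 80 10 50 500\n\n"
        "101 300 10 20.0 10 95 0 180 25 25 25 25 2.0 ACGTACGTAA ACGT\n"
    )
    recs = read_trf_dat(str(dat))
    assert len(recs) == 1
    r = recs[0]
    assert (r.contig, r.start, r.end, r.motif) == ("chr1", 100, 300, "ACGTACGTAA")
    assert r.total_len == 200 and r.motif_len == 10


def test_bed_reader(tmp_path):
    bed = tmp_path / "x.bed"
    bed.write_text("chr1\t100\t300\tACGTACGTAA\t10\t200\n")
    r = read_repeat_bed(str(bed))[0]
    assert (r.start, r.end, r.motif_len) == (100, 300, 10)


def test_lift_identity_shift_deletion_and_ambiguity():
    ref = [(0, 100, 200), (1, 500, 600)]
    corr = pd.DataFrame(
        [
            # identity on hap A
            {"locus": 0, "hap": "A", "contig": "A", "start": 100, "end": 200},
            {"locus": 1, "hap": "A", "contig": "A", "start": 500, "end": 600},
            # 100-base upstream insertion on hap B
            {"locus": 0, "hap": "B", "contig": "B", "start": 200, "end": 300},
            # locus 1 deleted on hap B -> absent
            # ambiguous mapping on hap C
            {"locus": 0, "hap": "C", "contig": "C", "start": 100, "end": 200},
            {"locus": 0, "hap": "C", "contig": "C", "start": 900, "end": 1000},
        ]
    )
    cat = lift_loci(ref, corr, haplotypes=["A", "B", "C"])
    a0 = cat.df[(cat.df.locus == 0) & (cat.df.hap == "A")].iloc[0]
    assert (a0.start, a0.end) == (100, 200)
    b0 = cat.df[(cat.df.locus == 0) & (cat.df.hap == "B")].iloc[0]
    assert (b0.start, b0.end) == (200, 300)
    assert cat.df[(cat.df.locus == 1) & (cat.df.hap == "B")].empty
    c0 = cat.df[(cat.df.locus == 0) & (cat.df.hap == "C")].iloc[0]
    assert c0.status == STATUS_AMBIGUOUS
    assert cat.support(1) == 1  # only hap A carries locus 1


def test_clean_flanks_leave_boundaries_unchanged(small_cohort):
    cfg, haps, truth, catalog = small_cohort
    before = catalog.df[["locus", "hap", "start", "end"]].copy()
    out = expand_boundaries(catalog, haps, k=cfg.k)
    pd.testing.assert_frame_equal(
        before, out.df[["locus", "hap", "start", "end"]], check_dtype=False
    )
    assert check_flank_invariant(out, haps, k=cfg.k)


def test_dirty_flank_expansion_restores_invariant():
    cfg = SimConfig(n_loci=4, n_genomes=2, copy_number_range=(5, 15), seed=21)
    haps, truth, catalog = gen_population(cfg, dirty_flank=True)
    assert not check_flank_invariant(catalog, haps, k=cfg.k)
    out = expand_boundaries(catalog, haps, k=cfg.k)
    assert check_flank_invariant(out, haps, k=cfg.k)
    # intervals only grow, and 3' boundaries moved past the planted copy
    merged = out.df.merge(
        catalog.df, on=["locus", "hap"], suffixes=("_new", "_old")
    )
    assert (merged.start_new <= merged.start_old).all()
    assert (merged.end_new >= merged.end_old).all()
    assert (merged.end_new > merged.end_old).any()


def test_saturated_contig_fails_expansion():
    motif = "ACGGTTCAGGAT"
    seq = motif * 400  # repeat everywhere: expansion cannot terminate
    df = pd.DataFrame(
        [
            {
                "locus": 0,
                "hap": "A",
                "contig": "A",
                "start": 2000,
                "end": 2400,
                "ref_start": 2000,
                "ref_end": 2400,
                "status": STATUS_OK,
            }
        ]
    )
    cat = LocusCatalog(df=df, haplotypes=["A"], flank_len=700)
    out = expand_boundaries(cat, {"A": seq}, k=21, max_expansion=1000)
    assert (out.df.status == STATUS_FAILED_EXPANSION).all()


def _catalog(rows, haplotypes, flank=700):
    df = pd.DataFrame(rows)
    df["ref_start"] = df.get("ref_start", df["start"])
    df["ref_end"] = df.get("ref_end", df["end"])
    if "status" not in df:
        df["status"] = STATUS_OK
    return LocusCatalog(df=df, haplotypes=haplotypes, flank_len=flank)


def test_support_below_90pct_dropped():
    haps = [f"h{i}" for i in range(10)]
    rows = [
        {"locus": 0, "hap": h, "contig": h, "start": 100, "end": 400} for h in haps[:8]
    ]
    cat = merge_and_qc(_catalog(rows, haps))
    assert 0 in cat.dropped
    assert cat.df.empty


def test_support_9_of_10_retained():
    haps = [f"h{i}" for i in range(10)]
    rows = [
        {"locus": 0, "hap": h, "contig": h, "start": 100, "end": 400} for h in haps[:9]
    ]
    cat = merge_and_qc(_catalog(rows, haps))
    assert 0 not in cat.dropped
    assert cat.support(0) == 9


def test_adjacent_loci_merge_to_hull_on_every_haplotype():
    haps = ["h0", "h1", "h2"]
    rows = []
    for h in haps:
        rows.append({"locus": 0, "hap": h, "contig": h, "start": 1000, "end": 1400})
        rows.append({"locus": 1, "hap": h, "contig": h, "start": 1900, "end": 2300})
    cat = merge_and_qc(_catalog(rows, haps))
    assert cat.loci() == [0]
    assert cat.merged_from == {0: [0, 1]}
    sub = cat.ok()
    assert (sub.start == 1000).all() and (sub.end == 2300).all()
    assert len(sub) == 3


def test_distant_loci_stay_separate():
    haps = ["h0", "h1"]
    rows = []
    for h in haps:
        rows.append({"locus": 0, "hap": h, "contig": h, "start": 1000, "end": 1400})
        rows.append({"locus": 1, "hap": h, "contig": h, "start": 2200, "end": 2600})
    cat = merge_and_qc(_catalog(rows, haps))
    assert cat.loci() == [0, 1]


def test_discordant_orthology_haplotype_dropped():
    haps = [f"h{i}" for i in range(10)]
    rows = []
    for i, h in enumerate(haps):
        rows.append(
            {
                "locus": 0,
                "hap": h,
                "contig": h,
                "start": 100,
                "end": 400,
                "ref_start": 100 if i else 5000,  # h0 maps 4.9 kb away
                "ref_end": 400 if i else 5300,
            }
        )
    cat = merge_and_qc(_catalog(rows, haps))
    assert cat.support(0) == 9
    assert "h0" not in set(cat.ok()["hap"])


def test_clean_synthetic_pipeline_recovers_truth_exactly(small_cohort):
    cfg, haps, truth, catalog = small_cohort
    out = merge_and_qc(expand_boundaries(catalog, haps, k=cfg.k))
    got = out.ok().sort_values(["locus", "hap"]).reset_index(drop=True)
    want = catalog.df.sort_values(["locus", "hap"]).reset_index(drop=True)
    assert (got[["start", "end"]].values == want[["start", "end"]].values).all()


def test_catalog_tsv_roundtrip(tmp_path, small_cohort):
    _, _, _, catalog = small_cohort
    p = tmp_path / "cat.tsv"
    catalog.to_tsv(str(p))
    back = LocusCatalog.from_tsv(str(p))
    pd.testing.assert_frame_equal(catalog.df, back.df, check_dtype=False)
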