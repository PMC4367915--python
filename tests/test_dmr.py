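"""Peak scanning and DMR calling against exact enumeration oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from medipdiff import (
    assign_to_genes,
    call_dmrs,
    count_in_regions,
    dmg_table_totals,
    methylated_gene_set,
    scan_peaks,
    region_tests,
    tile_and_count,
    union_regions,
)
from medipdiff.profiles import FragmentSet, WindowCounts

from conftest import make_fragments


def exact_fisher_two_sided(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the 2x2 table, exact rationals.

    Margins fixed; two-sided p sums the probabilities of all tables as or
    less probable than the observed one.
    """
    r1, r2 = a + b, c + d
    col1 = a + c
    n = r1 + r2
    denom = comb(n, col1)
    lo, hi = max(0, col1 - r2), min(col1, r1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, col1 - k), denom) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def make_windows(counts, width=1_000, sample="S"):
    n = len(counts)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "count": counts,
        }
    )
    total = int(np.sum(counts))
    df["rpkm"] = df["count"] / (width / 1000) / (max(total, 1) / 1e6)
    return WindowCounts(sample, width, df, total)


# --- peak scanning ----------------------------------------------------------


def test_uniform_coverage_yields_no_peaks():
    rng = np.random.default_rng(0)
    counts = rng.poisson(30, size=2_000)
    peaks = scan_peaks(make_windows(counts))
    assert len(peaks) <= 1  # essentially none at BH-adjusted 1e-4


def test_extreme_window_becomes_single_peak():
    counts = np.full(200, 10)
    counts[57] = 500  # 50x the mean
    peaks = scan_peaks(make_windows(counts))
    assert len(peaks) == 1
    assert peaks.iloc[0].start == 57_000 and peaks.iloc[0].end == 58_000
    assert peaks.iloc[0]["count"] == 500


def test_adjacent_enriched_windows_merge():
    counts = np.full(200, 10)
    counts[57] = 400
    counts[58] = 450
    merged = scan_peaks(make_windows(counts), merge_gap=1_000)
    assert len(merged) == 1
    assert merged.iloc[0]["count"] == 850
    split = scan_peaks(make_windows(counts), merge_gap=0)
    assert len(split) == 1  # windows abut: gap 0 still merges touching windows


def test_empty_library_gives_empty_peaks():
    peaks = scan_peaks(make_windows(np.zeros(100, dtype=int)))
    assert len(peaks) == 0


def test_union_regions_merges_overlaps():
    a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000]})
    b = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [500, 5_000], "end": [2_000, 6_000]})
    regions = union_regions(a, b)
    assert regions.to_records(index=False).tolist() == [
        ("chr1", 0, 2_000),
        ("chr1", 5_000, 6_000),
    ]


# --- differential calling ---------------------------------------------------


def test_fisher_p_matches_exact_enumeration_fixture():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000]})
    table = region_tests(regions, np.array([40]), np.array([10]), 100_000, 100_000)
    fold = table["fold"].iloc[0]
    assert fold == pytest.approx((40.5 / 100_000) / (10.5 / 100_000))
    p_oracle = exact_fisher_two_sided(40, 100_000 - 40, 10, 100_000 - 10)
    assert table["p"].iloc[0] == pytest.approx(p_oracle, abs=1e-12)


@pytest.mark.parametrize("total_s,total_f", [(200, 200), (500, 300)])
def test_fisher_p_matches_enumeration_grid(total_s, total_f):
    counts = [(0, 5), (3, 3), (10, 2), (25, 5), (7, 30)]
    regions = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(len(counts)) * 10, "end": np.arange(len(counts)) * 10 + 10}
    )
    cs = np.array([c[0] for c in counts])
    cf = np.array([c[1] for c in counts])
    table = region_tests(regions, cs, cf, total_s, total_f)
    for i, (a, c) in enumerate(counts):
        oracle = exact_fisher_two_sided(a, total_s - a, c, total_f - c)
        assert table["p"].iloc[i] == pytest.approx(oracle, abs=1e-12)


def test_equal_counts_never_called():
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000]})
    called = call_dmrs(regions, np.array([50]), np.array([50]), 10_000, 10_000)
    assert len(called) == 0


def test_label_swap_flips_directions_only():
    rng = np.random.default_rng(1)
    n = 50
    regions = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * 1_000, "end": (np.arange(n) + 1) * 1_000}
    )
    cs = rng.poisson(30, n)
    cf = rng.poisson(30, n)
    cf[:5] = cs[:5] * 5 + 10
    fw = region_tests(regions, cs, cf, 100_000, 100_000)
    bw = region_tests(regions, cf, cs, 100_000, 100_000)
    assert np.allclose(fw["p"], bw["p"], atol=1e-12)
    assert np.allclose(fw["q"], bw["q"], atol=1e-12)
    flipped = {"hyper": "hypo", "hypo": "hyper"}
    tested = fw["tested"] & (fw["fold"] != 1.0)
    assert (
        bw.loc[tested, "direction"] == fw.loc[tested, "direction"].map(flipped)
    ).all()


def test_zero_zero_regions_excluded():
    regions = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 1_000], "end": [1_000, 2_000]}
    )
    table = region_tests(regions, np.array([0, 20]), np.array([0, 2]), 1_000, 1_000)
    assert not table["tested"].iloc[0] and table["tested"].iloc[1]
    assert np.isnan(table["p"].iloc[0])


def test_bh_q_matches_step_up_rule():
    """BH step-up oracle computed literally from the definition."""
    rng = np.random.default_rng(5)
    n = 40
    regions = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * 1_000, "end": (np.arange(n) + 1) * 1_000}
    )
    cs = rng.poisson(25, n)
    cs[:4] += 80
    cf = rng.poisson(25, n)
    table = region_tests(regions, cs, cf, 50_000, 50_000)
    p = table["p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    q_sorted = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_oracle = np.empty(m)
    q_oracle[order] = np.minimum(q_sorted, 1.0)
    assert np.allclose(table["q"].to_numpy(), q_oracle, atol=1e-12)
    # q is monotone in p rank
    assert (np.diff(table["q"].to_numpy()[order]) >= -1e-12).all()
    # rejection set at q <= 0.05 equals the textbook step-up rule
    thresh = 0.05 * (np.arange(m) + 1) / m
    k = np.max(np.where(p[order] <= thresh)[0], initial=-1)
    step_up_reject = np.zeros(m, dtype=bool)
    if k >= 0:
        step_up_reject[order[: k + 1]] = True
    assert ((table["q"].to_numpy() <= 0.05) == step_up_reject).all()


# --- gene assignment --------------------------------------------------------


def test_single_intron_dmr_tabulated(experiment):
    ann = experiment.annotation
    gene = ann.genes[0]
    intron = gene.elements["intron"][0]
    dmrs = pd.DataFrame(
        {
            "chrom": [gene.chrom],
            "start": [intron[0]],
            "end": [intron[0] + 10],
            "direction": ["hyper"],
        }
    )
    annotated, dmg = assign_to_genes(dmrs, ann)
    per_element = dmg[~dmg["element"].isin(["column_sum", "distinct_total"])]
    assert per_element.set_index("element").loc["Intron", "hyper"] == 1
    assert per_element["hyper"].sum() == 1 and per_element["hypo"].sum() == 0


def test_dmr_spanning_two_elements_counts_both(experiment):
    ann = experiment.annotation
    gene = next(g for g in ann.genes if g.strand == "+")
    utr_start = gene.elements["5utr"][0][0]
    dmrs = pd.DataFrame(
        {
            "chrom": [gene.chrom],
            "start": [utr_start - 50],
            "end": [utr_start + 50],
            "direction": ["hypo"],
        }
    )
    _, dmg = assign_to_genes(dmrs, ann)
    idx = dmg.set_index("element")
    assert idx.loc["Upstream 2k", "hypo"] == 1
    assert idx.loc["5'UTR", "hypo"] == 1


def test_no_dmrs_gives_zero_table(experiment):
    empty = pd.DataFrame(columns=["chrom", "start", "end", "direction"])
    _, dmg = assign_to_genes(empty, experiment.annotation)
    assert (dmg[["hyper", "hypo"]].to_numpy() == 0).all()


def test_dmg_table_totals_sums_columns():
    table = pd.DataFrame(
        {"element": ["a", "b"], "hyper": [3, 4], "hypo": [1, 2]}
    )
    totals = dmg_table_totals(table)
    assert totals["hyper"] == 7 and totals["hypo"] == 3 and totals["total"] == 10


def test_methylated_gene_set_semantics(experiment):
    ann = experiment.annotation
    gene = ann.genes[1]
    up = gene.elements["upstream2k"][0]
    peaks = pd.DataFrame(
        {"chrom": [gene.chrom], "start": [up[0]], "end": [up[0] + 100]}
    )
    genes = methylated_gene_set(peaks, ann)
    assert gene.gene_id in genes
    assert methylated_gene_set(pd.DataFrame(columns=["chrom", "start", "end"]), ann) == set()
    # determinism on identical inputs
    assert methylated_gene_set(peaks, ann) == genes


def test_count_in_regions_uses_midpoints():
    fs = make_fragments([("chr1", 950, 1_250), ("chr1", 10, 20)])
    regions = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 1_000], "end": [1_000, 2_000]}
    )
    counts = count_in_regions(fs, regions)
    assert counts.tolist() == [1, 1]  # midpoint 1100 falls in the second region
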