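"""Coverage profiling: windows, RPKM, metagene, distributions, level tests."""

import math

import numpy as np
import pandas as pd
import pytest

from medipdiff import (
    ValidationError,
    chromosome_distribution,
    compare_levels,
    component_distribution,
    filter_unique,
    metagene,
    pooled_t_test,
    rpkm,
    tile_and_count,
    tile_windows,
    unique_mapping_rate,
)
from medipdiff.profiles import FragmentSet, WindowCounts, significance_stars

from conftest import make_fragments, uniform_1bp_fragments


# --- unique filtering -------------------------------------------------------


def test_filter_unique_keeps_flagged_fragments(rng):
    rows = [("chr1", i * 10, i * 10 + 5, i >= 40) for i in range(100)]
    fs = make_fragments(rows)
    kept = filter_unique(fs)
    assert kept.total_reads == 60
    assert kept.fragments["unique"].all()

    all_unique = make_fragments([("chr1", 0, 10), ("chr1", 5, 15)])
    assert filter_unique(all_unique).total_reads == 2

    none_unique = make_fragments([("chr1", 0, 10, False)])
    with pytest.warns(UserWarning, match="no uniquely mapped"):
        assert filter_unique(none_unique).total_reads == 0


def test_unique_mapping_rate_arithmetic():
    assert unique_mapping_rate(60, 100) == 60.0
    assert unique_mapping_rate(1, 3) == 33.33
    with pytest.raises(ValidationError):
        unique_mapping_rate(5, 0)


# --- windows ----------------------------------------------------------------


def test_tiling_counts_and_midpoint_rule():
    sizes = {"chr1": 10_000}
    assert len(tile_windows(sizes, 1_000)) == 10
    # width larger than the chromosome: one clipped window
    clipped = tile_windows({"chr1": 700}, 1_000)
    assert clipped.to_records(index=False).tolist() == [("chr1", 0, 700)]

    # fragment [950, 1250) has midpoint 1100 -> window [1000, 2000)
    fs = make_fragments([("chr1", 950, 1250)])
    wc = tile_and_count(fs, sizes, 1_000)
    assert wc.windows.loc[wc.windows["start"] == 1_000, "count"].iloc[0] == 1
    assert wc.windows["count"].sum() == 1


def test_window_count_conservation(experiment, small_config):
    fs = filter_unique(experiment.fragments["S"])
    wc = tile_and_count(fs, experiment.annotation.chrom_sizes, 1_000)
    assert wc.windows["count"].sum() == fs.total_reads


@pytest.mark.parametrize(
    "count,length,total,expected",
    [(25, 1_000, 5_000_000, 5.0), (0, 1_000, 5_000_000, 0.0), (10, 1_000, 1_000_000, 10.0)],
)
def test_rpkm_direct_arithmetic(count, length, total, expected):
    assert rpkm(count, length, total) == pytest.approx(expected)


def test_rpkm_linearity_and_relabelling_invariance(rng):
    counts = rng.integers(0, 100, size=50)
    lengths = np.full(50, 1_000)
    base = rpkm(counts, lengths, 2_000_000)
    assert rpkm(3 * counts, lengths, 2_000_000) == pytest.approx(3 * base)
    perm = rng.permutation(50)
    assert rpkm(counts[perm], lengths[perm], 2_000_000) == pytest.approx(base[perm])


# --- metagene ---------------------------------------------------------------


def test_metagene_uniform_coverage_is_flat():
    fs = uniform_1bp_fragments("chr1", 10_000)
    features = pd.DataFrame(
        {"chrom": ["chr1"], "start": [4_000], "end": [8_000], "strand": ["+"]}
    )
    prof = metagene(fs, features, flank=2_000)
    vals = prof.values
    assert len(vals) == 80
    assert (vals >= 0).all()
    assert (vals.max() - vals.min()) <= 1e-6 * vals.mean()


def test_metagene_flank_only_depth():
    # depth only in the 2-kb flanks, none in the body
    rows = [("chr1", i, i + 1) for i in range(2_000, 4_000)]
    rows += [("chr1", i, i + 1) for i in range(8_000, 10_000)]
    fs = make_fragments(rows)
    features = pd.DataFrame(
        {"chrom": ["chr1"], "start": [4_000], "end": [8_000], "strand": ["+"]}
    )
    prof = metagene(fs, features)
    assert prof.body.max() == 0
    assert prof.upstream.min() > 0 and prof.downstream.min() > 0


def test_metagene_strand_reversal_reverses_profile():
    # asymmetric depth concentrated 5' of the body start
    rows = [("chr1", i, i + 1) for i in range(3_500, 4_500)]
    fs = make_fragments(rows)
    plus = pd.DataFrame(
        {"chrom": ["chr1"], "start": [4_000], "end": [8_000], "strand": ["+"]}
    )
    minus = plus.assign(strand="-")
    p_plus = metagene(fs, plus)
    p_minus = metagene(fs, minus)
    assert np.allclose(p_plus.values, p_minus.values[::-1])


def test_metagene_short_feature_skipped_with_warning():
    fs = uniform_1bp_fragments("chr1", 1_000)
    features = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [100, 500],
            "end": [110, 900],  # first is shorter than 40 bins
            "strand": ["+", "+"],
        }
    )
    with pytest.warns(UserWarning, match="skipped 1"):
        prof = metagene(fs, features)
    assert prof.n_features == 1


# --- component / chromosome distributions -----------------------------------


def test_component_distribution_on_known_gene(experiment):
    ann = experiment.annotation
    gene = ann.genes[0]
    cds_start, cds_end = gene.elements["cds"][0]
    peaks = pd.DataFrame(
        {"chrom": [gene.chrom], "start": [cds_start], "end": [cds_start + 10]}
    )
    dist = component_distribution(peaks, ann)
    counts = dict(zip(dist["element"], dist["n_peaks"]))
    assert counts["cds"] == 1
    assert counts["3utr"] == 0 and counts["5utr"] == 0

    # a peak spanning the upstream2k/5'UTR boundary increments both
    utr_start = gene.elements["5utr"][0][0]
    up_iv = gene.elements["upstream2k"][0]
    span = pd.DataFrame(
        {
            "chrom": [gene.chrom],
            "start": [min(utr_start, up_iv[1]) - 5],
            "end": [min(utr_start, up_iv[1]) + 5],
        }
    )
    dist2 = component_distribution(span, ann)
    counts2 = dict(zip(dist2["element"], dist2["n_peaks"]))
    assert counts2["upstream2k"] == 1 and counts2["5utr"] == 1

    none = component_distribution(pd.DataFrame(columns=["chrom", "start", "end"]), ann)
    assert none["n_peaks"].sum() == 0


def test_chromosome_distribution_counts(experiment):
    fs = experiment.fragments["S"]
    dist = chromosome_distribution(fs, experiment.annotation.chrom_sizes)
    assert dist["count"].sum() == fs.total_reads
    empty = chromosome_distribution(
        FragmentSet("x", pd.DataFrame(columns=["chrom", "start", "end", "unique"])),
        experiment.annotation.chrom_sizes,
    )
    assert len(empty) == 0


def test_two_equal_chromosomes_get_equal_density():
    rng = np.random.default_rng(8)
    n = 20_000
    chroms = np.where(rng.random(n) < 0.5, "chr1", "chr2")
    starts = rng.integers(0, 99_000, size=n)
    fs = FragmentSet(
        "u", pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + 200})
    )
    dist = chromosome_distribution(fs, {"chr1": 100_000, "chr2": 100_000})
    p = dist["count"].iloc[0] / n
    se = math.sqrt(0.25 / n)
    assert abs(p - 0.5) < 4 * se


# --- level comparisons ------------------------------------------------------


def textbook_pooled_t(a, b):
    """Hand formula: pooled-variance two-sample t and its two-sided p."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    sa2 = sum((x - sum(a) / na) ** 2 for x in a) / (na - 1)
    sb2 = sum((x - sum(b) / nb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    t = (sum(a) / na - sum(b) / nb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def test_pooled_t_matches_textbook_fixture():
    a = [4.1, 5.2, 6.3, 5.8, 4.9]
    b = [7.0, 8.1, 6.9, 7.7, 8.4]
    t, p = pooled_t_test(np.array(a), np.array(b))
    t_ref, p_ref = textbook_pooled_t(a, b)
    assert t == pytest.approx(t_ref, rel=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-12)


def test_pooled_t_degenerate_cases():
    same = np.array([2.0, 2.0, 2.0])
    assert pooled_t_test(same, same) == (0.0, 1.0)
    t, p = pooled_t_test(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
    assert p == 0.0 and t < 0

    # identical vectors with variance: t = 0, p = 1
    v = np.array([1.0, 2.0, 3.0])
    t, p = pooled_t_test(v, v)
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_location_shift_detected():
    rng = np.random.default_rng(10)
    a = rng.normal(0, 1, size=500)
    b = a + 1.0
    _, p = pooled_t_test(a, b)
    assert p < 0.001
    assert significance_stars(p) == "***"


def test_compare_levels_groups(experiment):
    ann = experiment.annotation
    fs_s = filter_unique(experiment.fragments["S"])
    fs_f = filter_unique(experiment.fragments["F"])
    wc_s = tile_and_count(fs_s, ann.chrom_sizes, 1_000)
    wc_f = tile_and_count(fs_f, ann.chrom_sizes, 1_000)
    result = compare_levels(wc_s, wc_f, ann)
    assert "all" in set(result["group"])
    assert set(result["group"]) <= {"all", *[c for c in ann.genes[0].elements]}
    # identical input gives t = 0, p = 1 everywhere
    null = compare_levels(wc_s, wc_s, ann)
    assert (null["t"] == 0).all() and (null["p"] == 1).all()
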