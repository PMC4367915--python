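"""Methylation-peak scanning and differential methylated region (DMR) calling.

Peaks are tiled windows whose unique-fragment count exceeds a Poisson
background (rate = genome-wide mean count per window) at a Benjamini-Hochberg
adjusted p below ``alpha``, merged across gaps. Differential calling tests
each candidate region's 2x2 table (region count vs library remainder,
condition S vs F) with Fisher's exact test, adjusts with BH, computes a
pseudocount-stabilised normalized fold change

    fold = ((count_S + 0.5) / total_S) / ((count_F + 0.5) / total_F)

and keeps a region iff p < p_max, q < q_max and fold >= fc_min or
<= 1/fc_min. Direction is hyper-in-S when fold > 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import ELEMENT_CLASSES, ELEMENT_LABELS, GenomeAnnotation
from .exceptions import ValidationError
from .profiles import WindowCounts, _element_trees, _midpoints_by_chrom, FragmentSet


def scan_peaks(
    windows: WindowCounts, merge_gap: int = 0, alpha: float = 1e-4
) -> pd.DataFrame:
    """Call enriched windows against a Poisson background and merge them.

    Returns a frame (chrom, start, end, count, q_min) where ``count`` is the
    summed fragment count of the merged windows and ``q_min`` the smallest
    BH-adjusted p among them. An empty library yields an empty frame.
    """
    w = windows.windows
    counts = w["count"].to_numpy()
    if counts.sum() == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "count", "q_min"])
    lam = counts.mean()
    # P(X >= c) under Poisson(lam)
    pvals = stats.poisson.sf(counts - 1, lam)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    sig = qvals < alpha

    rows = []
    chroms = w["chrom"].to_numpy()
    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    current = None
    for i in np.where(sig)[0]:
        if (
            current is not None
            and chroms[i] == current["chrom"]
            and starts[i] - current["end"] <= merge_gap
        ):
            current["end"] = int(ends[i])
            current["count"] += int(counts[i])
            current["q_min"] = min(current["q_min"], float(qvals[i]))
        else:
            if current is not None:
                rows.append(current)
            current = {
                "chrom": chroms[i],
                "start": int(starts[i]),
                "end": int(ends[i]),
                "count": int(counts[i]),
                "q_min": float(qvals[i]),
            }
    if current is not None:
        rows.append(current)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "q_min"])


def union_regions(*peak_frames: pd.DataFrame) -> pd.DataFrame:
    """Union of peak intervals from several samples (merged where they touch)."""
    frames = [p[["chrom", "start", "end"]] for p in peak_frames if len(p)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    allp = pd.concat(frames).sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = row.start, row.end
            elif row.start <= cur_e:
                cur_e = max(cur_e, row.end)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = row.start, row.end
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def count_in_regions(fragment_set: FragmentSet, regions: pd.DataFrame) -> np.ndarray:
    """Midpoint-rule fragment counts per region (regions may be irregular)."""
    mids = _midpoints_by_chrom(fragment_set.fragments)
    out = np.zeros(len(regions), dtype=np.int64)
    for i, row in enumerate(regions.itertuples(index=False)):
        chrom_mids = mids.get(row.chrom)
        if chrom_mids is None:
            continue
        lo = np.searchsorted(chrom_mids, row.start)
        hi = np.searchsorted(chrom_mids, row.end)
        out[i] = hi - lo
    return out


def region_tests(
    regions: pd.DataFrame,
    counts_s: np.ndarray,
    counts_f: np.ndarray,
    total_s: int,
    total_f: int,
) -> pd.DataFrame:
    """Fisher exact test + BH over all candidate regions.

    Regions with zero counts in both samples are excluded from testing and
    flagged via the ``tested`` column. Returns all regions with count_s,
    count_f, fold, p, q, direction, tested.
    """
    if total_s <= 0 or total_f <= 0:
        raise ValidationError("library totals must be positive")
    counts_s = np.asarray(counts_s, dtype=np.int64)
    counts_f = np.asarray(counts_f, dtype=np.int64)
    if not (len(regions) == len(counts_s) == len(counts_f)):
        raise ValidationError("regions and count vectors must align")

    out = regions.reset_index(drop=True).copy()
    out["count_s"] = counts_s
    out["count_f"] = counts_f
    fold = ((counts_s + 0.5) / total_s) / ((counts_f + 0.5) / total_f)
    out["fold"] = fold
    tested = (counts_s + counts_f) > 0
    out["tested"] = tested

    pvals = np.full(len(out), np.nan)
    for i in np.where(tested)[0]:
        table = [
            [int(counts_s[i]), int(total_s - counts_s[i])],
            [int(counts_f[i]), int(total_f - counts_f[i])],
        ]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    out["p"] = pvals
    qvals = np.full(len(out), np.nan)
    if tested.any():
        _, q, _, _ = multipletests(pvals[tested], method="fdr_bh")
        qvals[tested] = q
    out["q"] = qvals
    out["direction"] = np.where(fold > 1, "hyper", "hypo")
    return out


def call_dmrs(
    regions: pd.DataFrame,
    counts_s: np.ndarray,
    counts_f: np.ndarray,
    total_s: int,
    total_f: int,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Significant DMRs at the fold-change + p + FDR thresholds.

    The test universe is the supplied region set (union of peaks from both
    samples, so hyper and hypo calls are symmetric). Returns the subset of
    :func:`region_tests` output passing p < p_max, q < q_max and
    fold >= fc_min or <= 1/fc_min.
    """
    if fc_min < 1:
        raise ValidationError("fc_min must be >= 1")
    table = region_tests(regions, counts_s, counts_f, total_s, total_f)
    keep = (
        table["tested"]
        & (table["p"] < p_max)
        & (table["q"] < q_max)
        & ((table["fold"] >= fc_min) | (table["fold"] <= 1 / fc_min))
    )
    return table[keep].reset_index(drop=True)


def assign_to_genes(
    dmrs: pd.DataFrame, annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate DMRs with overlapping (gene, element) pairs and tabulate.

    Returns (annotated, dmg_table). ``annotated`` has one row per
    (DMR, gene, element) overlap. ``dmg_table`` counts distinct genes per
    element class and direction, plus two clearly distinct summary rows:
    ``column_sum`` (sum of the per-element rows; a gene with DMRs in several
    elements is counted once per element) and ``distinct_total`` (distinct
    genes with at least one DMR of that direction anywhere).
    """
    trees = _element_trees(annotation)
    rows = []
    for i, row in enumerate(dmrs.itertuples(index=False)):
        for element in ELEMENT_CLASSES:
            tree = trees[element].get(row.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(row.start, row.end):
                rows.append(
                    {
                        "dmr_index": i,
                        "chrom": row.chrom,
                        "start": row.start,
                        "end": row.end,
                        "direction": getattr(row, "direction", "hyper"),
                        "gene_id": hit.data,
                        "element": element,
                    }
                )
    annotated = pd.DataFrame(
        rows,
        columns=["dmr_index", "chrom", "start", "end", "direction", "gene_id", "element"],
    )

    table_rows = []
    for element in ELEMENT_CLASSES:
        sub = annotated[annotated["element"] == element]
        table_rows.append(
            {
                "element": ELEMENT_LABELS[element],
                "hyper": sub.loc[sub["direction"] == "hyper", "gene_id"].nunique(),
                "hypo": sub.loc[sub["direction"] == "hypo", "gene_id"].nunique(),
            }
        )
    dmg = pd.DataFrame(table_rows, columns=["element", "hyper", "hypo"])
    column_sum = {"element": "column_sum", "hyper": int(dmg["hyper"].sum()),
                  "hypo": int(dmg["hypo"].sum())}
    distinct = {
        "element": "distinct_total",
        "hyper": annotated.loc[annotated["direction"] == "hyper", "gene_id"].nunique(),
        "hypo": annotated.loc[annotated["direction"] == "hypo", "gene_id"].nunique(),
    }
    dmg = pd.concat([dmg, pd.DataFrame([column_sum, distinct])], ignore_index=True)
    return annotated, dmg


def methylated_gene_set(
    peaks: pd.DataFrame, annotation: GenomeAnnotation
) -> set[str]:
    """Genes overlapping any peak in upstream 2k, gene body, or downstream 2k."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gene in annotation.genes:
        spans = [gene.body]
        spans += gene.elements.get("upstream2k", [])
        spans += gene.elements.get("downstream2k", [])
        for s, e in spans:
            if e > s:
                trees.setdefault(gene.chrom, IntervalTree()).addi(s, e, gene.gene_id)
    genes: set[str] = set()
    for row in peaks.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(row.start, row.end):
            genes.add(hit.data)
    return genes


def dmg_table_totals(dmg_counts: pd.DataFrame) -> pd.Series:
    """Column sums of a per-element DMG table (hyper, hypo, combined).

    Input: frame with per-element rows and numeric ``hyper``/``hypo``
    columns (summary rows, if present, must be excluded by the caller).
    """
    hyper = int(dmg_counts["hyper"].sum())
    hypo = int(dmg_counts["hypo"].sum())
    return pd.Series({"hyper": hyper, "hypo": hypo, "total": hyper + hypo})
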