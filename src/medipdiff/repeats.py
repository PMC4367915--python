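"""Repeat-class methylation summaries on tiled genome windows.

Fragments are assigned to fixed windows (default 10 kb) by midpoint; each
window's count is attributed to the repeat classes overlapping the window,
proportionally to each class's overlap length within it. Percentages are of
the repeat-assigned total. A direct per-element mode (fragment midpoint
inside a repeat element) is provided as a labelled alternative.
"""

from __future__ import annotations

import warnings

import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ValidationError
from .profiles import FragmentSet, tile_and_count

KNOWN_REPEAT_CLASSES = (
    "LTR/Copia",
    "DNA/En-Spm",
    "LTR/Gypsy",
    "LTR",
    "LINE/L1",
    "SINE",
)


def _repeat_trees(repeats: pd.DataFrame, vocabulary) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    unknown = set()
    for row in repeats.itertuples(index=False):
        label = row.name if row.name in vocabulary else "other"
        if label == "other" and row.name not in vocabulary:
            unknown.add(row.name)
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, label)
    if unknown:
        warnings.warn(
            f"unknown repeat classes retained under 'other': {sorted(unknown)}",
            stacklevel=3,
        )
    return trees


def repeat_summary(
    fragment_set: FragmentSet,
    repeats: pd.DataFrame | None,
    chrom_sizes: dict[str, int],
    width: int = 10_000,
    mode: str = "window",
    vocabulary=KNOWN_REPEAT_CLASSES,
) -> pd.DataFrame:
    """Per-repeat-class read allocation and percentage for one sample.

    ``mode="window"``: window counts split among overlapping classes by
    overlap length (the tiled-window route). ``mode="element"``: a fragment
    counts toward a class iff its midpoint lies inside one of that class's
    elements. Returns (repeat_class, reads, percent) with percentages of the
    repeat-assigned total.
    """
    if repeats is None or len(repeats) == 0:
        warnings.warn("no repeat annotation supplied; empty summary", stacklevel=2)
        return pd.DataFrame(columns=["repeat_class", "reads", "percent"])
    if mode not in ("window", "element"):
        raise ValidationError(f"unknown repeat summary mode {mode!r}")

    trees = _repeat_trees(repeats, vocabulary)
    classes = list(vocabulary) + ["other"]
    reads = {c: 0.0 for c in classes}

    if mode == "window":
        wc = tile_and_count(fragment_set, chrom_sizes, width)
        for row in wc.windows.itertuples(index=False):
            if row.count == 0:
                continue
            tree = trees.get(row.chrom)
            if tree is None:
                continue
            overlaps: dict[str, int] = {}
            for hit in tree.overlap(row.start, row.end):
                length = min(hit.end, row.end) - max(hit.begin, row.start)
                overlaps[hit.data] = overlaps.get(hit.data, 0) + length
            total = sum(overlaps.values())
            if total == 0:
                continue
            for label, length in overlaps.items():
                reads[label] += row.count * length / total
    else:
        frags = fragment_set.fragments
        mids = (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2
        for chrom, mid in zip(frags["chrom"].to_numpy(), mids):
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = tree.at(int(mid))
            for hit in hits:
                reads[hit.data] += 1

    total_assigned = sum(reads.values())
    out = pd.DataFrame(
        {
            "repeat_class": classes,
            "reads": [reads[c] for c in classes],
            "percent": [
                100.0 * reads[c] / total_assigned if total_assigned else 0.0
                for c in classes
            ],
        }
    )
    if out.loc[out["repeat_class"] == "other", "reads"].iloc[0] == 0:
        out = out[out["repeat_class"] != "other"].reset_index(drop=True)
    return out
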