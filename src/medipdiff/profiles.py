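"""Coverage profiling from mapped MeDIP fragments.

Counting is fragment-level (the pulldown enriches fragments, not reads; the
two ends of one pair are one observation), a fragment is assigned to exactly
the tiled window containing its midpoint, and RPKM uses the unique-fragment
library size as denominator: count / (window_kb) / (library / 1e6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import ELEMENT_CLASSES, GenomeAnnotation
from .exceptions import ValidationError
from .io import read_bed


@dataclass
class FragmentSet:
    """Mapped fragment intervals of one sample with library totals."""

    sample: str
    fragments: pd.DataFrame  # chrom, start, end, unique(bool)

    def __post_init__(self):
        required = {"chrom", "start", "end"}
        if not required.issubset(self.fragments.columns):
            raise ValidationError(f"fragment frame needs columns {sorted(required)}")
        if "unique" not in self.fragments.columns:
            self.fragments = self.fragments.assign(unique=True)

    @property
    def total_reads(self) -> int:
        return len(self.fragments)

    @property
    def unique_reads(self) -> int:
        return int(self.fragments["unique"].sum())

    @classmethod
    def from_bed(cls, path, sample: str) -> "FragmentSet":
        """Load fragments from BED6; score 1 marks uniquely mapped, 0 multi."""
        bed = read_bed(path)
        bed["unique"] = bed["score"].astype(int) > 0
        return cls(sample, bed[["chrom", "start", "end", "unique"]])


@dataclass
class WindowCounts:
    """Fixed-width tiled windows with per-window fragment counts and RPKM."""

    sample: str
    width: int
    windows: pd.DataFrame  # chrom, start, end, count, rpkm
    library_size: int

    @property
    def counts(self) -> np.ndarray:
        return self.windows["count"].to_numpy()


@dataclass
class MetageneProfile:
    """Binned normalized-depth curve: flank bins, body bins, flank bins."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_features: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def unique_mapping_rate(unique_reads: int, total_reads: int) -> float:
    """Percentage of uniquely mapped reads, rounded to two decimals."""
    if total_reads <= 0:
        raise ValidationError("total_reads must be positive")
    if unique_reads > total_reads:
        raise ValidationError("unique_reads cannot exceed total_reads")
    return round(100.0 * unique_reads / total_reads, 2)


def filter_unique(fragment_set: FragmentSet) -> FragmentSet:
    """Keep only uniquely mapped fragments (the peak-scanning input)."""
    kept = fragment_set.fragments[fragment_set.fragments["unique"]].reset_index(drop=True)
    if len(kept) == 0:
        warnings.warn(
            f"sample {fragment_set.sample}: no uniquely mapped fragments remain",
            stacklevel=2,
        )
    return FragmentSet(fragment_set.sample, kept)


def tile_windows(chrom_sizes: dict[str, int], width: int) -> pd.DataFrame:
    """Non-overlapping windows of ``width`` bp tiling each chromosome.

    The last window of a chromosome is clipped; a width larger than the
    chromosome yields a single clipped window.
    """
    if width <= 0:
        raise ValidationError("window width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, width)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + width, size))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def rpkm(count, window_length, library_size):
    """Reads per kb of window per million mapped reads (vectorized)."""
    count = np.asarray(count, dtype=float)
    window_length = np.asarray(window_length, dtype=float)
    if library_size <= 0:
        raise ValidationError("library size must be positive for RPKM")
    return count / (window_length / 1000.0) / (library_size / 1e6)


def tile_and_count(
    fragment_set: FragmentSet,
    chrom_sizes: dict[str, int],
    width: int,
    library_size: int | None = None,
) -> WindowCounts:
    """Count fragments into tiled windows by the midpoint rule and add RPKM."""
    windows = tile_windows(chrom_sizes, width)
    frags = fragment_set.fragments
    if library_size is None:
        library_size = len(frags)
    counts = np.zeros(len(windows), dtype=np.int64)
    offsets = {}
    offset = 0
    n_windows_by_chrom = {}
    for chrom, size in chrom_sizes.items():
        n_w = int(np.ceil(size / width)) if size > 0 else 0
        offsets[chrom] = offset
        n_windows_by_chrom[chrom] = n_w
        offset += n_w
    for chrom, grp in frags.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise ValidationError(f"fragments on unknown chromosome {chrom!r}")
        mids = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(np.int64)
        idx = np.minimum(mids // width, n_windows_by_chrom[chrom] - 1)
        np.add.at(counts, offsets[chrom] + idx, 1)
    windows["count"] = counts
    lengths = windows["end"] - windows["start"]
    windows["rpkm"] = (
        rpkm(counts, lengths, library_size) if library_size > 0 else np.zeros(len(windows))
    )
    return WindowCounts(fragment_set.sample, width, windows, library_size)


def _midpoints_by_chrom(fragments: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in fragments.groupby("chrom", sort=False):
        mids = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
        out[chrom] = np.sort(mids)
    return out


def metagene(
    fragment_set: FragmentSet,
    features: pd.DataFrame,
    library_size: int | None = None,
    flank: int = 2000,
    flank_bins: int = 20,
    body_bins: int = 40,
) -> MetageneProfile:
    """Average normalized depth around features in fixed bin counts.

    Flanks are split into ``flank_bins`` equal bins of ``flank/flank_bins``
    bp; each feature body into ``body_bins`` equal parts. Depth per bin is
    the midpoint-assigned fragment count divided by bin length (bp) and by
    library size in millions; minus-strand features are reversed so bin 1 is
    always 5'-most. The profile is the mean over features; features shorter
    than ``body_bins`` bp are skipped with a warning.
    """
    if len(features) == 0:
        raise ValidationError("metagene requires at least one feature")
    if library_size is None:
        library_size = len(fragment_set.fragments)
    lib_m = max(library_size, 1) / 1e6
    mids = _midpoints_by_chrom(fragment_set.fragments)
    flank_bin_len = flank / flank_bins

    up_acc = np.zeros(flank_bins)
    body_acc = np.zeros(body_bins)
    down_acc = np.zeros(flank_bins)
    n_used = 0
    n_skipped = 0

    if "strand" not in features.columns:
        features = features.assign(strand="+")

    for row in features.itertuples(index=False):
        body_len = row.end - row.start
        if body_len < body_bins:
            n_skipped += 1
            continue
        chrom_mids = mids.get(row.chrom, np.empty(0, dtype=np.int64))

        def _bin_counts(lo: int, hi: int, n_bins: int) -> np.ndarray:
            sel = chrom_mids[
                np.searchsorted(chrom_mids, lo) : np.searchsorted(chrom_mids, hi)
            ]
            idx = ((sel - lo) * n_bins // (hi - lo)).astype(np.int64)
            counts = np.zeros(n_bins)
            np.add.at(counts, np.minimum(idx, n_bins - 1), 1)
            return counts

        up = _bin_counts(row.start - flank, row.start, flank_bins) / flank_bin_len
        body = (
            _bin_counts(row.start, row.end, body_bins) * body_bins / body_len
        )
        down = _bin_counts(row.end, row.end + flank, flank_bins) / flank_bin_len
        if row.strand == "-":
            up, down = down[::-1], up[::-1]
            body = body[::-1]
        up_acc += up
        body_acc += body
        down_acc += down
        n_used += 1

    if n_skipped:
        warnings.warn(
            f"metagene: skipped {n_skipped} features shorter than {body_bins} bp",
            stacklevel=2,
        )
    if n_used == 0:
        raise ValidationError("metagene: no feature long enough to profile")
    scale = n_used * lib_m
    return MetageneProfile(up_acc / scale, body_acc / scale, down_acc / scale, n_used)


def _element_trees(annotation: GenomeAnnotation) -> dict[str, dict[str, IntervalTree]]:
    """Per element class, per chromosome interval trees (payload = gene id)."""
    trees: dict[str, dict[str, IntervalTree]] = {c: {} for c in ELEMENT_CLASSES}
    for gene in annotation.genes:
        for element, ivs in gene.elements.items():
            for s, e in ivs:
                if e > s:
                    trees[element].setdefault(gene.chrom, IntervalTree()).addi(
                        s, e, gene.gene_id
                    )
    return trees


def component_distribution(
    peaks: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Attribute each peak to every gene element class it overlaps.

    A peak spanning e.g. upstream2k and 5'UTR increments both classes, so the
    per-class counts may exceed the number of peaks. Fractions are relative
    to the peak count.
    """
    trees = _element_trees(annotation)
    counts = {c: 0 for c in ELEMENT_CLASSES}
    for row in peaks.itertuples(index=False):
        for element in ELEMENT_CLASSES:
            tree = trees[element].get(row.chrom)
            if tree is not None and tree.overlap(row.start, row.end):
                counts[element] += 1
    n_peaks = len(peaks)
    return pd.DataFrame(
        {
            "element": list(ELEMENT_CLASSES),
            "n_peaks": [counts[c] for c in ELEMENT_CLASSES],
            "fraction": [
                counts[c] / n_peaks if n_peaks else 0.0 for c in ELEMENT_CLASSES
            ],
        }
    )


def chromosome_distribution(
    fragment_set: FragmentSet, chrom_sizes: dict[str, int]
) -> pd.DataFrame:
    """Per-chromosome fragment counts and per-bp densities."""
    frags = fragment_set.fragments
    if len(frags) == 0:
        return pd.DataFrame(columns=["chrom", "count", "density"])
    counts = frags.groupby("chrom", sort=False).size()
    rows = []
    for chrom, size in chrom_sizes.items():
        c = int(counts.get(chrom, 0))
        rows.append((chrom, c, c / size if size else 0.0))
    return pd.DataFrame(rows, columns=["chrom", "count", "density"])


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Student's t with pooled variance.

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    give (inf-signed t, 0) rather than a division error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t test needs >= 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.sign(np.mean(a) - np.mean(b)) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def compare_levels(
    windows_a: WindowCounts,
    windows_b: WindowCounts,
    annotation: GenomeAnnotation | None = None,
) -> pd.DataFrame:
    """Student's t (pooled variance) on per-window RPKM between two samples.

    Rows: "all" (every window) plus, when an annotation is supplied, one row
    per gene element class over the windows overlapping that class.
    Windows must come from identical tilings.
    """
    wa, wb = windows_a.windows, windows_b.windows
    if len(wa) != len(wb) or windows_a.width != windows_b.width:
        raise ValidationError("compare_levels requires identical window tilings")

    groups: dict[str, np.ndarray] = {"all": np.ones(len(wa), dtype=bool)}
    if annotation is not None:
        trees = _element_trees(annotation)
        for element in ELEMENT_CLASSES:
            mask = np.zeros(len(wa), dtype=bool)
            for i, row in enumerate(wa.itertuples(index=False)):
                tree = trees[element].get(row.chrom)
                if tree is not None and tree.overlap(row.start, row.end):
                    mask[i] = True
            groups[element] = mask

    rows = []
    for name, mask in groups.items():
        if mask.sum() < 2:
            continue
        a = wa.loc[mask, "rpkm"].to_numpy()
        b = wb.loc[mask, "rpkm"].to_numpy()
        t, p = pooled_t_test(a, b)
        rows.append(
            {
                "group": name,
                "n_windows": int(mask.sum()),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": t,
                "p": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
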