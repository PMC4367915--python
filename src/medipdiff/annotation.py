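"""Genome annotation model: gene element classes, CpG islands, CpG O/E.

Each gene is decomposed into six element classes — upstream 2 kb, 5'UTR, CDS,
intron, 3'UTR, downstream 2 kb — with the flanks strand-aware (upstream is
always the 5' side) and clipped at chromosome edges. "Gene body" means the
transcript span (5'UTR start to 3'UTR end); CDS and intron partition the body
between the UTRs.

The CpG observed/expected ratio follows the Gardiner-Garden & Frommer form

    O/E = n_CpG * L / (n_C * n_G)

with N bases excluded from all counts and from L. CpG islands are maximal
merged runs of 200-bp windows with GC >= 0.5 and O/E >= 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ValidationError
from .io import read_bed, read_fasta

# element class identifiers, in the order the study's tables use
ELEMENT_CLASSES = ("upstream2k", "5utr", "cds", "intron", "3utr", "downstream2k")

# display labels for table output
ELEMENT_LABELS = {
    "upstream2k": "Upstream 2k",
    "5utr": "5'UTR",
    "cds": "CDS",
    "intron": "Intron",
    "3utr": "3'UTR",
    "downstream2k": "Downstream 2k",
}

DEFAULT_FLANK = 2000


@dataclass
class GeneModel:
    """One gene with its derived element intervals (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int  # transcript span start
    end: int  # transcript span end
    strand: str
    elements: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def body(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class CpGStats:
    """Dinucleotide statistics of one interval."""

    chrom: str
    start: int
    end: int
    length: int  # N-excluded length
    count_c: int
    count_g: int
    count_cpg: int
    oe_ratio: float


@dataclass
class GenomeAnnotation:
    """Chromosomes, gene models, repeats and CpG islands for one genome."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    repeats: pd.DataFrame | None = None  # BED6-shaped, name = repeat class
    islands: pd.DataFrame | None = None  # chrom/start/end
    genome: dict[str, str] | None = None

    def element_intervals(self) -> pd.DataFrame:
        """All element intervals as a flat frame (chrom, start, end, gene_id, element)."""
        rows = []
        for gene in self.genes:
            for element, ivs in gene.elements.items():
                for s, e in ivs:
                    rows.append((gene.chrom, s, e, gene.gene_id, element))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "element"])

    def gene_bodies(self) -> pd.DataFrame:
        rows = [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in self.genes]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def derive_elements(
    chrom_size: int,
    start: int,
    end: int,
    strand: str,
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
    utr5: list[tuple[int, int]],
    utr3: list[tuple[int, int]],
    flank: int = DEFAULT_FLANK,
) -> dict[str, list[tuple[int, int]]]:
    """Derive the six element classes for one transcript span.

    Introns are the body minus exons. Flanks are strand-aware and clipped to
    the chromosome; a gene without annotated UTRs gets empty UTR element
    lists (recorded as such, never fabricated).
    """
    if strand == "+":
        upstream = (max(0, start - flank), start)
        downstream = (end, min(chrom_size, end + flank))
    else:
        upstream = (end, min(chrom_size, end + flank))
        downstream = (max(0, start - flank), start)

    introns: list[tuple[int, int]] = []
    if exons:
        merged = _merge_intervals(exons)
        cursor = start
        for s, e in merged:
            if s > cursor:
                introns.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < end:
            introns.append((cursor, end))

    return {
        "upstream2k": [upstream] if upstream[0] < upstream[1] else [],
        "5utr": sorted(utr5),
        "cds": sorted(cds),
        "intron": introns,
        "3utr": sorted(utr3),
        "downstream2k": [downstream] if downstream[0] < downstream[1] else [],
    }


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def load_annotation(
    gff3_path,
    fasta_path,
    repeat_bed_path=None,
    islands_bed_path=None,
    flank: int = DEFAULT_FLANK,
) -> GenomeAnnotation:
    """Load genome + GFF3 gene models (+ optional repeat/island BEDs).

    GFF3 coordinates (1-based inclusive) are converted to the package's
    0-based half-open convention on read. Any feature extending beyond its
    chromosome raises a :class:`ValidationError` naming the record.
    """
    genome = read_fasta(fasta_path)
    chrom_sizes = {name: len(seq) for name, seq in genome.items()}

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in chrom_sizes:
            raise ValidationError(f"gene {gene.id}: unknown chromosome {gene.seqid!r}")
        chrom_size = chrom_sizes[gene.seqid]
        start, end = gene.start - 1, gene.end
        if start < 0 or end > chrom_size:
            raise ValidationError(
                f"gene {gene.id}: interval [{start}, {end}) outside "
                f"chromosome {gene.seqid} of length {chrom_size}"
            )
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(gene, order_by="start"):
            iv = (child.start - 1, child.end)
            if iv[0] < 0 or iv[1] > chrom_size:
                raise ValidationError(
                    f"feature {child.id} of gene {gene.id}: outside chromosome"
                )
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        elements = derive_elements(
            chrom_size, start, end, gene.strand, exons, cds, utr5, utr3, flank
        )
        genes.append(GeneModel(gene.id, gene.seqid, start, end, gene.strand, elements))

    repeats = read_bed(repeat_bed_path) if repeat_bed_path else None
    islands = read_bed(islands_bed_path) if islands_bed_path else None
    return GenomeAnnotation(chrom_sizes, genes, repeats, islands, genome)


# ---------------------------------------------------------------------------
# CpG statistics


def cpg_counts(sequence: str) -> tuple[int, int, int, int]:
    """Return (N-excluded length, n_C, n_G, n_CpG) for one sequence."""
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    length = len(seq) - seq.count("N")
    return length, n_c, n_g, n_cpg


def cpg_oe(sequence: str) -> float:
    """CpG observed/expected ratio, Gardiner-Garden & Frommer form.

    O/E = n_CpG * L / (n_C * n_G); defined as 0 when n_C * n_G == 0.
    N bases are excluded from counts and length.
    """
    if len(sequence) == 0:
        raise DegenerateInputError("cpg_oe of an empty sequence is undefined")
    length, n_c, n_g, n_cpg = cpg_counts(sequence)
    if n_c * n_g == 0:
        return 0.0
    return n_cpg * length / (n_c * n_g)


def cpg_stats(genome: dict[str, str], chrom: str, start: int, end: int) -> CpGStats:
    seq = genome[chrom][start:end]
    length, n_c, n_g, n_cpg = cpg_counts(seq)
    oe = 0.0 if n_c * n_g == 0 else n_cpg * length / (n_c * n_g)
    return CpGStats(chrom, start, end, length, n_c, n_g, n_cpg, oe)


def detect_cpg_islands(
    genome: dict[str, str],
    window: int = 200,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> pd.DataFrame:
    """Detect CpG islands as merged maximal runs of qualifying windows.

    Every ``window``-bp window (1-bp step) with GC fraction >= ``min_gc`` and
    CpG O/E >= ``min_oe`` qualifies; overlapping or abutting qualifying
    windows are unioned, and unions shorter than ``min_length`` dropped.
    """
    rows = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        n = len(arr)
        if n < window:
            continue
        is_c = (arr == b"C").astype(np.int64)
        is_g = (arr == b"G").astype(np.int64)
        is_cpg = np.zeros(n, dtype=np.int64)
        if n > 1:
            is_cpg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")

        c_cum = np.concatenate([[0], np.cumsum(is_c)])
        g_cum = np.concatenate([[0], np.cumsum(is_g)])
        cpg_cum = np.concatenate([[0], np.cumsum(is_cpg)])

        starts = np.arange(0, n - window + 1)
        n_c = c_cum[starts + window] - c_cum[starts]
        n_g = g_cum[starts + window] - g_cum[starts]
        n_cpg = cpg_cum[starts + window] - cpg_cum[starts]

        gc_ok = (n_c + n_g) >= min_gc * window
        denom = n_c * n_g
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(denom > 0, n_cpg * window / np.maximum(denom, 1), 0.0)
        qualifying = gc_ok & (oe >= min_oe)

        # union of [s, s+window) over qualifying s via a coverage diff array
        cover = np.zeros(n + 1, dtype=np.int64)
        qs = starts[qualifying]
        np.add.at(cover, qs, 1)
        np.add.at(cover, qs + window, -1)
        covered = np.cumsum(cover[:-1]) > 0
        for s, e in _bool_runs(covered):
            if e - s >= min_length:
                rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def oe_distribution(
    regions: pd.DataFrame, genome: dict[str, str], bin_width: float = 0.2
) -> pd.Series:
    """Histogram of per-region CpG O/E ratios in fixed-width bins.

    Bins are [0, w), [w, 2w), ...; the returned counts sum to the number of
    regions. Index labels give each bin's left edge.
    """
    ratios = []
    for row in regions.itertuples(index=False):
        seq = genome[row.chrom][row.start : row.end]
        ratios.append(cpg_oe(seq) if len(seq) else 0.0)
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) == 0:
        return pd.Series(dtype=int, name="n_regions")
    n_bins = int(np.floor(ratios.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(ratios, bins=edges)
    index = pd.Index(np.round(edges[:-1], 10), name="oe_bin_left")
    return pd.Series(counts, index=index, name="n_regions")


def write_elements_bed(annotation: GenomeAnnotation, path) -> None:
    """Write all gene elements as BED6 (name = gene_id|element)."""
    df = annotation.element_intervals()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["gene_id"] + "|" + df["element"],
            "score": 0,
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_elements_bed(path) -> pd.DataFrame:
    """Read an elements BED back into (chrom, start, end, gene_id, element)."""
    bed = read_bed(path)
    split = bed["name"].str.split("|", n=1, expand=True)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "gene_id": split[0],
            "element": split[1],
        }
    )
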