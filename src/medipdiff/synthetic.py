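"""Synthetic two-condition MeDIP experiment with planted ground truth.

The generator emulates the study design this package analyses: sonicated
fragments of 100-500 bp, paired-end 50-bp reads, a fraction of multi-mapping
fragments, 5mC-dependent pulldown enrichment, and planted hyper-/hypo-
methylated regions between a sterile-like condition S and a fertile-like
condition F. Methylation is assigned at region level (fixed tiles), matching
the resolution of every downstream statistic.

Pulldown model: a fragment's capture weight is its methylated-CpG content
plus a small background epsilon. With region-level methylation this is
realised by drawing fragment midpoints from a categorical over regions with

    w_r = level_r * mean_fragment_length * nCpG_r + epsilon * region_length

then placing the midpoint uniformly within the region; under an all-zero
methylome the weights reduce to region lengths, i.e. uniform background.
All randomness flows through one seeded numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import DEFAULT_FLANK, GeneModel, GenomeAnnotation, derive_elements
from .exceptions import DegenerateInputError, SizingError, ValidationError
from .io import ensure_dir, write_bed, write_fasta
from .profiles import FragmentSet
from .repeats import KNOWN_REPEAT_CLASSES

BASES = np.array(["A", "C", "G", "T"])

# repeat element length ranges by class (bp); invented but class-typical
_REPEAT_LENGTHS = {
    "LTR/Copia": (1000, 4000),
    "DNA/En-Spm": (500, 3000),
    "LTR/Gypsy": (1000, 4000),
    "LTR": (300, 1500),
    "LINE/L1": (500, 2000),
    "SINE": (150, 400),
}


@dataclass
class SyntheticConfig:
    """Parameters of one simulated two-condition MeDIP experiment."""

    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 40
    n_repeats_per_class: int = 10
    repeat_classes: tuple = KNOWN_REPEAT_CLASSES
    gc_content: float = 0.44
    n_fragments: int = 50_000
    frag_len_range: tuple = (100, 500)
    read_len: int = 50
    n_planted_dmrs: int = 20
    planted_fold: float = 4.0
    region_size: int = 1000
    epsilon: float = 0.1
    nonunique_fraction: float = 0.35
    island_promoter_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.frag_len_range[0] < self.read_len:
            raise ValidationError("minimum fragment length must be >= read length")
        if self.planted_fold < 1:
            raise ValidationError("planted_fold must be >= 1")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_fragments",
                     "region_size"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_repeats_per_class < 0 or self.n_planted_dmrs < 0:
            raise ValidationError("counts must be non-negative")
        if not 0 < self.gc_content < 1:
            raise ValidationError("gc_content must be in (0, 1)")
        if not 0 <= self.nonunique_fraction <= 1:
            raise ValidationError("nonunique_fraction must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueMethylome:
    """Region-level methylation per condition with the planted-DMR truth table."""

    regions: pd.DataFrame  # chrom, start, end, level_S, level_F, planted, direction, fold

    @property
    def truth(self) -> pd.DataFrame:
        """Planted DMRs only (the parameter-recovery ground truth)."""
        return self.regions[self.regions["planted"]].reset_index(drop=True)

    def levels(self, condition: str) -> np.ndarray:
        return self.regions[f"level_{condition}"].to_numpy()


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(BASES, size=length, p=probs)


def _island_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-dense, GC-rich sequence for seeding islands at promoters."""
    out: list[str] = []
    while len(out) < length:
        if rng.random() < 0.3:
            out.extend(("C", "G"))
        else:
            out.append(str(rng.choice(BASES, p=[0.2, 0.3, 0.3, 0.2])))
    return np.array(out[:length])


def _gene_structure(rng: np.random.Generator) -> dict:
    """Draw one gene's internal layout: 5'UTR, >=2 CDS exons, introns, 3'UTR."""
    utr5 = int(rng.integers(120, 300))
    utr3 = int(rng.integers(120, 300))
    n_exons = int(rng.integers(2, 4))
    exon_lens = rng.integers(200, 800, size=n_exons)
    intron_lens = rng.integers(100, 800, size=n_exons - 1)
    return {
        "utr5": utr5,
        "utr3": utr3,
        "exon_lens": exon_lens.tolist(),
        "intron_lens": intron_lens.tolist(),
        "body": utr5 + utr3 + int(exon_lens.sum()) + int(intron_lens.sum()),
    }


# worst-case body span for capacity checks
_MAX_BODY = 300 + 300 + 3 * 800 + 2 * 800
_GENE_SPACING = (200, 1000)


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], GenomeAnnotation]:
    """Generate a random genome with gene models, repeats and CpG islands.

    Genes are laid out left to right with 2-kb flanks and random spacing,
    alternating strand so both strands are represented; each has a 5'UTR,
    >= 2 exons (hence >= 1 intron) and a 3'UTR. A configurable fraction of
    promoters receives a planted CpG-dense island. Repeats are placed
    uniformly at random per class. Raises :class:`SizingError` when the
    chromosomes cannot hold the requested features.
    """
    if rng is None:
        rng = config.rng()

    # distribute genes over chromosomes round-robin
    genes_per_chrom = [0] * config.n_chromosomes
    for i in range(config.n_genes):
        genes_per_chrom[i % config.n_chromosomes] += 1
    worst_span = _MAX_BODY + 2 * DEFAULT_FLANK + _GENE_SPACING[1]
    for c, n_g in enumerate(genes_per_chrom):
        if n_g * worst_span + DEFAULT_FLANK > config.chrom_length:
            raise SizingError(
                f"chromosome {c + 1} of {config.chrom_length} bp too short for "
                f"{n_g} genes (worst-case span {worst_span} bp each)"
            )

    genome: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    repeat_rows = []
    gene_counter = 0

    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = _random_sequence(rng, config.chrom_length, config.gc_content)

        cursor = DEFAULT_FLANK + int(rng.integers(*_GENE_SPACING))
        for _ in range(genes_per_chrom[c]):
            structure = _gene_structure(rng)
            strand = "+" if gene_counter % 2 == 0 else "-"
            start = cursor
            end = start + structure["body"]

            # build exon/CDS/UTR intervals in genomic orientation
            if strand == "+":
                utr5_iv = (start, start + structure["utr5"])
                utr3_iv = (end - structure["utr3"], end)
                pos = utr5_iv[1]
            else:
                utr3_iv = (start, start + structure["utr3"])
                utr5_iv = (end - structure["utr5"], end)
                pos = utr3_iv[1]
            cds, introns = [], []
            exon_lens = structure["exon_lens"]
            intron_lens = structure["intron_lens"]
            if strand == "-":
                exon_lens = exon_lens[::-1]
                intron_lens = intron_lens[::-1]
            for k, ex_len in enumerate(exon_lens):
                cds.append((pos, pos + ex_len))
                pos += ex_len
                if k < len(intron_lens):
                    introns.append((pos, pos + intron_lens[k]))
                    pos += intron_lens[k]
            # exons (UTR-containing) = body minus introns
            exons = _subtract(start, end, introns)

            gene_id = f"gene{gene_counter + 1:04d}"
            elements = derive_elements(
                config.chrom_length, start, end, strand,
                exons, cds, [utr5_iv], [utr3_iv],
            )
            gene_models.append(GeneModel(gene_id, chrom, start, end, strand, elements))

            # planted CpG island in a fraction of promoters (just 5' of the TSS)
            if rng.random() < config.island_promoter_fraction:
                island_len = 300
                if strand == "+":
                    isl = (max(0, start - island_len), start)
                else:
                    isl = (end, min(config.chrom_length, end + island_len))
                seq[isl[0]:isl[1]] = _island_sequence(rng, isl[1] - isl[0])

            gene_counter += 1
            cursor = end + 2 * DEFAULT_FLANK + int(rng.integers(*_GENE_SPACING))

        genome[chrom] = "".join(seq)

    # repeats: uniform placement per class
    for rep_class in config.repeat_classes:
        lo, hi = _REPEAT_LENGTHS.get(rep_class, (300, 2000))
        for _ in range(config.n_repeats_per_class):
            chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
            length = int(rng.integers(lo, hi))
            if length >= config.chrom_length:
                raise SizingError(
                    f"repeat of {length} bp does not fit chromosome of "
                    f"{config.chrom_length} bp"
                )
            start = int(rng.integers(0, config.chrom_length - length))
            strand = "+" if rng.random() < 0.5 else "-"
            repeat_rows.append((chrom, start, start + length, rep_class, 0, strand))

    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    chrom_sizes = {name: len(s) for name, s in genome.items()}
    annotation = GenomeAnnotation(chrom_sizes, gene_models, repeats, None, genome)
    return genome, annotation


def _subtract(start: int, end: int, introns: list[tuple[int, int]]) -> list:
    """Exon intervals = [start, end) minus intron intervals."""
    out = []
    cursor = start
    for s, e in sorted(introns):
        if s > cursor:
            out.append((cursor, s))
        cursor = e
    if cursor < end:
        out.append((cursor, end))
    return out


def tile_regions(chrom_sizes: dict[str, int], region_size: int) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        for s in range(0, size, region_size):
            rows.append((chrom, s, min(s + region_size, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_methylome(
    annotation: GenomeAnnotation,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> TrueMethylome:
    """Draw a region-level methylome and plant the configured DMRs.

    Baseline levels are shared between conditions; exactly
    ``n_planted_dmrs`` distinct regions are altered in condition S by
    ``planted_fold`` (hyper: level * fold, capped at 1; hypo: level / fold),
    with the direction drawn per region. ``planted_fold = 1`` yields a null
    methylome with identical conditions.
    """
    if rng is None:
        rng = config.rng()
    regions = tile_regions(annotation.chrom_sizes, config.region_size)
    n = len(regions)
    if config.n_planted_dmrs > n:
        raise ValidationError(
            f"{config.n_planted_dmrs} planted DMRs requested but only {n} regions exist"
        )
    baseline = rng.uniform(0.05, 0.25, size=n)
    level_s = baseline.copy()
    level_f = baseline.copy()
    planted = np.zeros(n, dtype=bool)
    direction = np.array([""] * n, dtype=object)

    idx = rng.choice(n, size=config.n_planted_dmrs, replace=False)
    for i in idx:
        planted[i] = True
        if rng.random() < 0.5:
            direction[i] = "hyper"
            level_s[i] = min(baseline[i] * config.planted_fold, 1.0)
        else:
            direction[i] = "hypo"
            level_s[i] = baseline[i] / config.planted_fold

    regions = regions.assign(
        level_S=level_s,
        level_F=level_f,
        planted=planted,
        direction=direction,
        fold=np.where(planted, config.planted_fold, 1.0),
    )
    return TrueMethylome(regions)


def _region_cpg_counts(genome: dict[str, str], regions: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, row in enumerate(regions.itertuples(index=False)):
        counts[i] = genome[row.chrom].count("CG", row.start, row.end)
    return counts


def simulate_medip(
    genome: dict[str, str],
    methylome: TrueMethylome,
    config: SyntheticConfig,
    condition: str,
    rng: np.random.Generator | None = None,
) -> FragmentSet:
    """Sample one condition's MeDIP fragment library.

    Fragment midpoints are drawn region-categorically with weight
    level * mean_fragment_length * nCpG + epsilon * region_length, lengths
    uniform in ``frag_len_range``, and a ``nonunique_fraction`` of fragments
    flagged multi-mapping. Raises :class:`DegenerateInputError` for a
    CpG-free genome with epsilon = 0.
    """
    if rng is None:
        rng = config.rng()
    regions = methylome.regions
    n_cpg = _region_cpg_counts(genome, regions)
    if n_cpg.sum() == 0 and config.epsilon == 0:
        raise DegenerateInputError(
            "genome contains no CpG and epsilon is 0: zero pulldown weight everywhere"
        )
    levels = methylome.levels(condition)
    lengths_r = (regions["end"] - regions["start"]).to_numpy()
    mean_frag = (config.frag_len_range[0] + config.frag_len_range[1]) / 2.0
    weights = levels * mean_frag * n_cpg + config.epsilon * lengths_r
    if weights.sum() <= 0:
        raise DegenerateInputError("all pulldown weights are zero")
    probs = weights / weights.sum()

    chrom_sizes = {c: len(s) for c, s in genome.items()}
    region_idx = rng.choice(len(regions), size=config.n_fragments, p=probs)
    offsets = rng.random(config.n_fragments)
    frag_lens = rng.integers(
        config.frag_len_range[0], config.frag_len_range[1] + 1, size=config.n_fragments
    )
    starts_r = regions["start"].to_numpy()[region_idx]
    mids = starts_r + (offsets * lengths_r[region_idx]).astype(np.int64)
    chroms = regions["chrom"].to_numpy()[region_idx]
    sizes = np.array([chrom_sizes[c] for c in chroms])
    starts = mids - frag_lens // 2
    starts = np.clip(starts, 0, sizes - frag_lens)
    ends = starts + frag_lens
    unique = rng.random(config.n_fragments) >= config.nonunique_fraction

    frags = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "unique": unique}
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    return FragmentSet(condition, frags)


def generate_term_map(
    annotation: GenomeAnnotation,
    n_terms: int = 20,
    mean_genes_per_term: int = 8,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Random gene->term map over the synthetic genes (for enrichment demos)."""
    if rng is None:
        rng = np.random.default_rng()
    gene_ids = [g.gene_id for g in annotation.genes]
    rows = []
    for t in range(n_terms):
        size = max(2, int(rng.poisson(mean_genes_per_term)))
        size = min(size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        for g in members:
            rows.append((g, f"TERM:{t + 1:04d}"))
    return pd.DataFrame(rows, columns=["gene", "term"])


@dataclass
class SimulatedExperiment:
    """Bundle of one synthetic two-condition MeDIP experiment."""

    config: SyntheticConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    methylome: TrueMethylome
    fragments: dict[str, FragmentSet]  # condition -> FragmentSet
    term_map: pd.DataFrame


def simulate_experiment(config: SyntheticConfig) -> SimulatedExperiment:
    """Run the full generator under one seed: genome, methylome, libraries."""
    rng = config.rng()
    genome, annotation = generate_genome(config, rng)
    methylome = assign_methylome(annotation, config, rng)
    frag_s = simulate_medip(genome, methylome, config, "S", rng)
    frag_f = simulate_medip(genome, methylome, config, "F", rng)
    term_map = generate_term_map(annotation, rng=rng)
    return SimulatedExperiment(
        config, genome, annotation, methylome, {"S": frag_s, "F": frag_f}, term_map
    )


# ---------------------------------------------------------------------------
# file emission


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write gene models as GFF3 (1-based inclusive on write)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in annotation.chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for gene in annotation.genes:
            base = f"{gene.chrom}\tmedipdiff\t"
            attrs = f"ID={gene.gene_id}"
            fh.write(
                f"{base}gene\t{gene.start + 1}\t{gene.end}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{gene.gene_id}.1"
            fh.write(
                f"{base}mRNA\t{gene.start + 1}\t{gene.end}\t.\t{gene.strand}\t.\t"
                f"ID={mrna_id};Parent={gene.gene_id}\n"
            )
            feature_types = (
                ("five_prime_UTR", "5utr"),
                ("CDS", "cds"),
                ("three_prime_UTR", "3utr"),
            )
            # exons = body minus introns
            introns = gene.elements.get("intron", [])
            exons = _subtract(gene.start, gene.end, list(introns))
            for s, e in exons:
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\tParent={mrna_id}\n"
                )
            for ftype, element in feature_types:
                for s, e in gene.elements.get(element, []):
                    fh.write(
                        f"{base}{ftype}\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                        f"Parent={mrna_id}\n"
                    )


def write_fragments_bed(fragment_set: FragmentSet, path) -> None:
    """Fragments as BED6; score 1 = uniquely mapped, 0 = multi-mapping."""
    frags = fragment_set.fragments
    df = pd.DataFrame(
        {
            "chrom": frags["chrom"],
            "start": frags["start"],
            "end": frags["end"],
            "name": [f"{fragment_set.sample}_frag{i}" for i in range(len(frags))],
            "score": frags["unique"].astype(int),
            "strand": "+",
        }
    )
    write_bed(df, path)


def write_fragments_sam(
    fragment_set: FragmentSet, genome: dict[str, str], path, read_len: int = 50
) -> None:
    """Optional paired-end SAM emission: two ``read_len``-bp ends per fragment."""
    import pysam

    chrom_names = list(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chrom_names],
    }
    tid = {c: i for i, c in enumerate(chrom_names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        frags = fragment_set.fragments
        for i, row in enumerate(frags.itertuples(index=False)):
            name = f"{fragment_set.sample}_frag{i}"
            mapq = 60 if row.unique else 0
            for mate, (s, e) in enumerate(
                [(row.start, row.start + read_len), (row.end - read_len, row.end)]
            ):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.reference_id = tid[row.chrom]
                a.reference_start = int(s)
                seq = genome[row.chrom][s:e]
                if mate == 1:
                    from .bisulfite import reverse_complement

                    seq = reverse_complement(seq)
                a.query_sequence = seq
                a.cigarstring = f"{read_len}M"
                a.mapping_quality = mapq
                a.flag = (99, 147)[mate]
                a.next_reference_id = tid[row.chrom]
                a.next_reference_start = int((row.end - read_len, row.start)[mate])
                a.template_length = int((e - s if mate == 0 else s - e))
                out.write(a)


def write_experiment(exp: SimulatedExperiment, outdir, sam: bool = False) -> dict:
    """Write the full experiment bundle; byte-identical under a fixed seed."""
    out = ensure_dir(outdir)
    paths = {
        "genome": out / "genome.fa",
        "genes": out / "genes.gff3",
        "repeats": out / "repeats.bed",
        "truth": out / "true_methylome.tsv",
        "term_map": out / "gene_terms.tsv",
    }
    write_fasta(exp.genome, paths["genome"])
    write_gff3(exp.annotation, paths["genes"])
    write_bed(exp.annotation.repeats, paths["repeats"])
    exp.methylome.regions.to_csv(paths["truth"], sep="\t", index=False)
    exp.term_map.to_csv(paths["term_map"], sep="\t", index=False, header=False)
    for cond, fs in exp.fragments.items():
        p = out / f"fragments_{cond}.bed"
        write_fragments_bed(fs, p)
        paths[f"fragments_{cond}"] = p
        if sam:
            sp = out / f"reads_{cond}.sam"
            write_fragments_sam(fs, exp.genome, sp, exp.config.read_len)
            paths[f"reads_{cond}"] = sp
    return {k: str(v) for k, v in paths.items()}
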