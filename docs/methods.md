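# Methods

This note documents the models, statistics and design choices behind
`medipdiff`, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Data model and coordinates

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on read and write, BED shares the internal convention. Counting is
fragment-level everywhere: MeDIP enriches fragments, not reads, so the two
ends of a read pair are one observation, and a fragment is assigned to
exactly one tiled window — the one containing its midpoint — which avoids
double counting across window edges. Library-size normalization uses the
uniquely mapped fragment count, and only uniquely mapped fragments enter
peak scanning and differential testing.

Each gene is decomposed into six element classes: upstream 2 kb, 5'UTR,
CDS, intron, 3'UTR, downstream 2 kb. Flanks are strand-aware (upstream is
the 5' side) and clipped at chromosome edges. "Gene body" means the
transcript span — 5'UTR start to 3'UTR end — with CDS and intron
partitioning the interior; this inclusion of UTRs in the body is a
convention choice and is labelled as such in outputs. Genes without
annotated UTRs keep empty UTR element sets rather than fabricated ones. One
model per gene; isoform resolution is out of scope.

## CpG statistics

The CpG observed/expected ratio uses the Gardiner-Garden & Frommer form
O/E = n_CpG · L / (n_C · n_G), with N bases excluded from all counts and
from L, and O/E defined as 0 when n_C·n_G = 0. CpG islands are maximal
unions of 200-bp windows (1-bp step) with GC ≥ 0.5 and O/E ≥ 0.6 — the
classic island criteria; unions shorter than 200 bp are dropped. Histograms
of per-region O/E use fixed left-closed bins of width 0.2.

## Profiles

Metagene curves split each 2-kb flank into 20 fixed 100-bp bins and each
feature body into 40 equal parts. Per bin, midpoint-assigned fragment
counts are divided by bin length (bp) and by library size in millions;
minus-strand features are reversed so bin 1 is always 5'-most, and the
profile is the unweighted mean over features. Features shorter than the
body bin count are skipped with a warning. On deterministic uniform
coverage the curve is flat to better than 10⁻⁶ relative — this is asserted
in the tests.

Between-sample level comparisons use the two-sample Student's *t* with
pooled variance (not Welch) on per-window RPKM, genome-wide and per element
class (a window belongs to a class when it overlaps any element of that
class; both groupings are emitted because flank windows can also be scored
as element subsets). Zero-variance degenerate inputs return t = 0, p = 1
for equal means instead of a division error. Stars mark p < 0.01 and
p < 0.001.

## Peak scanning and DMR calling

Peak scanning is the minimal standard model: per tiled window a Poisson
upper-tail p-value against the genome-wide mean count per window,
Benjamini-Hochberg adjustment, windows with adjusted p < 10⁻⁴ kept and
merged across gaps up to `merge_gap`, carrying summed counts.

The differential test universe is the union of peaks from both samples, so
hyper- and hypomethylation are treated symmetrically. Each region's 2×2
table — (region count, library remainder) × (S, F) — is tested with
Fisher's exact test (two-sided); an exact count test is the defensible
default at region scale and its p-values match exhaustive hypergeometric
enumeration to 10⁻¹². BH across all tested regions gives q. The normalized
fold change adds a 0.5 pseudocount to each count to keep zero-count regions
finite. A region is called iff p < 0.05, q < 0.05 and fold ≥ 2 or ≤ ½
(all thresholds configurable). Regions with zero counts in both samples are
excluded from testing and flagged.

The per-element differentially-methylated-gene table reports distinct genes
per (element class, direction). Because a gene can host DMRs in several
elements, the table carries two deliberately distinct summary rows:
`column_sum` (sum of per-element rows) and `distinct_total` (distinct genes
with ≥ 1 DMR of that direction anywhere). Published tabulations of this
shape are ambiguous about which rule their totals follow — the hypo column
of the reference tabulation sums to 401 against a printed total of 533 —
so both are always emitted, clearly labelled. "Methylated genes" are those
overlapping any peak in upstream 2 kb, gene body or downstream 2 kb.

## Repeat summaries

Fragments are assigned to 10-kb tiled windows by midpoint; each window's
count is attributed to the repeat classes overlapping the window
proportionally to each class's overlap length, and percentages are of the
repeat-assigned total (this denominator reproduces the internal consistency
of the reference tabulation's count/percentage pairs). Unknown class labels
are retained under "other" with a warning. A direct per-element mode
(midpoint inside a repeat element) is provided as a labelled alternative,
since window-mediated attribution and direct element counting can differ.

## Term enrichment

For a universe of N annotated genes with n differential, a term annotating
M genes of which m are differential scores P(X ≥ m) for hypergeometric X —
the upper tail 1 − Σ_{i=0}^{m−1} C(M,i)C(N−M,n−i)/C(N,n) — computed by
log-space summation (log-gamma binomials + logsumexp) for stability. BH
step-up gives the Q-value; significance is q ≤ 0.05. Terms with M = 0 or
m = 0 are reported with p = 1 rather than omitted so term lists are stable
across runs. Duplicate input ids are collapsed; ids outside the universe
are dropped with a warning. The same machinery serves GO and KEGG; GO graph
propagation is out of scope (the gene→term map is taken as supplied).

## Bisulfite clone analysis

Cytosine contexts CG, CHG, CHH (H ∈ {A, C, T}) are classified with CG >
CHG > CHH precedence from the two downstream bases on the amplified strand;
edge cytosines without two flank bases are unscorable and excluded from
denominators. Quantification is strand-specific — a bisulfite PCR
amplifies one strand, so the opposite strand needs its own amplicon — and
the one-strand semantics are labelled in outputs. Per context,
% methylation = 100 × retained-C calls / scorable calls; clones that do not
match the reference length are rejected by name (alignment with indels is
out of scope), and non-C/T bases at cytosine positions are mismatches
excluded from both numerator and denominator. No minimum-conversion filter
is applied by default; an optional clone filter on CHH retention is
available but off, and the CHH retention fraction is reported as a
conversion-failure proxy. The clone simulator methylates each site with its
context probability, never converts methylated C, and converts unmethylated
C with the configured efficiency (default 0.99).

## Relative expression (2^−ΔΔCt)

Replicate Ct values are averaged per (sample, gene) before differencing:
ΔCt = mean Ct(target) − mean Ct(reference), ΔΔCt = ΔCt(sample) −
ΔCt(calibrator), fold = 2^−ΔΔCt. The standard error is delta-method
propagated from the four replicate-group variances of the mean:
SE = fold · ln 2 · sqrt(Σ s²ᵢ/nᵢ). Amplification-efficiency correction
(Pfaffl) is out of scope. The reference gene defaults to *actin1*.

## The synthetic-data generator

The generator emulates the study design the package analyses, and its
defaults are the study's stated conditions where they exist: fragments
uniform in 100–500 bp (sonication range), paired-end 50-bp reads, and a
multi-mapping fraction of 0.35 chosen to match the observed unique/mapped
ratio of the real libraries (~65% of mapped reads unique). The remaining
parameters are free — the IP efficiency and background rate of the real
libraries are not published — and were fixed once at field-plausible
values: GC content 0.44 (rice-like), background pulldown ε = 0.1, baseline
methylation uniform in [0.05, 0.25] per 1-kb region.

Methylation is assigned at region level (1-kb tiles by default), matching
the resolution of all downstream statistics. Baseline levels are shared
between conditions; exactly `n_planted_dmrs` regions are altered in
condition S by `planted_fold` (hyper: ×fold capped at 1; hypo: ÷fold), with
direction drawn per region, so non-planted regions are exactly null.

Pulldown sampling: the spec-level model weights a fragment by its
methylated-CpG count plus ε. With region-level methylation this is realised
as a categorical draw of the fragment midpoint over regions with weight
w_r = level_r · mean_fragment_length · nCpG_r + ε · region_length, then a
uniform midpoint within the region and a uniform length — the region-level
rendering of the per-fragment weight, which coincides with it in
expectation at the resolution methylation is defined on. Under an all-zero
methylome the weights reduce to region lengths, i.e. uniform background
(verified by a χ² goodness-of-fit test), and mean region coverage is
monotone in the planted level.

What the generator does **not** emulate: sequencing errors, base qualities,
adapter artefacts, mappability structure (multi-mapping flags are i.i.d.
rather than repeat-driven), per-cytosine methylation heterogeneity,
fragment-level GC bias, and any real-genome sequence composition. Passing
tests therefore demonstrate the correctness and calibration of the
statistics under the stated sampling model, not robustness to real-data
artefacts such as mappability-correlated background.

Genes are laid out left-to-right with alternating strands (both strands
always represented), each with a 5'UTR, 2–3 CDS exons, introns and a 3'UTR;
a configurable fraction of promoters (default 0.5) receives a planted
300-bp CpG-dense island. Repeats are placed uniformly per class with
class-typical length ranges. All randomness flows through one seeded numpy
Generator passed explicitly; a fixed seed reproduces every output file
byte-identically.

## Evaluation problem sizes

The planted-truth benchmark runs 20 simulated experiments of 1000 1-kb
regions with 100 planted 4-fold DMRs and 100,000 fragments per library
(~65 unique fragments per region after multi-mapper filtering), scoring
sensitivity (planted regions recovered with correct direction), pooled
empirical FDR, and — with fold 1 — the null called fraction. These sizes
give the exact test ample power while keeping the benchmark to a few
minutes on one CPU; they are the sizes reported by `scripts/acceptance.py`.
Oracle-equivalence checks enumerate 2×2 tables with library totals up to
500 in exact rational arithmetic and all hypergeometric parameter
combinations with N ≤ 60.

## Known limitations

- The peak-scanning background is a global Poisson rate; no local
  (GC- or mappability-stratified) background correction.
- Fisher's exact test treats fragments as independent draws; overdispersion
  between biological replicates is not modelled (the design has one library
  per condition, as in the motivating study).
- Enrichment does not propagate GO ancestors; results depend on the
  supplied gene→term map.
- Bisulfite quantification requires indel-free clone alignments.
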