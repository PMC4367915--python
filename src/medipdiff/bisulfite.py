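"""Bisulfite clone analysis: cytosine contexts, conversion simulation, and
per-context methylation quantification.

Bisulfite treatment deaminates unmethylated cytosine to uracil (sequenced as
T) while 5-methylcytosine resists conversion, so a retained C in a clone is
read as methylated. Plant methylation is scored in three sequence contexts —
CG, CHG, CHH (H in {A, C, T}) — classified with CG > CHG > CHH precedence
from the two downstream bases on the amplified strand.

Quantification is strand-specific: a bisulfite PCR amplifies one strand, so
percentages refer to the amplified strand only; the opposite strand needs
its own amplicon. Per context,

    % methylation = 100 * retained C calls / total scorable calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

CONTEXTS = ("CG", "CHG", "CHH")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CytosineSite:
    """One reference cytosine on the amplified strand."""

    position: int  # 0-based within the amplicon, amplified-strand orientation
    strand: str
    context: str | None  # CG | CHG | CHH | None when unscorable
    scorable: bool


@dataclass
class CloneMethylation:
    """Per-site calls and per-context percentages over a clone set."""

    per_site: pd.DataFrame  # position, context, n_meth, n_unmeth, n_mismatch
    percentages: dict[str, float]  # context -> percent, only contexts present
    n_clones: int
    conversion_failure_estimate: float  # CHH retention fraction (proxy)
    rejected_clones: list[str] = field(default_factory=list)


def classify_contexts(
    amplicon: str,
    right_flank: str = "",
    strand: str = "+",
    left_flank: str = "",
) -> list[CytosineSite]:
    """Classify every cytosine of the amplified strand of an amplicon.

    ``left_flank``/``right_flank`` are genomic sequence beyond the amplicon
    edges (reference orientation); two downstream bases are needed to score a
    site, so edge cytosines without flank are flagged unscorable and excluded
    from denominators. For ``strand="-"`` the amplified strand is the reverse
    complement; positions are still reported in that strand's 5'->3' frame.
    """
    amplicon = amplicon.upper()
    if strand == "-":
        work = reverse_complement(amplicon)
        down = reverse_complement(left_flank.upper())
    elif strand == "+":
        work = amplicon
        down = right_flank.upper()
    else:
        raise ValidationError(f"strand must be + or -, got {strand!r}")

    extended = work + down
    sites: list[CytosineSite] = []
    n = len(work)
    for i in range(n):
        if work[i] != "C":
            continue
        b1 = extended[i + 1] if i + 1 < len(extended) else None
        b2 = extended[i + 2] if i + 2 < len(extended) else None
        context: str | None
        scorable = True
        if b1 == "G":
            context = "CG"
        elif b1 in ("A", "C", "T"):
            if b2 == "G":
                context = "CHG"
            elif b2 in ("A", "C", "T"):
                context = "CHH"
            else:
                context, scorable = None, False
        else:
            context, scorable = None, False
        sites.append(CytosineSite(i, strand, context, scorable))
    return sites


def simulate_clones(
    amplicon: str,
    sites: list[CytosineSite],
    context_probabilities: dict[str, float],
    n_clones: int = 15,
    conversion_efficiency: float = 0.99,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Simulate bisulfite-converted clone sequences of one amplicon strand.

    Each scorable site is methylated with its context probability; a
    methylated C is never converted, an unmethylated C converts to T with
    ``conversion_efficiency`` (residual Cs are conversion failures).
    Unscorable cytosines are treated as unmethylated. Deterministic under a
    seeded ``rng``.
    """
    for ctx, p in context_probabilities.items():
        if not 0 <= p <= 1:
            raise ValidationError(f"probability for {ctx} outside [0, 1]: {p}")
    if not 0 <= conversion_efficiency <= 1:
        raise ValidationError("conversion_efficiency must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    work = amplicon.upper()
    clones = []
    for _ in range(n_clones):
        seq = list(work)
        for site in sites:
            p_meth = context_probabilities.get(site.context, 0.0) if site.scorable else 0.0
            if rng.random() < p_meth:
                continue  # methylated: C retained
            if rng.random() < conversion_efficiency:
                seq[site.position] = "T"
        clones.append("".join(seq))
    return clones


def quantify(
    amplicon: str,
    sites: list[CytosineSite],
    clones: list[str],
    max_chh_retention: float | None = None,
) -> CloneMethylation:
    """Per-context methylation percentages from aligned clone sequences.

    Clones must align to the amplicon without indels (length mismatch
    rejects the clone with a message). At each scorable cytosine a retained
    C counts methylated, a T unmethylated; any other base is a mismatch and
    excluded from numerator and denominator. The optional
    ``max_chh_retention`` filter (off by default) drops clones whose CHH
    retention fraction exceeds the threshold, a conventional screen for
    failed conversion.
    """
    work = amplicon.upper()
    accepted: list[str] = []
    rejected: list[str] = []
    for idx, clone in enumerate(clones):
        clone = clone.upper()
        if len(clone) != len(work):
            rejected.append(
                f"clone {idx}: length {len(clone)} != reference {len(work)}"
            )
            continue
        accepted.append(clone)
    if rejected:
        warnings.warn(
            f"rejected {len(rejected)} clones with length mismatches", stacklevel=2
        )

    scorable = [s for s in sites if s.scorable]

    def _chh_retention(clone: str) -> float:
        chh = [s for s in scorable if s.context == "CHH"]
        calls = [clone[s.position] for s in chh if clone[s.position] in "CT"]
        if not calls:
            return 0.0
        return calls.count("C") / len(calls)

    if max_chh_retention is not None:
        kept = []
        for clone in accepted:
            if _chh_retention(clone) > max_chh_retention:
                rejected.append("clone dropped: CHH retention above threshold")
            else:
                kept.append(clone)
        accepted = kept

    rows = []
    for site in scorable:
        n_meth = n_unmeth = n_mismatch = 0
        for clone in accepted:
            base = clone[site.position]
            if base == "C":
                n_meth += 1
            elif base == "T":
                n_unmeth += 1
            else:
                n_mismatch += 1
        rows.append(
            {
                "position": site.position,
                "context": site.context,
                "n_meth": n_meth,
                "n_unmeth": n_unmeth,
                "n_mismatch": n_mismatch,
            }
        )
    per_site = pd.DataFrame(
        rows, columns=["position", "context", "n_meth", "n_unmeth", "n_mismatch"]
    )

    percentages: dict[str, float] = {}
    for ctx in CONTEXTS:
        sub = per_site[per_site["context"] == ctx]
        total = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
        if len(sub):
            percentages[ctx] = 100.0 * sub["n_meth"].sum() / total if total else 0.0

    chh_sub = per_site[per_site["context"] == "CHH"]
    chh_total = int(chh_sub["n_meth"].sum() + chh_sub["n_unmeth"].sum())
    conv_fail = chh_sub["n_meth"].sum() / chh_total if chh_total else 0.0

    return CloneMethylation(per_site, percentages, len(accepted), float(conv_fail), rejected)
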