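"""Hypergeometric term enrichment for gene sets (GO / KEGG orthology alike).

For a universe of N annotated genes, n of them differential, a term
annotating M genes of which m are differential, the enrichment p-value is
the upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)
      = P(X >= m),  X ~ Hypergeometric(N, M, n)

computed by summing the log-space pmf over the achievable upper tail.
Benjamini-Hochberg across tested terms gives the Q-value; the same machinery
serves GO terms and KEGG pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_pmf_log(i: np.ndarray, N: int, n: int, M: int) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(N, M, n)."""
    i = np.asarray(i)
    return (
        _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
    )


def hypergeom_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail enrichment probability P(X >= m).

    Parameters follow the field convention: N annotated genes in the
    universe, n differential genes, M genes annotated to the term, m
    differential genes in the term. m = 0 gives exactly 1.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValidationError(f"invalid universe: N={N}, n={n}, M={M}")
    if not (0 <= m <= min(n, M)):
        raise ValidationError(f"m={m} outside [0, min(n={n}, M={M})]")
    if m == 0:
        return 1.0
    lo = max(m, n + M - N)
    hi = min(n, M)
    if lo > hi:
        return 0.0
    i = np.arange(lo, hi + 1)
    p = float(np.exp(logsumexp(hypergeom_pmf_log(i, N, n, M))))
    return min(max(p, 0.0), 1.0)


@dataclass
class TermUniverse:
    """Annotated gene universe with term -> gene-set map."""

    terms: dict[str, set[str]]
    genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        annotated = set().union(*self.terms.values()) if self.terms else set()
        if not self.genes:
            self.genes = annotated
        elif not annotated <= self.genes:
            raise ValidationError("term map annotates genes outside the universe")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @classmethod
    def from_tsv(cls, path) -> "TermUniverse":
        """Two-column gene<TAB>term mapping (no header)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
        terms: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            terms.setdefault(str(row.term), set()).add(str(row.gene))
        return cls(terms)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TermUniverse":
        terms: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            terms.setdefault(str(row.term), set()).add(str(row.gene))
        return cls(terms)


def enrich(
    de_genes, universe: TermUniverse, q_max: float = 0.05
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a differential gene set.

    Duplicated input ids are collapsed; ids outside the universe are dropped
    with a warning. Terms with M = 0 or m = 0 are reported with p = 1 so term
    lists are stable across runs. Output is sorted by p with BH q-values and
    a ``significant`` flag at q <= q_max.
    """
    de = set(map(str, de_genes))
    strays = de - universe.genes
    if strays:
        warnings.warn(
            f"{len(strays)} differential genes absent from the universe were dropped",
            stacklevel=2,
        )
        de &= universe.genes
    if not de:
        warnings.warn("empty differential gene set; no enrichment computed", stacklevel=2)
        return pd.DataFrame(columns=["term", "m", "n", "M", "N", "p", "q", "significant"])

    N = universe.n_genes
    n = len(de)
    rows = []
    for term, members in sorted(universe.terms.items()):
        M = len(members)
        m = len(de & members)
        p = hypergeom_p(N, n, M, m) if (M > 0 and m > 0) else 1.0
        rows.append({"term": term, "m": m, "n": n, "M": M, "N": N, "p": p})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out["significant"] = out["q"] <= q_max
    return out.sort_values(["p", "term"]).reset_index(drop=True)
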