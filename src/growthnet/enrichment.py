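"""Gene-set over-representation statistics.

For a query gene list against a background universe, each annotation term is
tested with the one-sided Fisher exact test (equivalently the hypergeometric
upper tail).  Alongside the p-value two effect sizes are reported:

* odds ratio, defined from the 2x2 table as (a/(A-a)) / (b/(B-b)) where
  a = list genes carrying the term, A = list size, b = non-list genes carrying
  the term and B = number of non-list background genes;
* fold enrichment, (a/A) / ((a+b)/(A+B)), i.e. the in-list annotation rate
  over the background annotation rate.

Multiple testing is handled with Benjamini-Hochberg step-up FDR adjustment.
An optional EASE-style correction (subtracting one success before computing
the tail) is available for compatibility with DAVID-like tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import log_filter

ANNOTATION_SOURCES = ("GO_BP", "GO_MF", "GO_CC", "KEGG", "UP_KEYWORDS", "OMIM_DISEASE")


@dataclass(frozen=True)
class TermAnnotation:
    """One annotation term (GO/KEGG/keyword/disease) and its gene set."""

    term_id: str
    source: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id!r}: empty gene set")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class EnrichmentResult:
    """2x2-table counts and statistics for one term against one gene list.

    a of A list genes carry the term; b of B non-list background genes do.
    ``odds_ratio`` is ``inf`` when the term covers the whole list (A == a) or
    is absent outside it (b == 0 with B > b), and 0 when a == 0.
    """

    term_id: str
    a: int
    A: int
    b: int
    B: int
    p_raw: float
    odds_ratio: float
    fold_enrichment: float
    fdr: float = field(default=math.nan)


def _odds_ratio(a: int, A: int, b: int, B: int) -> float:
    if a == 0:
        return 0.0
    if A - a == 0 or (b == 0 and B - b > 0):
        return math.inf
    if B - b == 0:  # every non-list gene carries the term: odds (ii) infinite
        return 0.0
    return (a / (A - a)) / (b / (B - b))


def _fold_enrichment(a: int, A: int, b: int, B: int) -> float:
    if a == 0:
        return 0.0
    return (a / A) / ((a + b) / (A + B))


def hypergeom_tail(a: int, A: int, b: int, B: int) -> float:
    """P(X >= a) for X ~ Hypergeom(universe A+B, term size a+b, draws A)."""
    return float(stats.hypergeom.sf(a - 1, A + B, a + b, A))


def term_enrichment(
    gene_list: Iterable[str],
    term: TermAnnotation,
    background: Iterable[str],
    *,
    alternative: str = "greater",
    ease: bool = False,
) -> EnrichmentResult:
    """Test one term for over-representation in ``gene_list``.

    ``gene_list`` must be a subset of ``background``; the term's genes are
    intersected with the background before counting.  ``alternative`` is
    "greater" (one-sided enrichment, the default) or "two-sided".  With
    ``ease=True`` one success is removed before computing the tail (the
    conservative EASE score variant).
    """
    bg = set(background)
    query = set(gene_list)
    if not bg:
        raise ValueError("empty background universe")
    if not query:
        raise ValueError("empty gene list")
    if not query <= bg:
        missing = sorted(query - bg)[:5]
        raise ValueError(f"gene list not contained in background (e.g. {missing})")

    term_genes = term.genes & bg
    a = len(term_genes & query)
    A = len(query)
    b = len(term_genes - query)
    B = len(bg) - A

    a_eff = max(a - 1, 0) if ease else a
    if alternative == "greater":
        p = hypergeom_tail(a_eff, A, b, B) if a_eff > 0 else 1.0
    elif alternative == "two-sided":
        _, p = stats.fisher_exact([[a_eff, A - a_eff], [b, B - b]], alternative="two-sided")
        p = float(p)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return EnrichmentResult(
        term_id=term.term_id,
        a=a,
        A=A,
        b=b,
        B=B,
        p_raw=min(max(p, 0.0), 1.0) or np.nextafter(0, 1),
        odds_ratio=_odds_ratio(a, A, b, B),
        fold_enrichment=_fold_enrichment(a, A, b, B),
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Raises on p-values outside (0, 1]; the adjustment is independent of the
    input permutation (each input keeps its own adjusted value).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_terms(
    gene_list: Iterable[str],
    terms: Sequence[TermAnnotation],
    background: Iterable[str],
    *,
    alternative: str = "greater",
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Run :func:`term_enrichment` for every term and attach BH FDR values."""
    results = [
        term_enrichment(gene_list, t, background, alternative=alternative, ease=ease)
        for t in terms
    ]
    if results:
        adjusted = bh_fdr([r.p_raw for r in results])
        results = [replace(r, fdr=float(q)) for r, q in zip(results, adjusted)]
    return results


def significant_terms(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Terms with FDR <= alpha, sorted by raw p ascending, ties by term id."""
    kept = sorted(
        (r for r in results if r.fdr <= alpha),
        key=lambda r: (r.p_raw, r.term_id),
    )
    log_filter("enrichment.significant_terms", len(results), len(kept))
    return kept
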