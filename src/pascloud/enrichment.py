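"""Pathway prioritization for a gene list by one-sided Fisher's exact test.

Given a list of genes of interest (e.g. genes whose perturbation enhances a
phenotype) and a pathway database, each pathway is tested for
over-representation of list genes against a background universe (by default
the union of all database genes).  The one-sided p-value is the
hypergeometric upper tail P(X >= a) for the observed overlap a; results are
ranked by p with a Benjamini-Hochberg adjustment reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .pathway_model import PathwayDatabase

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_one_sided",
    "odds_ratio",
    "bh_adjust",
    "enrich",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table for one pathway against one gene list.

    a: genes in both the list and the pathway; b: list genes outside the
    pathway; c: pathway genes outside the list; d: background genes in
    neither.  Margins: a+b is the list size, a+c the pathway size within
    the universe, a+b+c+d the universe size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"count {name} must be a non-negative integer")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def list_size(self) -> int:
        return self.a + self.b

    @property
    def pathway_size(self) -> int:
        return self.a + self.c


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided (enrichment/greater) Fisher p: hypergeometric P(X >= a)."""
    # sf(a-1) is the exact upper tail of Hypergeom(N, K, n) at a
    return float(
        hypergeom.sf(t.a - 1, t.universe_size, t.pathway_size, t.list_size)
    )


def odds_ratio(t: ContingencyTable, haldane: bool = False) -> float:
    """Sample cross-product odds ratio (a*d)/(b*c).

    Returns ``inf`` when b*c = 0 with a*d > 0, ``nan`` when both products
    vanish.  ``haldane=True`` adds 0.5 to every cell instead.
    """
    if haldane:
        return ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    if t.b * t.c == 0:
        return math.inf if t.a * t.d > 0 else math.nan
    return (t.a * t.d) / (t.b * t.c)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p_values = list(p_values)
    if not p_values:
        return []
    for p in p_values:
        if not 0 < p <= 1:
            raise ValidationError(f"p-value out of (0, 1]: {p}")
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(q) for q in adjusted]


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's enrichment against the gene list.

    ``overlap_pct`` is 100 * a / (pathway size within the universe).  The
    odds ratio is the sample cross-product; under strong enrichment it
    exceeds 1 (other conventions exist in the literature — see docs).
    """

    pathway_id: str
    overlap_count: int
    overlap_pct: float
    odds_ratio: float
    p_value: float
    p_adjusted: float
    table: ContingencyTable


def enrich(
    gene_list: Iterable[str],
    db: PathwayDatabase,
    universe: Iterable[str] | None = None,
    haldane: bool = False,
) -> list[EnrichmentResult]:
    """Test every pathway for over-representation of ``gene_list`` genes.

    Genes outside the universe are dropped with a warning reporting the
    count.  Results are sorted ascending by p-value, ties by pathway_id;
    the BH adjustment spans all tested pathways.
    """
    uni = frozenset(g.upper() for g in (universe if universe is not None else db.universe))
    genes = {g.upper() for g in gene_list}
    outside = genes - uni
    if outside:
        warnings.warn(
            f"{len(outside)} gene(s) outside the universe dropped from the list",
            stacklevel=2,
        )
    genes &= uni
    if not genes:
        raise ValidationError("gene list empty after restricting to the universe")

    results: list[tuple[str, int, float, float, float, ContingencyTable]] = []
    for p in db:
        members = p.gene_ids & uni
        a = len(genes & members)
        b = len(genes) - a
        c = len(members) - a
        d = len(uni) - a - b - c
        t = ContingencyTable(a=a, b=b, c=c, d=d)
        pct = 100.0 * a / len(members) if members else 0.0
        results.append((p.pathway_id, a, pct, odds_ratio(t, haldane=haldane),
                        fisher_one_sided(t), t))

    adjusted = bh_adjust([r[4] for r in results])
    out = [
        EnrichmentResult(
            pathway_id=pid,
            overlap_count=a,
            overlap_pct=pct,
            odds_ratio=orat,
            p_value=pval,
            p_adjusted=padj,
            table=t,
        )
        for (pid, a, pct, orat, pval, t), padj in zip(results, adjusted)
    ]
    out.sort(key=lambda r: (r.p_value, r.pathway_id))
    return out
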