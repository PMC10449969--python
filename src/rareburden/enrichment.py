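"""Gene-set overrepresentation analysis (ORA) with BH FDR control.

For a gene list of size n drawn against a background universe of size M, a
term of size K overlapping the list in k genes is tested with the two-sided
Fisher exact test on [[k, n-k], [K-k, M-n-K+k]]; direction (over/under) is
the sign of k - nK/M. Two-sided testing keeps under-represented processes
(e.g. depleted immune-response terms) reportable alongside enriched ones; a
one-sided mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .models import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap (list ∩ term)
    n: int  # list size
    K: int  # term size within background
    M: int  # background size
    expected: float  # n*K/M
    direction: str  # "over" | "under"
    fold: float  # k / expected (inf when expected == 0 and k > 0)
    p_value: float
    fdr: float = float("nan")
    significant: bool = False


def bh_adjust(p_values, m_total: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    ``m_total`` may exceed the number of supplied p-values to adjust a
    subset against a larger family of tests (q_i = min_{j>=i} p_(j)*m/j,
    clipped at 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError(f"m_total ({m}) smaller than number of p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    # q >= p holds mathematically (m >= j); guard against 1-ulp rounding
    return np.maximum(out, p)


def ora_fisher(
    gene_list: set[str],
    term_genes: set[str],
    background: set[str],
    alternative: str = "two-sided",
) -> tuple[int, float, str, float, float]:
    """Fisher exact overrepresentation test for one term.

    Returns (k, p, direction, expected, fold). An empty term gives k=0, p=1
    and direction "under" by convention.
    """
    if not background:
        raise ValueError("background universe is empty")
    stray = gene_list - background
    if stray:
        raise ValueError(f"genes in list but not in background: {sorted(stray)[:10]}")
    stray = term_genes - background
    if stray:
        raise ValueError(f"genes in term but not in background: {sorted(stray)[:10]}")

    M, n, K = len(background), len(gene_list), len(term_genes)
    k = len(gene_list & term_genes)
    expected = n * K / M
    direction = "over" if k > expected else "under"
    if K == 0 or n == 0:
        return k, 1.0, direction, expected, 0.0
    table = [[k, n - k], [K - k, M - n - K + k]]
    p = float(fisher_exact(table, alternative=alternative)[1])
    fold = k / expected if expected > 0 else float("inf")
    return k, p, direction, expected, fold


def run_enrichment(
    gene_list: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    m_total: int | None = None,
) -> list[EnrichmentResult]:
    """Test every term in the collection; BH-adjust; sort by p ascending.

    The BH family size defaults to the number of terms tested. Significance
    is FDR < alpha; both directions are reported.
    """
    background = set(collection.background)
    stray = gene_list - background
    if stray:
        raise ValueError(f"genes in list but not in background: {sorted(stray)[:10]}")

    results = []
    for term_id, (name, genes) in collection.terms.items():
        k, p, direction, expected, fold = ora_fisher(
            gene_list, set(genes), background, alternative=alternative
        )
        results.append(
            EnrichmentResult(
                term_id=term_id, term_name=name, k=k, n=len(gene_list),
                K=len(genes), M=len(background), expected=expected,
                direction=direction, fold=fold, p_value=p,
            )
        )
    if not results:
        return []
    fdrs = bh_adjust([r.p_value for r in results], m_total=m_total)
    results = [
        EnrichmentResult(
            **{**r.__dict__, "fdr": float(q), "significant": bool(q < alpha)}
        )
        for r, q in zip(results, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
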