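"""Gene-set over-representation analysis.

Each term in a flat gene-set collection is tested against a gene list with
a one-sided Fisher exact (hypergeometric tail) test and a 1-df Pearson χ²
test on the same 2×2 table. Two corrections are reported side by side:

* a batch-level empirical FDR, ``1 - N_K/T``, where N_K counts terms whose
  Fisher p is strictly smaller than their χ² p among the T tested terms —
  a single value attached to every term in the batch; and
* the standard per-term Benjamini–Hochberg step-up adjustment.

Default significance gates: GO-style namespaces require fisher_p < 0.01 and
batch FDR < 0.05; pathway-style namespaces require fisher_p < 0.05. Both are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "GO": {"p": 0.01, "fdr": 0.05},
    "PATHWAY": {"p": 0.05, "fdr": None},
}


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent 2x2 counts: k={k}, K={K}, n={n}, N={N}")


def fisher_term_test(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation p-value: P(X >= k) for X hypergeometric
    with N total genes, K in the term, n drawn (the gene list)."""
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def chisq_term_test(k: int, K: int, n: int, N: int, correction: bool = False) -> float:
    """1-df Pearson χ² p-value on the 2×2 table (in list / not) × (in term / not).

    No continuity correction by default. A zero margin makes the statistic
    undefined and raises.
    """
    _check_counts(k, K, n, N)
    table = np.array([[k, n - k], [K - k, N - n - (K - k)]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table; chi-square undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(p)


def custom_fdr(fisher_ps: Sequence[float], chisq_ps: Sequence[float]) -> float:
    """Batch-level empirical FDR: 1 - N_K/T with N_K = #{i: fisher_p_i < chisq_p_i}.

    A single value for the whole batch of T paired tests, in {0, 1/T, ..., 1}.
    """
    if len(fisher_ps) == 0:
        raise ValueError("empty p-value lists")
    if len(fisher_ps) != len(chisq_ps):
        raise ValueError("paired p-value lists must have equal length")
    n_k = sum(1 for f, c in zip(fisher_ps, chisq_ps) if f < c)
    return 1.0 - n_k / len(fisher_ps)


def bh_adjust(ps: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(ps, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    out = np.maximum(out, p)  # guard float rounding: adjusted >= raw pointwise
    return out.tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    namespace: str
    k: int  # list genes in term
    K: int  # background genes in term
    n: int  # list size (after background filtering)
    N: int  # background size
    fisher_p: float
    chisq_p: float
    enrichment_ratio: float
    fdr_custom: float
    fdr_bh: float
    significant: bool
    members_in_list: tuple[str, ...] = ()


def run_enrichment(
    genes: Iterable[str],
    sets: GeneSetCollection,
    namespace: str | None = None,
    thresholds: dict | None = None,
) -> list[EnrichmentResult]:
    """Test every term in ``sets`` for over-representation of ``genes``.

    Genes outside the annotation background are dropped (count logged).
    Results are sorted by Fisher p ascending. χ² p defaults to 1 for tables
    with a zero margin (k = K = 0 terms), keeping the custom-FDR pairing total.
    """
    gene_list = set(genes)
    if not gene_list:
        raise ValueError("empty gene list")
    background = sets.background
    dropped = gene_list - set(background)
    if dropped:
        logger.info("dropping %d genes outside the annotation background", len(dropped))
    gene_list &= set(background)
    if not gene_list:
        raise ValueError("no genes remain after background filtering")
    N = len(background)
    n = len(gene_list)
    terms = [t for t in sets.terms if namespace is None or t.namespace == namespace]
    if not terms:
        return []
    rows = []
    for t in terms:
        K = len(t.members)
        hits = tuple(sorted(gene_list & t.members))
        k = len(hits)
        fisher_p = fisher_term_test(k, K, n, N)
        try:
            chisq_p = chisq_term_test(k, K, n, N)
        except ValueError:
            chisq_p = 1.0
        ratio = (k / n) / (K / N) if K > 0 else 0.0
        rows.append((t, k, K, hits, fisher_p, chisq_p, ratio))
    fdr = custom_fdr([r[4] for r in rows], [r[5] for r in rows])
    bh = bh_adjust([r[4] for r in rows])
    results = []
    for (t, k, K, hits, fisher_p, chisq_p, ratio), fdr_bh in zip(rows, bh):
        th = (thresholds or DEFAULT_THRESHOLDS).get(t.namespace, DEFAULT_THRESHOLDS["PATHWAY"])
        sig = fisher_p < th["p"] and (th.get("fdr") is None or fdr < th["fdr"])
        results.append(
            EnrichmentResult(
                t.term_id, t.name, t.namespace, k, K, n, N,
                fisher_p, chisq_p, ratio, fdr, fdr_bh, bool(sig), hits,
            )
        )
    results.sort(key=lambda r: (r.fisher_p, r.term_id))
    return results
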