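"""Gene-act and co-expression network construction and core analysis.

The gene-act network is the subgraph of a typed relation table induced on a
set of differentially expressed genes, with each node carrying its
regulation sign (up/down). The co-expression network links gene pairs whose
expression profiles correlate beyond a near-perfect Pearson threshold
(|r| > 0.999 by default) with a significant two-sided t-test (n − 2 df).

Analysis follows standard graph centrality practice: degree centrality
(links per node, counted once per neighbour pair), k-core decomposition,
and a core-factor ranking by the degree difference of each gene between two
condition-specific networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import RelationTable, ValidationError

MODE_GENE_ACT = "GENE_ACT"
MODE_COEXPRESSION = "COEXPRESSION"


def build_gene_act(
    relations: RelationTable,
    de_genes: Iterable[str],
    signs: Mapping[str, str],
) -> nx.MultiDiGraph:
    """Induce the typed relation graph on the DE gene set.

    Every DE gene becomes a node (isolated if it has no relations) with its
    up/down sign; edges keep kind, directedness and the indirect flag.
    """
    de = set(de_genes)
    missing = de - set(signs)
    if missing:
        raise ValidationError(f"regulation sign missing for genes: {sorted(missing)[:5]}...")
    g = nx.MultiDiGraph(mode=MODE_GENE_ACT)
    for gene in sorted(de):
        g.add_node(gene, sign=signs[gene])
    for row in relations.edges.itertuples(index=False):
        if row.source in de and row.target in de:
            g.add_edge(row.source, row.target, kind=row.kind, directed=bool(row.directed), indirect=bool(row.indirect))
            if not row.directed:
                g.add_edge(row.target, row.source, kind=row.kind, directed=False, indirect=bool(row.indirect))
    g.graph["n_up"] = sum(1 for _, d in g.nodes(data=True) if d["sign"] == "up")
    g.graph["n_down"] = sum(1 for _, d in g.nodes(data=True) if d["sign"] == "down")
    return g


def pearson_p_value(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform with n − 2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def build_coexpression(
    expr: pd.DataFrame,
    r_threshold: float = 0.999,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Undirected network over genes (rows of ``expr``) linking pairs with
    |r| strictly above ``r_threshold`` and correlation-test p below
    ``p_threshold``. Requires at least 3 samples (columns). Zero-variance
    genes cannot form edges."""
    n_samples = expr.shape[1]
    if n_samples < 3:
        raise ValidationError("co-expression needs >= 3 expression columns")
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    g = nx.Graph(mode=MODE_COEXPRESSION)
    genes = list(expr.index)
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    rv = r[iu, ju]
    ok = (sd[iu] > 0) & (sd[ju] > 0) & (np.abs(rv) > r_threshold)
    pv = np.ones_like(rv)
    pv[ok] = pearson_p_value(rv[ok], n_samples)
    ok &= pv < p_threshold
    for i, j, rij in zip(iu[ok], ju[ok], rv[ok]):
        g.add_edge(genes[i], genes[j], weight=float(rij))
    return g


def _simple_undirected(net: nx.Graph) -> nx.Graph:
    u = nx.Graph()
    u.add_nodes_from(net.nodes())
    u.add_edges_from((a, b) for a, b in net.edges() if a != b)
    return u


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Number of links per node: distinct neighbours, direction ignored,
    duplicate edges between a pair counted once."""
    return {n: d for n, d in _simple_undirected(net).degree()}


def k_core(net: nx.Graph) -> dict[str, int]:
    """Core number per node by iterative pruning (self-loops excluded)."""
    return nx.core_number(_simple_undirected(net))


@dataclass(frozen=True)
class CoreResult:
    gene: str
    degree_a: int
    degree_b: int
    degree_difference: int  # degree_a - degree_b
    core_a: int
    core_b: int
    rank: int


def core_factors(net_a: nx.Graph, net_b: nx.Graph) -> list[CoreResult]:
    """Rank genes by |degree in A − degree in B|, descending; ties break by
    gene id. Genes absent from one network count as degree 0 there."""
    deg_a = degree_centrality(net_a)
    deg_b = degree_centrality(net_b)
    core_a = k_core(net_a)
    core_b = k_core(net_b)
    genes = sorted(set(deg_a) | set(deg_b))
    rows = sorted(genes, key=lambda g: (-abs(deg_a.get(g, 0) - deg_b.get(g, 0)), g))
    return [
        CoreResult(
            g,
            deg_a.get(g, 0),
            deg_b.get(g, 0),
            deg_a.get(g, 0) - deg_b.get(g, 0),
            core_a.get(g, 0),
            core_b.get(g, 0),
            rank,
        )
        for rank, g in enumerate(rows, start=1)
    ]


def node_table(net: nx.Graph) -> pd.DataFrame:
    """Per-node summary: sign (if any), degree, core number."""
    deg = degree_centrality(net)
    core = k_core(net)
    rows = [
        {
            "gene": n,
            "sign": net.nodes[n].get("sign", ""),
            "degree": deg[n],
            "core_number": core[n],
        }
        for n in sorted(net.nodes())
    ]
    return pd.DataFrame(rows)


def edge_table(net: nx.Graph) -> pd.DataFrame:
    rows = []
    if net.is_directed():
        for u, v, d in net.edges(data=True):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "kind": d.get("kind", ""),
                    "directed": d.get("directed", True),
                    "indirect": d.get("indirect", False),
                }
            )
    else:
        for u, v, d in net.edges(data=True):
            rows.append({"source": u, "target": v, "r": d.get("weight", float("nan"))})
    return pd.DataFrame(rows)
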