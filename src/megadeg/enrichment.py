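"""Over-representation analysis and the shared-pathway gene–gene network.

A query gene list is tested against each set of a collection with the
one-sided Fisher exact (hypergeometric) test: with background size N, set
size K (within the background), query size n (within the background) and
overlap k, p = P(X ≥ k) for X hypergeometric(N, K, n). P-values across the
collection are adjusted with the Benjamini–Hochberg step-up procedure.

From the sets passing a significance threshold, a gene–gene interaction
network is assembled: two query genes are connected when they co-occur in
the overlap of at least one passing set, and the edge weight counts how many
such sets they share.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet

__all__ = [
    "EnrichmentResult",
    "GGIEdge",
    "fisher_enrichment",
    "bh_fdr",
    "build_ggi",
    "enrichment_to_frame",
    "ggi_to_frame",
    "ggi_to_graph",
    "write_ggi_graphml",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation test.

    k = |overlap|, K = set size within background, n = query size within
    background, N = background size.
    """

    set_id: str
    name: str
    overlap: frozenset[str]
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float


@dataclass(frozen=True)
class GGIEdge:
    """Undirected gene pair sharing ``shared`` >= 1 enriched sets."""

    gene_a: str
    gene_b: str
    shared: int

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValueError("edges must be in canonical order gene_a < gene_b")


def bh_fdr(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q(i) = min over j with p(j) >= p(i) of m·p(j)/rank(j), capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def fisher_enrichment(
    query: set[str],
    collection: list[GeneSet],
    background: set[str] | None = None,
) -> list[EnrichmentResult]:
    """One-sided Fisher exact enrichment of ``query`` in each collection set.

    ``background`` defaults to the union of all collection members and the
    query. Sets are intersected with the background before testing. Results
    come back sorted by p ascending, ties broken by set id, with BH q-values
    computed across the collection.
    """
    query = set(query)
    if background is None:
        background = set().union(*(s.members for s in collection)) if collection else set()
        background |= query
    else:
        background = set(background)
        if not query <= background:
            raise ValueError("query must be a subset of the background")
    if not background:
        raise ValueError("background universe is empty")
    N = len(background)
    q_in_bg = query & background
    n = len(q_in_bg)

    prelim = []
    for s in collection:
        members = s.members & background
        K = len(members)
        overlap = frozenset(q_in_bg & members)
        k = len(overlap)
        # P(X >= k), hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        prelim.append((s, overlap, k, K, p))

    qvals = bh_fdr([max(t[4], np.nextafter(0, 1)) for t in prelim]) if prelim else []
    results = [
        EnrichmentResult(s.set_id, s.name, overlap, k, K, n, N, p, q)
        for (s, overlap, k, K, p), q in zip(prelim, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_id))
    return results


def build_ggi(
    results: list[EnrichmentResult],
    threshold: float = 0.001,
    use: str = "p",
) -> list[GGIEdge]:
    """Shared-pathway gene–gene edges from enrichment results.

    Among sets with ``p`` (or ``q``) below ``threshold``, every unordered
    pair of genes co-occurring in a set's overlap gets an edge whose weight
    counts the number of such sets. Deterministic: edges sorted by gene pair.
    """
    if use not in ("p", "q"):
        raise ValueError("use must be 'p' or 'q'")
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        if (r.p if use == "p" else r.q) >= threshold:
            continue
        for a, b in combinations(sorted(r.overlap), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return [GGIEdge(a, b, c) for (a, b), c in sorted(counts.items())]


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "overlap": ";".join(sorted(r.overlap)),
            }
            for r in results
        ],
        columns=["set_id", "name", "k", "K", "n", "N", "p", "q", "overlap"],
    )


def ggi_to_frame(edges: list[GGIEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_a": e.gene_a, "gene_b": e.gene_b, "shared": e.shared} for e in edges],
        columns=["gene_a", "gene_b", "shared"],
    )


def ggi_to_graph(edges: list[GGIEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, shared=e.shared)
    return g


def write_ggi_graphml(edges: list[GGIEdge], path) -> None:
    nx.write_graphml(ggi_to_graph(edges), path)
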