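"""Functional-module enrichment on protein-protein interaction networks.

For genes that turn out not to be expressed in the tissue of interest, the
question becomes *what do these genes do*.  The study set is first extended
with its first-degree interaction partners (which increases the power of
module detection), then every GO term is tested for over-representation in
two complementary ways:

conventional
    a hypergeometric test counted in genes -- how many genes of the
    extended study set carry the term, against how many genes of the
    universe do;
network-wise
    a hypergeometric test counted in *functional edges* -- interactions
    whose two endpoints share the term.  Draws are the edges of the
    subgraph induced by the term's module genes inside the extended study
    set; successes in the population are all functional edges for the term
    in the whole network.

Raw p-values of each family are Benjamini-Hochberg adjusted separately,
and a module is called significant when (1) adjusted conventional p < 0.05,
(2) adjusted network-wise p < 0.05, and (3) it contains at least one of the
original study genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "PpiNetwork",
    "EnrichmentModule",
    "extend_study_set",
    "hypergeom_tail_p",
    "conventional_enrichment",
    "networkwise_enrichment",
    "bh_adjust",
    "call_modules",
    "enrich_modules",
]


class PpiNetwork:
    """Simple undirected PPI graph: no self-loops, no duplicate edges."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on {a!r} not allowed in a PpiNetwork")
            g.add_edge(a, b)
        self._g = g

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (a, b) tuples with a < b."""
        return [tuple(sorted(e)) for e in self._g.edges]

    def has_node(self, gene: str) -> bool:
        return self._g.has_node(gene)

    def neighbors(self, gene: str) -> set[str]:
        if not self._g.has_node(gene):
            return set()
        return set(self._g.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self._g.degree(gene) if self._g.has_node(gene) else 0

    def induced_edges(self, genes: Iterable[str]) -> list[tuple[str, str]]:
        sub = self._g.subgraph([g for g in genes if self._g.has_node(g)])
        return [tuple(sorted(e)) for e in sub.edges]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PpiNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass(frozen=True)
class EnrichmentModule:
    """One GO term with both enrichment p-values and the significance call."""

    term: str
    module_genes: tuple[str, ...]
    n_study_genes: int
    conventional_p: float
    networkwise_p: float
    conventional_adj: float
    networkwise_adj: float
    significant: bool


def extend_study_set(study: GeneSet, net: PpiNetwork) -> GeneSet:
    """Study genes plus all their first-degree PPI partners.

    Study genes absent from the network contribute no partners but are
    retained in the extended set.
    """
    extended: dict[str, None] = {g: None for g in study.genes}
    for g in study.genes:
        for nb in sorted(net.neighbors(g)):
            extended.setdefault(nb, None)
    return GeneSet(name=f"{study.name}+partners", genes=tuple(extended))


def hypergeom_tail_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    ``N`` genes (or edges) in the population, ``K`` of them successes,
    ``n`` drawn, ``k`` successes among the drawn.  Computed with exact
    integer arithmetic and converted to float at the end.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)):
            raise TypeError(f"{name} must be an integer, got {v!r}")
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent population: N={N}, K={K}, n={n}")
    lo, hi = max(0, n + K - N), min(K, n)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside the feasible range [{lo}, {hi}]")
    numer = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
    return float(Fraction(numer, math.comb(N, n)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def _annotated_with(annotations: Mapping[str, Iterable[str]], term: str, genes) -> set[str]:
    return {g for g in genes if term in annotations.get(g, ())}


def _all_terms(annotations: Mapping[str, Iterable[str]]) -> list[str]:
    terms: set[str] = set()
    for ts in annotations.values():
        terms.update(ts)
    return sorted(terms)


def conventional_enrichment(
    extended: GeneSet,
    annotations: Mapping[str, Iterable[str]],
    net: PpiNetwork | None = None,
    universe: GeneSet | None = None,
    min_term_genes: int = 2,
) -> pd.DataFrame:
    """Gene-counted hypergeometric enrichment, one row per tested term.

    The universe defaults to all annotated genes present in the network
    (pass ``universe`` to override, or ``net=None`` to use all annotated
    genes).  Terms annotating fewer than ``min_term_genes`` universe genes
    are skipped.  Returns a DataFrame indexed by term with columns
    ``K`` (universe genes with the term), ``k`` (extended genes with the
    term), ``n``, ``N`` and the raw ``p``.
    """
    if universe is not None:
        uni = set(universe.genes)
    else:
        annotated = {g for g, ts in annotations.items() if ts}
        uni = annotated & net.nodes() if net is not None else annotated
    if not uni:
        raise ValueError("empty universe: no annotated genes to test against")
    drawn = extended.as_set() & uni
    N, n = len(uni), len(drawn)
    rows = {}
    for term in _all_terms(annotations):
        term_genes = _annotated_with(annotations, term, uni)
        K = len(term_genes)
        if K < min_term_genes:
            logger.debug("skipping term %s: only %d universe genes", term, K)
            continue
        k = len(term_genes & drawn)
        rows[term] = {"K": K, "k": k, "n": n, "N": N, "p": hypergeom_tail_p(k, K, n, N)}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float).rename_axis("term")


def networkwise_enrichment(
    extended: GeneSet,
    net: PpiNetwork,
    annotations: Mapping[str, Iterable[str]],
    min_functional_edges: int = 1,
    draws: str = "induced",
) -> pd.DataFrame:
    """Edge-counted hypergeometric enrichment over functional PPIs.

    A functional edge for a term joins two genes that both carry the term.
    Population: all network edges (``N``); population successes: all
    functional edges for the term (``K``); draws: edges of the subgraph
    induced by the term's module genes within the extended study set
    (``n``; with ``draws="incident"`` instead all edges touching a module
    gene); drawn successes: functional edges among the draws (``k``).
    Terms with fewer than ``min_functional_edges`` functional edges in the
    whole network are skipped.
    """
    if draws not in ("induced", "incident"):
        raise ValueError(f"draws must be 'induced' or 'incident', got {draws!r}")
    N = net.n_edges
    if N == 0:
        raise ValueError("network has no edges")
    all_edges = net.edges()
    ext = extended.as_set()
    rows = {}
    for term in _all_terms(annotations):
        functional = [
            e
            for e in all_edges
            if term in annotations.get(e[0], ()) and term in annotations.get(e[1], ())
        ]
        K = len(functional)
        if K < min_functional_edges:
            logger.debug("skipping term %s: %d functional edges in network", term, K)
            continue
        module = _annotated_with(annotations, term, ext)
        if draws == "induced":
            drawn = net.induced_edges(module)
        else:
            drawn = [e for e in all_edges if e[0] in module or e[1] in module]
        n = len(drawn)
        k = sum(
            1
            for e in drawn
            if term in annotations.get(e[0], ()) and term in annotations.get(e[1], ())
        )
        rows[term] = {"K": K, "k": k, "n": n, "N": N, "p": hypergeom_tail_p(k, K, n, N)}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float).rename_axis("term")


def call_modules(
    conventional: pd.DataFrame,
    networkwise: pd.DataFrame,
    study: GeneSet,
    annotations: Mapping[str, Iterable[str]],
    extended: GeneSet,
    alpha: float = 0.05,
) -> list[EnrichmentModule]:
    """Combine both families into per-term modules with a significance call.

    BH adjustment is applied within each family over all of its tested
    terms; only terms tested in both families yield a module.  A module is
    significant iff both adjusted p-values are < ``alpha`` and it contains
    at least one original study gene.
    """
    conv_adj = pd.Series(bh_adjust(conventional["p"].to_numpy()), index=conventional.index)
    net_adj = pd.Series(bh_adjust(networkwise["p"].to_numpy()), index=networkwise.index)
    terms = sorted(set(conventional.index) & set(networkwise.index))
    ext = extended.as_set()
    study_set = study.as_set()
    modules = []
    for term in terms:
        module_genes = tuple(sorted(_annotated_with(annotations, term, ext)))
        n_study = len(study_set & set(module_genes))
        c_adj = float(conv_adj[term])
        w_adj = float(net_adj[term])
        modules.append(
            EnrichmentModule(
                term=term,
                module_genes=module_genes,
                n_study_genes=n_study,
                conventional_p=float(conventional.loc[term, "p"]),
                networkwise_p=float(networkwise.loc[term, "p"]),
                conventional_adj=c_adj,
                networkwise_adj=w_adj,
                significant=bool(c_adj < alpha and w_adj < alpha and n_study >= 1),
            )
        )
    return modules


def enrich_modules(
    study: GeneSet,
    net: PpiNetwork,
    annotations: Mapping[str, Iterable[str]],
    universe: GeneSet | None = None,
    alpha: float = 0.05,
    min_term_genes: int = 2,
    min_functional_edges: int = 1,
    draws: str = "induced",
) -> list[EnrichmentModule]:
    """Full pipeline: extend the study set, test both families, call modules."""
    extended = extend_study_set(study, net)
    conv = conventional_enrichment(
        extended, annotations, net=net, universe=universe, min_term_genes=min_term_genes
    )
    nw = networkwise_enrichment(
        extended, net, annotations, min_functional_edges=min_functional_edges, draws=draws
    )
    return call_modules(conv, nw, study, annotations, extended, alpha=alpha)
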