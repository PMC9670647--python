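"""Unsupervised dense-subgraph mining: paracliques via glom terms.

The unsupervised arm builds an unweighted graph over all variables (PRM
outcome included) by thresholding the |r| matrix at each of several
levels, then repeatedly extracts *paracliques*: an exact maximum clique
(the seed) augmented with every outside vertex adjacent to at least
|seed| − g seed members, where g is the *glom term*. Each paraclique's
members are removed before the next extraction, so paracliques are
pairwise vertex-disjoint. A paraclique is retained for interpretation when
it contains at least one PRM ratio vertex.

The maximum clique is computed by deterministic branch-and-bound with a
greedy-colouring upper bound (lexicographic vertex order), so outputs are
reproducible and exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import CorrelationGraph, DataModelError

logger = logging.getLogger("exposcreen")

DEFAULT_THRESHOLDS = (0.15, 0.2, 0.3, 0.5, 0.7, 0.8)
DEFAULT_GLOM_TERMS = (1, 2, 3)
DEFAULT_MIN_CLIQUE = 3
DEFAULT_NODE_BUDGET = 5_000_000


class CliqueBudgetExceeded(RuntimeError):
    """Branch-and-bound node budget exhausted; advise a higher threshold."""


def threshold_graph(cor_matrix: pd.DataFrame, t: float) -> CorrelationGraph:
    """Unweighted simple graph with an edge wherever |r| ≥ t (inclusive)."""
    if not 0.0 < t < 1.0:
        raise DataModelError(f"threshold must lie in (0,1), got {t}")
    r = cor_matrix.to_numpy(dtype=float)
    names = list(cor_matrix.columns)
    g = nx.Graph()
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(len(names), k=1)
    hit = ~np.isnan(r[iu, ju]) & (np.abs(r[iu, ju]) >= t - 1e-12)
    arr = np.asarray(names, dtype=object)
    for a, b, w in zip(arr[iu[hit]], arr[ju[hit]], r[iu[hit], ju[hit]]):
        g.add_edge(a, b, weight=float(w))
    return CorrelationGraph(g, threshold=t, threshold_mode="absolute")


# -- exact maximum clique ----------------------------------------------------


def maximum_clique(graph: CorrelationGraph | nx.Graph,
                   node_budget: int = DEFAULT_NODE_BUDGET) -> set[str]:
    """Exact maximum clique, deterministic.

    Branch-and-bound with a greedy-colouring upper bound: candidates are
    coloured greedily in lexicographic order; a branch is pruned when
    |current clique| + colour bound cannot beat the incumbent. Vertices are
    expanded in a fixed order, so ties resolve identically on every run
    (an edgeless graph returns its lexicographically first vertex).
    """
    g = graph.graph if isinstance(graph, CorrelationGraph) else graph
    nodes = sorted(g.nodes)
    if not nodes:
        return set()
    adj = {v: set(g.neighbors(v)) for v in nodes}
    best: list = [nodes[0]]
    expansions = 0

    def color_sort(candidates: list) -> tuple[list, list[int]]:
        # greedy colouring in lexicographic order; returns candidates
        # ordered by (colour, name) with each vertex's colour number
        color_classes: list[list] = []
        for v in candidates:
            for cls in color_classes:
                if not adj[v] & set(cls):
                    cls.append(v)
                    break
            else:
                color_classes.append([v])
        ordered, bounds = [], []
        for ci, cls in enumerate(color_classes, start=1):
            for v in cls:
                ordered.append(v)
                bounds.append(ci)
        return ordered, bounds

    def expand(clique: list, candidates: list) -> None:
        nonlocal best, expansions
        expansions += 1
        if expansions > node_budget:
            raise CliqueBudgetExceeded(
                f"maximum_clique exceeded its search budget "
                f"({node_budget} nodes); try a higher correlation threshold"
            )
        ordered, bounds = color_sort(candidates)
        for i in range(len(ordered) - 1, -1, -1):
            if len(clique) + bounds[i] <= len(best):
                return
            v = ordered[i]
            new_cands = [u for u in ordered[:i] if u in adj[v]]
            clique.append(v)
            if len(clique) > len(best):
                best = clique.copy()
            if new_cands:
                expand(clique, new_cands)
            clique.pop()

    expand([], nodes)
    return set(best)


# -- paracliques -------------------------------------------------------------


@dataclass
class Paraclique:
    """A seed maximum clique plus glommed vertices, with provenance."""

    seed_clique: set[str]
    glommed: set[str]
    glom_term: int
    threshold: float
    density: float

    @property
    def members(self) -> set[str]:
        return self.seed_clique | self.glommed

    def density_lower_bound(self) -> float:
        """Guaranteed density [C(s,2) + m·(s−g)] / C(s+m,2)."""
        s, m, g = len(self.seed_clique), len(self.glommed), self.glom_term
        if s + m < 2:
            return 1.0
        return (comb(s, 2) + m * (s - g)) / comb(s + m, 2)

    def manifest(self) -> str:
        lines = [
            f"# paraclique threshold={self.threshold} glom={self.glom_term} "
            f"density={self.density:.6f}",
            "[seed]",
            *sorted(self.seed_clique),
            "[glommed]",
            *sorted(self.glommed),
        ]
        return "\n".join(lines) + "\n"


def _density(g: nx.Graph, members: set) -> float:
    k = len(members)
    if k < 2:
        return 1.0
    edges = g.subgraph(members).number_of_edges()
    return edges / comb(k, 2)


def glom(graph: CorrelationGraph | nx.Graph, seed_clique: set,
         g_term: int, iterate: bool = False) -> Paraclique:
    """Augment a seed clique with vertices missing at most g seed adjacencies.

    One-pass rule (default): a vertex outside the seed joins when it is
    adjacent to at least |seed| − g members *of the seed* — candidates are
    never evaluated against previously glommed vertices, which preserves
    the closed-form density guarantee. ``iterate=True`` switches to the
    variant that re-runs the pass against the growing member set until a
    fixed point (no density guarantee; provided for comparison).
    """
    g = graph.graph if isinstance(graph, CorrelationGraph) else graph
    seed = set(seed_clique)
    thr = graph.threshold if isinstance(graph, CorrelationGraph) else float("nan")
    if g_term < 0:
        raise DataModelError("glom term must be non-negative")
    if g_term >= len(seed):
        raise DataModelError(
            f"glom term {g_term} must be smaller than the seed clique "
            f"size {len(seed)} (otherwise every vertex would join)"
        )
    for v in seed:
        if not seed - {v} <= set(g.neighbors(v)):
            raise DataModelError("seed is not a clique")
    need = len(seed) - g_term
    glommed = {
        v for v in g.nodes
        if v not in seed and len(set(g.neighbors(v)) & seed) >= need
    }
    if iterate:
        members = seed | glommed
        while True:
            extra = {
                v for v in g.nodes
                if v not in members
                and len(set(g.neighbors(v)) & members) >= len(members) - g_term
            }
            if not extra:
                break
            members |= extra
        glommed = members - seed
    return Paraclique(
        seed_clique=seed,
        glommed=glommed,
        glom_term=g_term,
        threshold=thr,
        density=_density(g, seed | glommed),
    )


def extract_all(
    graph: CorrelationGraph,
    g_term: int,
    min_clique: int = DEFAULT_MIN_CLIQUE,
    outcome_vertices: set[str] | None = None,
    require_outcome_vertex: bool = True,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> list[Paraclique]:
    """Iteratively extract vertex-disjoint paracliques.

    Loop: find the maximum clique; stop when its size drops below
    ``min_clique``; glom; record; delete the paraclique's members; repeat.
    When ``require_outcome_vertex`` the returned list keeps only
    paracliques containing at least one outcome vertex.
    """
    outcome_vertices = outcome_vertices or set()
    work = graph.graph.copy()
    found: list[Paraclique] = []
    while work.number_of_nodes() > 0:
        seed = maximum_clique(work, node_budget=node_budget)
        if len(seed) < min_clique:
            break
        wrapped = CorrelationGraph(work, threshold=graph.threshold,
                                   threshold_mode=graph.threshold_mode,
                                   min_pairs=graph.min_pairs)
        pc = glom(wrapped, seed, min(g_term, len(seed) - 1))
        found.append(pc)
        work.remove_nodes_from(pc.members)
    if require_outcome_vertex:
        retained = [p for p in found if p.members & outcome_vertices]
        logger.info(
            "paraclique extraction (t=%.2f, g=%d): %d found, %d retained "
            "with an outcome vertex", graph.threshold, g_term,
            len(found), len(retained),
        )
        return retained
    return found
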