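"""Bayesian-network structure learning with the Gaussian BIC score.

Each node is modelled as a linear-Gaussian function of its parents; the
network score is the sum over nodes of the local penalised log-likelihood

    local BIC(child | parents) = logLik − (p/2)·ln N,

with logLik = −(N/2)(ln 2πσ̂² + 1), σ̂² the maximum-likelihood residual
variance, and p = |parents| + 2 free parameters (slopes + intercept +
variance). We *maximise* this score; it is the negative half of the
common −2·logLik + p·ln N convention, so maximising it is exactly the
"minimal BIC" search. The score is decomposable, which lets greedy
hill-climbing (single arc additions, deletions, reversals, steepest
ascent from the empty DAG) evaluate moves by rescoring only the affected
children. Variables are continuous rates/percentages; no discretization
is applied.

The outcome node's parents in the learned DAG are its *direct
predictors*; ancestors and the Markov blanket are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log, pi

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import DataModelError, LearnedDAG
from .screening import ScreenResult, domain_sublists, top_k

logger = logging.getLogger("exposcreen")

VARIANCE_FLOOR = 1e-12
DEFAULT_MAX_ITER = 10_000
_GAIN_TOL = 1e-9


def local_bic(child: str, parent_set: tuple[str, ...] | list[str],
              data: pd.DataFrame) -> float:
    """Gaussian BIC contribution of one node given its parents.

    Requires complete-case rows (the caller drops missing rows once per
    network) and a non-constant child. Rank-deficient parent matrices are
    rejected naming the collinear parents.
    """
    parents = sorted(parent_set)
    y = data[child].to_numpy(dtype=float)
    n = y.size
    if n < len(parents) + 2:
        raise DataModelError(
            f"{child}: {n} rows is too few for {len(parents)} parents"
        )
    if np.ptp(y) == 0:
        raise DataModelError(f"child {child!r} is constant")
    if parents:
        X = np.column_stack(
            [np.ones(n)] + [data[p].to_numpy(dtype=float) for p in parents]
        )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise DataModelError(
                f"{child}: collinear parent set {parents}"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    else:
        resid = y - y.mean()
    sigma2 = max(float(resid @ resid) / n, VARIANCE_FLOOR)
    loglik = -0.5 * n * (log(2 * pi * sigma2) + 1.0)
    p = len(parents) + 2
    return loglik - 0.5 * p * log(n)


class _ScoreCache:
    def __init__(self, data: pd.DataFrame):
        self.data = data
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def __call__(self, child: str, parents: frozenset) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            try:
                self._cache[key] = local_bic(child, key[1], self.data)
            except DataModelError:
                self._cache[key] = -np.inf  # collinear/underdetermined move
        return self._cache[key]


_MOVE_RANK = {"add": 0, "delete": 1, "reverse": 2}


def hill_climb(data: pd.DataFrame, node_set: list[str] | None = None,
               max_iter: int = DEFAULT_MAX_ITER) -> LearnedDAG:
    """Greedy steepest-ascent search for the maximum-BIC DAG.

    Starts from the empty DAG and repeatedly applies the single arc
    addition, deletion, or reversal that most improves the total score
    subject to acyclicity, stopping at a local optimum (or ``max_iter``).
    Equal-gain moves break lexicographically on (move type: add < delete <
    reverse, parent, child), so the result is deterministic.
    """
    nodes = sorted(node_set) if node_set is not None else sorted(data.columns)
    df = data[nodes].dropna()
    if df.shape[0] < len(nodes) + 2:
        raise DataModelError(
            f"only {df.shape[0]} complete rows for {len(nodes)} nodes"
        )
    score = _ScoreCache(df)
    dag = nx.DiGraph()
    dag.add_nodes_from(nodes)
    local = {v: score(v, frozenset()) for v in nodes}

    def parent_set(v: str) -> frozenset:
        return frozenset(dag.predecessors(v))

    for _ in range(max_iter):
        best_gain, best_key, best_apply = _GAIN_TOL, None, None
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                pv = parent_set(v)
                if dag.has_edge(u, v):
                    # delete u→v
                    gain = score(v, pv - {u}) - local[v]
                    key = (_MOVE_RANK["delete"], u, v)
                    if _better(gain, key, best_gain, best_key):
                        best_gain, best_key = gain, key
                        best_apply = ("delete", u, v)
                    # reverse u→v (acyclic iff no other path u→v remains)
                    if not _path_avoiding_edge(dag, u, v):
                        pu = parent_set(u)
                        gain = (score(v, pv - {u}) - local[v]
                                + score(u, pu | {v}) - local[u])
                        key = (_MOVE_RANK["reverse"], u, v)
                        if _better(gain, key, best_gain, best_key):
                            best_gain, best_key = gain, key
                            best_apply = ("reverse", u, v)
                elif not dag.has_edge(v, u):
                    # add u→v unless it closes a cycle
                    if nx.has_path(dag, v, u):
                        continue
                    gain = score(v, pv | {u}) - local[v]
                    key = (_MOVE_RANK["add"], u, v)
                    if _better(gain, key, best_gain, best_key):
                        best_gain, best_key = gain, key
                        best_apply = ("add", u, v)
        if best_apply is None:
            break
        kind, u, v = best_apply
        if kind == "add":
            dag.add_edge(u, v)
        elif kind == "delete":
            dag.remove_edge(u, v)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)
            local[u] = score(u, parent_set(u))
        local[v] = score(v, parent_set(v))
    per_node = {v: score(v, parent_set(v)) for v in nodes}
    return LearnedDAG(
        nodes=nodes,
        arcs=sorted(dag.edges),
        score_total=float(sum(per_node.values())),
        per_node_score=per_node,
        n_rows=df.shape[0],
    )


def _better(gain: float, key: tuple, best_gain: float,
            best_key: tuple | None) -> bool:
    if gain > best_gain + _GAIN_TOL:
        return True
    if best_key is not None and abs(gain - best_gain) <= _GAIN_TOL:
        return key < best_key
    return False


def _path_avoiding_edge(dag: nx.DiGraph, u: str, v: str) -> bool:
    """True if a directed path u→v exists other than the edge (u, v) itself."""
    dag.remove_edge(u, v)
    try:
        return nx.has_path(dag, u, v)
    finally:
        dag.add_edge(u, v)


def total_score(dag: LearnedDAG, data: pd.DataFrame) -> float:
    """Recompute the network BIC from scratch (decomposability check)."""
    df = data[dag.nodes].dropna()
    return float(sum(local_bic(v, dag.parents(v), df) for v in dag.nodes))


def is_local_optimum(dag: LearnedDAG, data: pd.DataFrame,
                     tol: float = 1e-6) -> bool:
    """Certificate: no single add/delete/reverse move improves the score.

    Re-checked independently of the search bookkeeping.
    """
    df = data[dag.nodes].dropna()
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.arcs)

    def sc(child, parents):
        try:
            return local_bic(child, parents, df)
        except DataModelError:
            return -np.inf

    base = {v: sc(v, dag.parents(v)) for v in dag.nodes}
    for u in dag.nodes:
        for v in dag.nodes:
            if u == v:
                continue
            pv = set(g.predecessors(v))
            if g.has_edge(u, v):
                if sc(v, pv - {u}) - base[v] > tol:
                    return False
                if not _path_avoiding_edge(g, u, v):
                    gain = (sc(v, pv - {u}) - base[v]
                            + sc(u, set(g.predecessors(u)) | {v}) - base[u])
                    if gain > tol:
                        return False
            elif not g.has_edge(v, u) and not nx.has_path(g, v, u):
                if sc(v, pv | {u}) - base[v] > tol:
                    return False
    return True


def learn_outcome_network(data: pd.DataFrame, variables: list[str],
                          outcome: str) -> LearnedDAG:
    """Hill-climb over ``variables + outcome`` and mark the outcome node."""
    nodes = sorted(set(variables) | {outcome})
    dag = hill_climb(data, nodes)
    dag.outcome = outcome
    return dag


def direct_predictors(dag: LearnedDAG, outcome: str) -> list[str]:
    """Parents of the outcome node, sorted by name."""
    if outcome not in dag.nodes:
        raise DataModelError(f"outcome {outcome!r} not in learned network")
    return dag.parents(outcome)


def run_per_domain(
    data: pd.DataFrame,
    screen_result: ScreenResult,
    outcome: str,
    k: int = 20,
) -> dict[str, LearnedDAG]:
    """One network per exposome domain plus an ``overall`` network.

    Each network is learned on that domain's top-k screened correlates
    plus the outcome node; the overall network uses the combined top-k
    list. Domains with no retained variables are skipped with a log line.
    """
    networks: dict[str, LearnedDAG] = {}
    sublists = domain_sublists(screen_result)
    for domain, sub in sublists.items():
        vars_d = [v for v in top_k(sub, k) if v != outcome]
        if not vars_d:
            logger.info("run_per_domain: domain %r has no variables; skipped",
                        domain)
            continue
        networks[domain] = learn_outcome_network(data, vars_d, outcome)
    vars_all = [v for v in top_k(screen_result, k) if v != outcome]
    if vars_all:
        networks["overall"] = learn_outcome_network(data, vars_all, outcome)
    return networks
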