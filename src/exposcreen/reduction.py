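"""Variable reduction: autocorrelation graph + minimum dominating set.

Exposome repositories carry many repeated and collinear measures. The
reduction stage treats two variables as informationally redundant
("autocorrelates") when their Pearson correlation meets a high threshold
(default r ≥ 0.9), builds a simple undirected graph with an edge per
autocorrelate pair, and keeps only an exact minimum dominating set of that
graph — the smallest variable set such that every variable is either kept
or redundant with a kept one. Confidence-limit and margin-of-error
variables are then removed by name pattern.

Pearson is justified beforehand by a Shapiro–Wilk normality screen with
Benjamini–Hochberg false-discovery-rate adjustment across variables; the
screen is logged and (by default) informational — the pipeline proceeds
with Pearson regardless, with an optional Spearman fallback available.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse
import scipy.stats

from .data_model import CorrelationGraph, DataModelError, ExposomeTable

logger = logging.getLogger("exposcreen")

DEFAULT_AUTOCORR_THRESHOLD = 0.9
DEFAULT_MIN_PAIRS = 30

#: Case-insensitive substrings identifying confidence-limit / margin-of-error
#: variables. Configurable because repositories differ in naming conventions.
DEFAULT_NAME_PATTERNS = (
    "margin of error",
    "moe",
    "confidence limit",
    "confidence interval",
    "95% ci",
    "lower bound",
    "upper bound",
)


# -- correlation primitives --------------------------------------------------


def pearson(x: np.ndarray, y: np.ndarray,
            min_pairs: int = 2) -> float | None:
    """Pearson product-moment correlation over pairwise-complete entries.

    Returns ``None`` when fewer than ``min_pairs`` complete pairs exist or
    either variable is constant on the complete pairs. Pipeline callers
    pass ``min_pairs=30``-style floors; the bare default is the
    statistical minimum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataModelError(
            f"length mismatch: {x.shape[0]} vs {y.shape[0]}"
        )
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < max(min_pairs, 2):
        return None
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom <= 0:
        return None
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_matrix(values: pd.DataFrame,
                       min_pairs: int = DEFAULT_MIN_PAIRS) -> pd.DataFrame:
    """All-pairs pairwise-complete Pearson correlations, NaN where undefined.

    Vectorised via the masked-moment identities so the cost is a handful of
    dense matrix products rather than a Python loop over pairs.
    """
    X = values.to_numpy(dtype=float)
    M = (~np.isnan(X)).astype(float)
    Xz = np.where(np.isnan(X), 0.0, X)
    n_ij = M.T @ M
    s_x = Xz.T @ M          # Σ x over pairwise-complete rows
    s_y = s_x.T
    s_xx = (Xz * Xz).T @ M
    s_yy = s_xx.T
    s_xy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_xy - s_x * s_y / n_ij
        var_x = s_xx - s_x ** 2 / n_ij
        var_y = s_yy - s_y ** 2 / n_ij
        r = cov / np.sqrt(var_x * var_y)
    # degenerate pairs: too few observations or (near-)constant margins
    tiny = 1e-12
    bad = (n_ij < max(min_pairs, 2)) | (var_x <= tiny) | (var_y <= tiny)
    r[bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    cols = list(values.columns)
    return pd.DataFrame(r, index=cols, columns=cols)


# -- normality screen --------------------------------------------------------


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up false-discovery-rate adjusted p-values.

    Sort ascending; adjusted p_(i) = min over j ≥ i of p_(j)·m/j, capped at
    1; mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataModelError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass
class NormalityScreen:
    """Per-variable Shapiro–Wilk p-values and BH-adjusted non-normality flags."""

    pvalues: pd.Series            # raw Shapiro–Wilk p per variable
    adjusted: pd.Series           # BH-adjusted p
    flagged: pd.Series            # True ⇔ adjusted p < alpha (non-normal)
    unevaluable: list[str]        # variables with < 3 non-missing values
    alpha: float


def shapiro_wilk_screen(table: ExposomeTable,
                        alpha: float = 0.05) -> NormalityScreen:
    """Shapiro–Wilk per variable, BH-adjusted across all evaluable variables.

    Variables with fewer than 3 non-missing values are reported as
    unevaluable rather than failing the run.
    """
    raw: dict[str, float] = {}
    unevaluable: list[str] = []
    for name in table.variables:
        v = table.values[name].dropna().to_numpy()
        if v.size < 3 or np.ptp(v) == 0:
            unevaluable.append(name)
            continue
        # scipy warns above N=5000; p-value remains usable for screening
        raw[name] = float(scipy.stats.shapiro(v).pvalue)
    names = list(raw)
    pv = pd.Series([raw[n] for n in names], index=names, dtype=float)
    adj = pd.Series(benjamini_hochberg(pv.to_numpy()), index=names)
    flagged = adj < alpha
    if flagged.any():
        logger.info(
            "normality screen: %d/%d variables flagged non-normal at "
            "BH-adjusted alpha=%g", int(flagged.sum()), len(names), alpha,
        )
    return NormalityScreen(pv, adj, flagged, unevaluable, alpha)


# -- autocorrelation graph ---------------------------------------------------


def build_autocorrelation_graph(
    table: ExposomeTable,
    threshold: float = DEFAULT_AUTOCORR_THRESHOLD,
    threshold_mode: str = "signed",
    min_pairs: int = DEFAULT_MIN_PAIRS,
    corr: pd.DataFrame | None = None,
) -> CorrelationGraph:
    """Graph with a vertex per variable and edges between autocorrelates.

    An edge joins (u, v) when r ≥ threshold (``signed`` mode, the default —
    "at least 0.9" read literally) or |r| ≥ threshold (``absolute`` mode).
    The boundary is inclusive. Every variable is a vertex even if isolated.
    """
    if len(table.variables) < 2:
        raise DataModelError("need at least 2 variables to build a graph")
    if corr is None:
        corr = correlation_matrix(table.values, min_pairs=min_pairs)
    r = corr.to_numpy()
    stat = np.abs(r) if threshold_mode == "absolute" else r
    iu, ju = np.triu_indices(r.shape[0], k=1)
    # inclusive boundary with a 1e-12 slack so exact-threshold pairs are
    # not dropped by floating-point rounding
    hit = ~np.isnan(stat[iu, ju]) & (stat[iu, ju] >= threshold - 1e-12)
    g = nx.Graph()
    g.add_nodes_from(table.variables)
    names = np.asarray(table.variables, dtype=object)
    for a, b in zip(names[iu[hit]], names[ju[hit]]):
        g.add_edge(a, b, weight=float(corr.loc[a, b]))
    return CorrelationGraph(g, threshold=threshold,
                            threshold_mode=threshold_mode, min_pairs=min_pairs)


# -- minimum dominating set --------------------------------------------------


def is_dominating_set(graph: nx.Graph, subset: set) -> bool:
    """Certificate check: every vertex is in ``subset`` or adjacent to it."""
    return all(
        v in subset or any(u in subset for u in graph.neighbors(v))
        for v in graph.nodes
    )


def minimum_dominating_set(cg: CorrelationGraph | nx.Graph,
                           method: str = "ilp",
                           time_limit: float | None = None) -> set[str]:
    """Exact minimum dominating set via integer linear programming.

    Formulation: minimize Σ x_v subject to x_v + Σ_{u∈N(v)} x_u ≥ 1 for
    every vertex v, x binary. A tiny secondary objective prefers
    alphabetically earlier variable names among optima, so output is
    deterministic. Isolated vertices are always selected (they can only
    dominate themselves). ``method='greedy'`` switches to the 1+ln(Δ+1)
    approximation for very large graphs.

    The domination certificate is re-checked on every output regardless of
    solver.
    """
    graph = cg.graph if isinstance(cg, CorrelationGraph) else cg
    n = graph.number_of_nodes()
    if n == 0:
        return set()
    nodes = sorted(graph.nodes)
    if method == "greedy":
        result = _greedy_dominating_set(graph, nodes)
    elif method == "ilp":
        result = _ilp_dominating_set(graph, nodes, time_limit)
    else:
        raise DataModelError(f"unknown MDS method {method!r}")
    if not is_dominating_set(graph, result):
        raise DataModelError("solver returned a non-dominating set")
    return result


def _ilp_dominating_set(graph: nx.Graph, nodes: list,
                        time_limit: float | None) -> set:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for v in nodes:
        i = idx[v]
        rows.append(i)
        cols.append(i)
        for u in graph.neighbors(v):
            rows.append(i)
            cols.append(idx[u])
    A = scipy.sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    # secondary weights: total perturbation < 1/2 so cardinality dominates;
    # earlier names are cheaper, giving a deterministic alphabetical
    # preference among optimal sets
    sec = np.arange(1, n + 1, dtype=float) / (n + 1.0) ** 2
    c = 1.0 + sec
    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = scipy.optimize.milp(
        c=c,
        constraints=scipy.optimize.LinearConstraint(A, lb=1, ub=np.inf),
        integrality=np.ones(n),
        bounds=scipy.optimize.Bounds(0, 1),
        options=options,
    )
    if not res.success:
        size_bound = getattr(res, "mip_dual_bound", None)
        raise DataModelError(
            f"MDS ILP did not solve to optimality (status {res.status}); "
            f"best lower bound on size: {size_bound}"
        )
    return {nodes[i] for i in range(n) if res.x[i] > 0.5}


def _greedy_dominating_set(graph: nx.Graph, nodes: list) -> set:
    undominated = set(nodes)
    chosen: set = set()
    while undominated:
        best, best_gain = None, -1
        for v in nodes:
            if v in chosen:
                continue
            gain = len(undominated & ({v} | set(graph.neighbors(v))))
            if gain > best_gain:
                best, best_gain = v, gain
        chosen.add(best)
        undominated -= {best} | set(graph.neighbors(best))
    return chosen


# -- name-pattern filter -----------------------------------------------------


def name_pattern_filter(
    table: ExposomeTable,
    patterns: tuple[str, ...] = DEFAULT_NAME_PATTERNS,
) -> tuple[ExposomeTable, set[str]]:
    """Remove confidence-limit / margin-of-error variables by name.

    Patterns are case-insensitive substrings matched as whole tokens where
    that matters ("moe" must not fire inside e.g. "smoAtEr"-style words, so
    it is matched on word boundaries); an empty pattern list is a logged
    no-op.
    """
    if not patterns:
        logger.warning("name_pattern_filter: empty pattern list, no-op")
        return table, set()
    regexes = []
    for p in patterns:
        if len(p) <= 3 and p.isalnum():  # short tokens need word boundaries
            regexes.append(re.compile(rf"\b{re.escape(p)}\b", re.IGNORECASE))
        else:
            regexes.append(re.compile(re.escape(p), re.IGNORECASE))
    removed = {
        name for name in table.variables
        if any(rx.search(name) for rx in regexes)
    }
    return table.drop_variables(removed), removed


# -- the reduction driver ----------------------------------------------------


@dataclass
class ReductionReport:
    """Bookkeeping for one run of the reduction stage."""

    n_input: int
    n_after_mds: int
    n_after_name_filter: int
    dominating_set: set[str]
    removed_by_pattern: set[str]
    normality: NormalityScreen | None = None
    threshold: float = DEFAULT_AUTOCORR_THRESHOLD
    threshold_mode: str = "signed"

    def __post_init__(self) -> None:
        assert self.n_after_mds == len(self.dominating_set)
        assert self.n_after_name_filter <= self.n_after_mds


def reduce_table(
    table: ExposomeTable,
    threshold: float = DEFAULT_AUTOCORR_THRESHOLD,
    threshold_mode: str = "signed",
    min_pairs: int = DEFAULT_MIN_PAIRS,
    patterns: tuple[str, ...] = DEFAULT_NAME_PATTERNS,
    run_normality_screen: bool = True,
    mds_method: str = "ilp",
) -> tuple[ExposomeTable, ReductionReport]:
    """Full reduction: normality screen → autocorrelation graph → MDS → name filter."""
    screen = shapiro_wilk_screen(table) if run_normality_screen else None
    cg = build_autocorrelation_graph(
        table, threshold=threshold, threshold_mode=threshold_mode,
        min_pairs=min_pairs,
    )
    mds = minimum_dominating_set(cg, method=mds_method)
    reduced = table.subset(variables=[v for v in table.variables if v in mds])
    filtered, removed = name_pattern_filter(reduced, patterns)
    report = ReductionReport(
        n_input=len(table.variables),
        n_after_mds=len(mds),
        n_after_name_filter=len(filtered.variables),
        dominating_set=mds,
        removed_by_pattern=removed,
        normality=screen,
        threshold=threshold,
        threshold_mode=threshold_mode,
    )
    logger.info(
        "reduction: %d variables → %d after dominating set → %d after "
        "name filter", report.n_input, report.n_after_mds,
        report.n_after_name_filter,
    )
    return filtered, report
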