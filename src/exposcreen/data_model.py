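"""Core data structures and plain-text readers/writers.

The pipeline operates on three kinds of objects:

* :class:`ExposomeTable` — a counties × variables numeric matrix keyed by
  5-digit FIPS codes, each column carrying :class:`VariableMeta` (name,
  exposome domain, year, source, description).
* :class:`OutcomeSet` — per-county, per-stratum 4-year death and live-birth
  counts with derived pregnancy-related mortality (PRM) ratios and the
  birth-count inclusion flag.
* :class:`CorrelationGraph` — an undirected graph over variable names with
  Pearson-r edge weights, built at a stated threshold.

All serialization is diff-able plain text: comma-separated tables, an
edge-list format for graphs (with a vertex manifest so isolated vertices
survive a round trip), and DOT-compatible text for learned DAGs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("exposcreen")

#: The five exposome domains.
DOMAINS = ("built", "social", "natural", "health", "policy")

#: Outcome strata analysed by the pipeline.
STRATA = ("total", "nh_white", "nh_black", "hispanic")

_FIPS_RE = re.compile(r"^[0-9]{1,5}$")


class DataModelError(ValueError):
    """Raised on contract violations in table/graph construction or parsing."""


def normalize_fips(code: object) -> str:
    """Zero-pad a county FIPS code to the canonical 5-character string.

    Accepts integers or digit strings (``1001`` → ``"01001"``). Anything
    that is not 1–5 digits is rejected: FIPS codes are identifiers, not
    numbers, and must never round-trip through floats.
    """
    s = str(code).strip()
    if s.endswith(".0"):  # tolerate a float-typed CSV column
        s = s[:-2]
    if not _FIPS_RE.match(s):
        raise DataModelError(f"invalid FIPS code {code!r}")
    return s.zfill(5)


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one exposure variable."""

    name: str
    domain: str
    year: int | None = None
    source: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise DataModelError(
                f"variable {self.name!r}: unknown domain {self.domain!r} "
                f"(expected one of {DOMAINS})"
            )


class ExposomeTable:
    """Counties × variables numeric matrix with FIPS row keys and metadata.

    Internally a float DataFrame whose index holds normalized FIPS strings,
    plus a name → :class:`VariableMeta` mapping covering every column.
    Missing values are NaN and are never imputed; correlation routines use
    pairwise deletion.
    """

    def __init__(self, values: pd.DataFrame, meta: Mapping[str, VariableMeta]):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise DataModelError(f"duplicate FIPS row keys: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise DataModelError(f"duplicate variable names: {dups}")
        missing_meta = [c for c in values.columns if c not in meta]
        if missing_meta:
            raise DataModelError(
                f"columns without metadata: {missing_meta[:5]}"
                + ("..." if len(missing_meta) > 5 else "")
            )
        self.values = values.astype(float)
        self.values.index = pd.Index(
            [normalize_fips(i) for i in values.index], name="fips"
        )
        self.meta = {c: meta[c] for c in values.columns}

    # -- basic introspection -------------------------------------------------

    @property
    def fips(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def domain_of(self, name: str) -> str:
        return self.meta[name].domain

    def subset(self, variables: Sequence[str] | None = None,
               fips: Sequence[str] | None = None) -> "ExposomeTable":
        """Return a new table restricted to the given variables and/or rows."""
        vals = self.values
        if fips is not None:
            vals = vals.loc[list(fips)]
        if variables is not None:
            vals = vals[list(variables)]
        return ExposomeTable(vals, self.meta)

    def drop_variables(self, names: Iterable[str]) -> "ExposomeTable":
        names = set(names)
        keep = [c for c in self.variables if c not in names]
        return self.subset(variables=keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExposomeTable):
            return NotImplemented
        return (
            self.variables == other.variables
            and self.fips == other.fips
            and np.allclose(
                self.values.to_numpy(), other.values.to_numpy(), equal_nan=True
            )
            and self.meta == other.meta
        )

    # -- serialization -------------------------------------------------------

    def write(self, path: str | Path, meta_path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "fips", self.fips)
        out.to_csv(path, index=False, float_format="%.10g")
        rows = [
            {
                "name": m.name,
                "domain": m.domain,
                "year": "" if m.year is None else m.year,
                "source": m.source,
                "description": m.description,
            }
            for m in self.meta.values()
        ]
        pd.DataFrame(rows).to_csv(meta_path, index=False)


def read_variable_meta(meta_path: str | Path) -> dict[str, VariableMeta]:
    """Read a variable-metadata dictionary (CSV with name/domain columns)."""
    df = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
    required = {"name", "domain"}
    if not required.issubset(df.columns):
        raise DataModelError(
            f"metadata file {meta_path} must have columns {sorted(required)}"
        )
    meta: dict[str, VariableMeta] = {}
    for _, row in df.iterrows():
        name = row["name"]
        if name in meta:
            raise DataModelError(f"duplicate metadata for variable {name!r}")
        year = row.get("year", "")
        meta[name] = VariableMeta(
            name=name,
            domain=row["domain"],
            year=int(float(year)) if year not in ("", None) else None,
            source=row.get("source", ""),
            description=row.get("description", ""),
        )
    return meta


def read_exposome_table(path: str | Path,
                        meta_path: str | Path) -> ExposomeTable:
    """Read a counties × variables CSV plus its metadata dictionary.

    The data file must have a ``fips`` column (any 1–5 digit form; it is
    zero-padded) and a header row. Non-numeric cells become missing.
    Duplicate FIPS rows and data columns missing from the metadata file are
    hard errors.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "fips" not in raw.columns:
        raise DataModelError(f"{path}: no 'fips' column in header")
    fips = [normalize_fips(v) for v in raw["fips"]]
    if len(set(fips)) != len(fips):
        dups = sorted({f for f in fips if fips.count(f) > 1})
        raise DataModelError(f"{path}: duplicate FIPS rows {dups}")
    data = raw.drop(columns=["fips"]).apply(pd.to_numeric, errors="coerce")
    data.index = pd.Index(fips, name="fips")
    meta = read_variable_meta(meta_path)
    missing = [c for c in data.columns if c not in meta]
    if missing:
        raise DataModelError(
            f"{path}: columns without metadata entries: {missing}"
        )
    return ExposomeTable(data, meta)


# -- outcome counts ----------------------------------------------------------


class OutcomeSet:
    """Per-county, per-stratum 4-year deaths/births with PRM ratios.

    Backed by a DataFrame with columns ``fips, stratum, deaths_4yr,
    births_4yr, prm_ratio, included``. ``prm_ratio`` is present exactly when
    ``included`` is true (births at or above the inclusion minimum).
    """

    COLUMNS = ("fips", "stratum", "deaths_4yr", "births_4yr",
               "prm_ratio", "included")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("prm_ratio", "included"):
            if col not in df.columns:
                df[col] = np.nan if col == "prm_ratio" else False
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise DataModelError(f"OutcomeSet missing columns {missing}")
        df["fips"] = [normalize_fips(f) for f in df["fips"]]
        bad = set(df["stratum"]) - set(STRATA)
        if bad:
            raise DataModelError(f"unknown strata {sorted(bad)}")
        if df.duplicated(subset=["fips", "stratum"]).any():
            dup = df[df.duplicated(subset=["fips", "stratum"])]
            raise DataModelError(
                f"duplicate (fips, stratum) pairs: {dup[['fips', 'stratum']].values.tolist()[:5]}"
            )
        for col in ("deaths_4yr", "births_4yr"):
            vals = pd.to_numeric(df[col])
            if (vals < 0).any():
                raise DataModelError(f"negative values in {col}")
            df[col] = vals.astype(int)
        df["included"] = df["included"].astype(bool)
        # contract: ratio present iff included
        has_ratio = df["prm_ratio"].notna()
        if (has_ratio != df["included"]).any():
            raise DataModelError("prm_ratio must be present iff included")
        self.df = df[list(self.COLUMNS)].reset_index(drop=True)

    def for_stratum(self, stratum: str) -> pd.DataFrame:
        if stratum not in set(self.df["stratum"]):
            raise DataModelError(f"stratum {stratum!r} not present")
        return self.df[self.df["stratum"] == stratum]

    def included_fips(self, stratum: str) -> list[str]:
        sub = self.for_stratum(stratum)
        return list(sub.loc[sub["included"], "fips"])

    def inclusion_counts(self) -> dict[str, int]:
        """Number of included counties per stratum (run-log bookkeeping)."""
        return {
            s: int(self.df[(self.df["stratum"] == s) & self.df["included"]].shape[0])
            for s in sorted(set(self.df["stratum"]))
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OutcomeSet):
            return NotImplemented
        a = self.df.sort_values(["fips", "stratum"]).reset_index(drop=True)
        b = other.df.sort_values(["fips", "stratum"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False, atol=1e-9)
            return True
        except AssertionError:
            return False

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out["included"] = out["included"].astype(int)
        out.to_csv(path, index=False, float_format="%.10g")


def read_outcomes(path: str | Path) -> OutcomeSet:
    """Read a CSV of (fips, stratum, deaths_4yr, births_4yr[, prm_ratio, included])."""
    df = pd.read_csv(path, dtype={"fips": str})
    if "included" in df.columns:
        df["included"] = df["included"].astype(bool)
    return OutcomeSet(df)


# -- correlation graphs ------------------------------------------------------


@dataclass
class CorrelationGraph:
    """Undirected graph over variable names, edges weighted by Pearson r.

    ``threshold_mode`` records how edges were admitted: ``signed`` keeps
    pairs with r ≥ threshold, ``absolute`` keeps |r| ≥ threshold.
    """

    graph: nx.Graph
    threshold: float
    threshold_mode: str = "signed"
    min_pairs: int = 30

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("signed", "absolute"):
            raise DataModelError(
                f"threshold_mode must be 'signed' or 'absolute', "
                f"got {self.threshold_mode!r}"
            )
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise DataModelError(f"self-loop at {u!r}")
            if w is not None and not -1.0 - 1e-12 <= w <= 1.0 + 1e-12:
                raise DataModelError(f"edge ({u},{v}) weight {w} outside [-1,1]")

    @property
    def vertices(self) -> list[str]:
        return sorted(self.graph.nodes)

    def equals(self, other: "CorrelationGraph", tol: float = 5e-7) -> bool:
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        ea = {frozenset(e): w for *e, w in self.graph.edges(data="weight")}
        eb = {frozenset(e): w for *e, w in other.graph.edges(data="weight")}
        if ea.keys() != eb.keys():
            return False
        return all(abs(ea[k] - eb[k]) <= tol for k in ea)


def write_graph(cg: CorrelationGraph, path: str | Path) -> None:
    """Serialize a correlation graph as plain text.

    Format: a header line with threshold/mode/min_pairs, a vertex manifest
    (one name per line, so isolated vertices survive), then an edge list
    ``u<TAB>v<TAB>weight`` with weights to 6 decimals.
    """
    g = cg.graph
    lines = [
        f"# correlation-graph threshold={cg.threshold} "
        f"mode={cg.threshold_mode} min_pairs={cg.min_pairs}",
        "[vertices]",
        *sorted(g.nodes),
        "[edges]",
    ]
    for u, v, w in sorted(
        (tuple(sorted((a, b))) + (w,)) for a, b, w in g.edges(data="weight")
    ):
        lines.append(f"{u}\t{v}\t{w:.6f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_graph(path: str | Path) -> CorrelationGraph:
    """Parse a graph written by :func:`write_graph`.

    Malformed lines raise :class:`DataModelError` naming the line number.
    """
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or not text[0].startswith("# correlation-graph"):
        raise DataModelError(f"{path}:1: missing correlation-graph header")
    header = dict(
        tok.split("=", 1) for tok in text[0].split() if "=" in tok
    )
    g = nx.Graph()
    section = None
    for lineno, line in enumerate(text[1:], start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        if line == "[vertices]":
            section = "v"
            continue
        if line == "[edges]":
            section = "e"
            continue
        if section == "v":
            g.add_node(line)
        elif section == "e":
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataModelError(
                    f"{path}:{lineno}: expected 'u<TAB>v<TAB>weight', got {line!r}"
                )
            u, v, ws = parts
            try:
                w = float(ws)
            except ValueError as exc:
                raise DataModelError(
                    f"{path}:{lineno}: bad weight {ws!r}"
                ) from exc
            g.add_edge(u, v, weight=w)
        else:
            raise DataModelError(f"{path}:{lineno}: content before [vertices]")
    return CorrelationGraph(
        graph=g,
        threshold=float(header.get("threshold", 0.0)),
        threshold_mode=header.get("mode", "signed"),
        min_pairs=int(header.get("min_pairs", 0)),
    )


# -- learned DAGs ------------------------------------------------------------


@dataclass
class LearnedDAG:
    """A DAG learned by score-based search, with its BIC decomposition.

    ``per_node_score`` maps each node to its local Gaussian BIC
    contribution; ``score_total`` is their sum (decomposability).
    """

    nodes: list[str]
    arcs: list[tuple[str, str]]
    score_total: float
    per_node_score: dict[str, float]
    outcome: str | None = None
    n_rows: int = 0

    def __post_init__(self) -> None:
        dag = nx.DiGraph()
        dag.add_nodes_from(self.nodes)
        dag.add_edges_from(self.arcs)
        if not nx.is_directed_acyclic_graph(dag):
            raise DataModelError("arc set contains a cycle")
        self._dag = dag

    def parents(self, node: str) -> list[str]:
        return sorted(self._dag.predecessors(node))

    def children(self, node: str) -> list[str]:
        return sorted(self._dag.successors(node))

    @property
    def direct_predictors(self) -> list[str]:
        if self.outcome is None:
            return []
        return self.parents(self.outcome)

    @property
    def markov_blanket(self) -> list[str]:
        """Parents, children, and co-parents of the outcome node."""
        if self.outcome is None:
            return []
        mb = set(self.parents(self.outcome)) | set(self.children(self.outcome))
        for child in self._dag.successors(self.outcome):
            mb |= set(self._dag.predecessors(child))
        mb.discard(self.outcome)
        return sorted(mb)

    def ancestors(self, node: str) -> list[str]:
        return sorted(nx.ancestors(self._dag, node))

    def to_dot(self) -> str:
        lines = ["digraph learned_network {"]
        for n in sorted(self.nodes):
            shape = "box" if n == self.outcome else "ellipse"
            lines.append(f'  "{n}" [shape={shape}];')
        for p, c in sorted(self.arcs):
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_dot(), encoding="utf-8")


def read_dag(path: str | Path) -> tuple[list[str], list[tuple[str, str]]]:
    """Parse nodes and arcs from DOT text written by :meth:`LearnedDAG.write`."""
    nodes, arcs = [], []
    node_re = re.compile(r'^\s*"([^"]+)"\s*\[')
    arc_re = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"')
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        m = arc_re.match(line)
        if m:
            arcs.append((m.group(1), m.group(2)))
            continue
        m = node_re.match(line)
        if m:
            nodes.append(m.group(1))
    return nodes, arcs


# -- linkage -----------------------------------------------------------------


def outcome_column_name(stratum: str) -> str:
    return f"prm_{stratum}"


def link_outcomes(table: ExposomeTable, outcomes: OutcomeSet,
                  stratum: str) -> ExposomeTable:
    """Join PRM ratios onto the exposome table by FIPS for one stratum.

    Restricts to counties *included* for the stratum (birth-count rule) and
    appends one outcome column named ``prm_<stratum>``. Outcome counties
    absent from the exposome table are dropped with a warning; no overlap at
    all is an error.
    """
    sub = outcomes.for_stratum(stratum)
    inc = sub[sub["included"]]
    in_table = set(table.fips)
    keep = [f for f in inc["fips"] if f in in_table]
    missing = sorted(set(inc["fips"]) - in_table)
    if missing:
        logger.warning(
            "link_outcomes: %d included counties absent from exposome table "
            "(e.g. %s); dropped", len(missing), missing[:3],
        )
    if not keep:
        raise DataModelError(
            f"no overlap between exposome table and included counties "
            f"for stratum {stratum!r}"
        )
    ratios = inc.set_index("fips")["prm_ratio"]
    col = outcome_column_name(stratum)
    vals = table.values.loc[keep].copy()
    vals[col] = [float(ratios[f]) for f in keep]
    meta = dict(table.meta)
    meta[col] = VariableMeta(
        name=col, domain="health",
        description=f"pregnancy-related mortality ratio, {stratum} stratum, "
                    "deaths per 100,000 live births",
    )
    return ExposomeTable(vals, meta)
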