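"""End-to-end orchestration: generate/load → reduce → link → screen → mine → learn.

One :class:`RunConfig` (readable from a YAML file) drives the full
analysis in the method's stage order:

1. obtain an exposome table and outcome counts (synthetic or from files);
2. apply the birth-count inclusion rule per stratum;
3. variable reduction (autocorrelation graph at 0.9, minimum dominating
   set, margin-of-error name filter);
4. per stratum: FIPS linkage, the supervised correlation screen (one
   combined + five domain lists), and per-domain Bayesian networks on the
   top-k correlates;
5. unsupervised paraclique extraction across the configured threshold ×
   glom-term grid, retaining paracliques containing an outcome vertex.

The run report is plain text with a content digest: identical config and
seed reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bayesnet, outcomes as outcomes_mod, paraclique as pc
from . import reduction, screening, synthetic_data
from .data_model import (
    DataModelError,
    ExposomeTable,
    OutcomeSet,
    link_outcomes,
    outcome_column_name,
    read_exposome_table,
    read_outcomes,
    write_graph,
)

logger = logging.getLogger("exposcreen")


@dataclass
class RunConfig:
    """All knobs of one analysis run; every value is echoed in the report."""

    # inputs: either file paths or a synthetic design
    table_path: str | None = None
    meta_path: str | None = None
    outcomes_path: str | None = None
    synthetic: bool = True
    design: synthetic_data.SyntheticDesign = field(
        default_factory=synthetic_data.SyntheticDesign
    )
    moe_fraction: float = 0.1

    strata: tuple[str, ...] = ("total", "nh_white", "nh_black", "hispanic")
    min_births: int = 1000
    autocorr_threshold: float = 0.9
    autocorr_mode: str = "signed"
    min_pairs: int = 30
    retention_r: float = 0.15
    top_k: int = 20
    paraclique_thresholds: tuple[float, ...] = pc.DEFAULT_THRESHOLDS
    glom_terms: tuple[int, ...] = pc.DEFAULT_GLOM_TERMS
    min_clique: int = 3
    drop_missing_exposures: bool = False  # drop counties with any missing cell
    seed: int = 0
    out_dir: str = "run_out"

    def __post_init__(self) -> None:
        for t in (self.autocorr_threshold, self.retention_r,
                  *self.paraclique_thresholds):
            if not 0 < t < 1:
                raise DataModelError(f"threshold {t} outside (0,1)")
        if self.min_births < 0:
            raise DataModelError("min_births must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        design_kwargs = raw.pop("design", {})
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if design_kwargs:
            cfg.design = synthetic_data.SyntheticDesign(**design_kwargs)
        cfg.design.seed = cfg.seed if "seed" not in design_kwargs else cfg.design.seed
        return cfg


@dataclass
class RunReport:
    lines: list[str] = field(default_factory=list)

    def add(self, text: str = "") -> None:
        self.lines.append(text)

    def text(self) -> str:
        body = "\n".join(self.lines) + "\n"
        digest = hashlib.sha256(body.encode()).hexdigest()[:16]
        return body + f"digest: {digest}\n"


@dataclass
class RunResult:
    table: ExposomeTable
    outcomes: OutcomeSet
    reduced: ExposomeTable
    reduction_report: reduction.ReductionReport
    screens: dict[str, screening.ScreenResult]          # stratum → combined list
    sublists: dict[str, dict[str, screening.ScreenResult]]
    paracliques: dict[tuple[float, int], list[pc.Paraclique]]
    networks: dict[str, dict[str, "bayesnet.LearnedDAG"]]  # stratum → domain → DAG
    truth: synthetic_data.TruthRecord | None
    report: str


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic:
        cfg.design.seed = cfg.design.seed or cfg.seed
        table, outc, truth = synthetic_data.generate(cfg.design)
        planted: list[str] = []
        if cfg.moe_fraction > 0:
            table, planted = synthetic_data.plant_moe_variables(
                table, cfg.moe_fraction, seed=cfg.seed + 1
            )
        truth.moe_planted = planted
        return table, outc, truth
    if not (cfg.table_path and cfg.meta_path and cfg.outcomes_path):
        raise DataModelError(
            "non-synthetic run requires table_path, meta_path, outcomes_path"
        )
    table = read_exposome_table(cfg.table_path, cfg.meta_path)
    raw = read_outcomes(cfg.outcomes_path)
    return table, raw, None


def run(cfg: RunConfig, write_artifacts: bool = True) -> RunResult:
    """Execute the full pipeline; see the module docstring for stage order."""
    out = Path(cfg.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    rep = RunReport()
    rep.add("exposcreen run report")
    rep.add(f"seed: {cfg.seed}")
    for k, v in dataclasses.asdict(cfg).items():
        if k not in ("design", "out_dir"):
            rep.add(f"config.{k}: {v}")
    for k, v in dataclasses.asdict(cfg.design).items():
        rep.add(f"design.{k}: {v}")

    # stage 1: inputs
    table, outc, truth = _load_inputs(cfg)
    rep.add(f"input: {table.shape[0]} counties x {table.shape[1]} variables")

    # stage 2: inclusion rule
    outc = outcomes_mod.apply_inclusion(outc.df, min_births=cfg.min_births)
    for s, cnt in outc.inclusion_counts().items():
        rep.add(f"included[{s}]: {cnt}")

    # optional handling of counties with missing exposure cells at linkage
    if cfg.drop_missing_exposures:
        complete = table.values.dropna().index
        table = table.subset(fips=list(complete))
        rep.add(f"complete-case counties: {table.shape[0]}")

    # stage 3: reduction
    reduced, red_rep = reduction.reduce_table(
        table,
        threshold=cfg.autocorr_threshold,
        threshold_mode=cfg.autocorr_mode,
        min_pairs=cfg.min_pairs,
    )
    rep.add(
        f"reduction: {red_rep.n_input} -> {red_rep.n_after_mds} (dominating "
        f"set) -> {red_rep.n_after_name_filter} (name filter)"
    )
    if write_artifacts:
        cg = reduction.build_autocorrelation_graph(
            table, cfg.autocorr_threshold, cfg.autocorr_mode, cfg.min_pairs
        )
        write_graph(cg, out / "autocorrelation_graph.txt")

    # stage 4: supervised per stratum
    screens: dict[str, screening.ScreenResult] = {}
    sublists: dict[str, dict[str, screening.ScreenResult]] = {}
    networks: dict[str, dict[str, bayesnet.LearnedDAG]] = {}
    linked_tables: dict[str, ExposomeTable] = {}
    for stratum in cfg.strata:
        linked = link_outcomes(reduced, outc, stratum)
        linked_tables[stratum] = linked
        col = outcome_column_name(stratum)
        res = screening.screen(linked, col, retention_r=cfg.retention_r,
                               min_pairs=cfg.min_pairs)
        subs = screening.domain_sublists(res)
        screens[stratum] = res
        sublists[stratum] = subs
        rep.add(
            f"screen[{stratum}]: {len(res.entries)} correlates, "
            f"{len(res.retained)} retained at |r|>{cfg.retention_r}"
        )
        if write_artifacts:
            res.write(out / f"list_{stratum}_combined.csv")
            for d, sub in subs.items():
                sub.write(out / f"list_{stratum}_{d}.csv")
        nets = bayesnet.run_per_domain(linked.values, res, col, k=cfg.top_k)
        networks[stratum] = nets
        for dom, dag in sorted(nets.items()):
            preds = ",".join(dag.direct_predictors) or "None"
            rep.add(f"network[{stratum}][{dom}]: direct predictors: {preds}")
            if write_artifacts:
                dag.write(out / f"dag_{stratum}_{dom}.dot")

    # stage 5: unsupervised paracliques over the total-population counties
    base_stratum = cfg.strata[0]
    base = linked_tables[base_stratum]
    vals = base.values.copy()
    # add the other strata's ratio columns (missing where not included)
    for stratum in cfg.strata[1:]:
        col = outcome_column_name(stratum)
        sub = outc.for_stratum(stratum)
        ratios = sub[sub["included"]].set_index("fips")["prm_ratio"]
        vals[col] = [ratios.get(f, float("nan")) for f in vals.index]
    outcome_cols = {outcome_column_name(s) for s in cfg.strata}
    corr = reduction.correlation_matrix(vals, min_pairs=cfg.min_pairs)
    paracliques: dict[tuple[float, int], list[pc.Paraclique]] = {}
    for t in cfg.paraclique_thresholds:
        graph = pc.threshold_graph(corr, t)
        for g in cfg.glom_terms:
            retained = pc.extract_all(
                graph, g, min_clique=cfg.min_clique,
                outcome_vertices=outcome_cols,
            )
            paracliques[(t, g)] = retained
            rep.add(
                f"paraclique[t={t},g={g}]: {len(retained)} retained "
                f"(sizes {[len(p.members) for p in retained]})"
            )
            if write_artifacts:
                for i, p in enumerate(retained):
                    (out / f"paraclique_t{t}_g{g}_{i}.txt").write_text(
                        p.manifest(), encoding="utf-8"
                    )

    report = rep.text()
    if write_artifacts:
        (out / "report.txt").write_text(report, encoding="utf-8")
    return RunResult(
        table=table, outcomes=outc, reduced=reduced,
        reduction_report=red_rep, screens=screens, sublists=sublists,
        paracliques=paracliques, networks=networks, truth=truth,
        report=report,
    )
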