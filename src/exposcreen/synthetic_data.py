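"""Synthetic county-level exposome and outcome data with planted structure.

The real inputs — restricted-use vital-statistics files and a 62,000-variable
county-level exposure repository — cannot be redistributed, so every
downstream stage is exercised on synthetic data whose *statistical*
structure matches what the analysis assumes:

* **Autocorrelate blocks**: groups of near-duplicate variables,
  equicorrelated at ``within_block_r`` > 0.9, so the autocorrelation graph
  at threshold 0.9 resolves each block into one connected clique and the
  dominating-set step keeps exactly one representative per block.
* **Planted dense clusters**: groups equicorrelated at a moderate
  ``cluster_r`` (below the 0.9 threshold, above the paraclique
  thresholds), each driven by its own latent factor. Cluster 1's factor is
  a latent *deprivation* score that also drives the outcome, so cluster 1
  ∪ {outcome} is the planted paraclique and cluster-1 variables are the
  planted supervised signal.
* **Noise variables**: independent Gaussians.
* **Outcomes**: per county, total live births are uniform integers on
  ``births_range``, partitioned into race/ethnicity strata by
  Dirichlet-distributed shares; stratum deaths are Poisson with mean
  births × ratio / 100,000, where log(ratio) = log(base_ratio) +
  outcome_effect × deprivation + small log-normal noise, times a
  per-stratum rate multiplier emulating the observed disparities.

Every pairwise correlation is analytically known (equicorrelated Gaussian
construction: x = √r·factor + √(1−r)·noise), and the model-implied
correlation between each cluster-1 variable and the *realized* PRM ratio —
including log-normal spread and Poisson sampling attenuation — is computed
in closed form and recorded in the truth record, so recovery can be tested
quantitatively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import exp, log, sqrt
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    DOMAINS,
    STRATA,
    DataModelError,
    ExposomeTable,
    OutcomeSet,
    VariableMeta,
)
from .outcomes import PER, apply_inclusion

logger = logging.getLogger("exposcreen")

#: Dirichlet concentration for (nh_white, nh_black, hispanic, other) birth
#: shares; means ≈ (0.60, 0.15, 0.20, 0.05).
_SHARE_ALPHA = (12.0, 3.0, 4.0, 1.0)

#: Per-stratum multipliers on the mortality ratio, emulating the large
#: NH-Black disparity reported for pregnancy-related mortality.
_STRATUM_RATE = {"nh_white": 0.8, "nh_black": 2.2, "hispanic": 0.9}


@dataclass
class SyntheticDesign:
    """Parameters of the planted-structure generator.

    Defaults are the package's standard study conditions: 2000 counties,
    near-duplicate blocks at r = 0.95, planted clusters at r = 0.3, and an
    outcome effect calibrated so each cluster-1 variable's model-implied
    correlation with the realized PRM ratio is ≈ 0.25.
    """

    n_counties: int = 2000
    n_blocks: int = 10
    block_size: int = 4
    within_block_r: float = 0.95
    n_clusters: int = 3
    cluster_size: int = 8
    cluster_r: float = 0.3
    outcome_effect: float = 0.4
    log_ratio_noise: float = 0.1
    n_noise_vars: int = 30
    births_range: tuple[int, int] = (500, 20_000)
    base_ratio: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.9 < self.within_block_r < 1:
            raise DataModelError(
                "within_block_r must lie in (0.9, 1) so blocks form "
                "autocorrelation-graph components"
            )
        if not 0 < self.cluster_r < self.within_block_r:
            raise DataModelError(
                "cluster_r must lie in (0, within_block_r); values outside "
                "[0, 1) have no positive-definite equicorrelation structure"
            )
        if self.base_ratio <= 0:
            raise DataModelError("base_ratio must be positive")
        if self.births_range[0] < 0 or self.births_range[0] > self.births_range[1]:
            raise DataModelError("invalid births_range")

    # -- analytic moments ---------------------------------------------------

    def _ratio_moments(self) -> tuple[float, float]:
        """E[R] and Var(R) of the log-normal county mortality ratio."""
        s2 = self.outcome_effect ** 2 + self.log_ratio_noise ** 2
        mean = self.base_ratio * exp(s2 / 2)
        var = mean ** 2 * (exp(s2) - 1)
        return mean, var

    def _mean_inv_births(self, min_births: int) -> float:
        """E[1/B] for B uniform on the integer births range, B ≥ min_births."""
        lo = max(self.births_range[0], min_births)
        hi = self.births_range[1]
        b = np.arange(lo, hi + 1, dtype=float)
        return float(np.mean(1.0 / b))

    def design_correlation(self, min_births: int = 1000) -> float:
        """Model-implied corr(cluster-1 variable, realized total-PRM ratio).

        The variable is x = √c·dep + √(1−c)·ε and the realized ratio is
        Y = 10⁵·D/B with D | B, R ~ Poisson(B·R/10⁵) and
        R = base·exp(β·dep + τ·u). Then Cov(x, Y) = √c·β·E[R] and
        Var(Y) = Var(R) + 10⁵·E[R]·E[1/B], restricted to included
        counties (B ≥ min_births; B is independent of the exposures, so
        inclusion does not bias the correlation).
        """
        mean_r, var_r = self._ratio_moments()
        poisson_var = PER * mean_r * self._mean_inv_births(min_births)
        cov = sqrt(self.cluster_r) * self.outcome_effect * mean_r
        return cov / sqrt(var_r + poisson_var)

    def latent_correlation(self) -> float:
        """Corr(cluster-1 variable, latent log-ratio η = β·dep + τ·u)."""
        beta, tau = self.outcome_effect, self.log_ratio_noise
        denom = sqrt(beta ** 2 + tau ** 2)
        if denom == 0:  # degenerate: constant log-ratio
            return 0.0
        return sqrt(self.cluster_r) * beta / denom


@dataclass
class TruthRecord:
    """Ground truth for one generated dataset."""

    blocks: dict[str, list[str]]          # block id → member variables
    clusters: dict[str, list[str]]        # cluster id → member variables
    signal_variables: list[str]           # cluster 1 (outcome-linked)
    design_corr_outcome: float            # per signal variable, vs realized PRM
    design_corr_latent: float             # per signal variable, vs latent log-ratio
    deprivation: pd.Series                # latent deprivation score per county
    moe_planted: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        lines = [
            f"design_corr_outcome={self.design_corr_outcome:.6f}",
            f"design_corr_latent={self.design_corr_latent:.6f}",
            "signal_variables=" + ",".join(self.signal_variables),
            "moe_planted=" + ",".join(self.moe_planted),
        ]
        for bid, members in self.blocks.items():
            lines.append(f"block.{bid}=" + ",".join(members))
        for cid, members in self.clusters.items():
            lines.append(f"cluster.{cid}=" + ",".join(members))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _equicorrelated(rng: np.random.Generator, factor: np.ndarray,
                    r: float, k: int) -> np.ndarray:
    """k columns x_j = √r·factor + √(1−r)·ε_j (pairwise correlation r)."""
    n = factor.size
    eps = rng.standard_normal((n, k))
    return sqrt(r) * factor[:, None] + sqrt(1.0 - r) * eps


def generate(design: SyntheticDesign) -> tuple[ExposomeTable, OutcomeSet,
                                               TruthRecord]:
    """Draw one synthetic dataset; identical seed ⇒ bit-identical outputs."""
    rng = np.random.default_rng(design.seed)
    n = design.n_counties
    fips = [f"{i:05d}" for i in range(1001, 1001 + n)]

    cols: dict[str, np.ndarray] = {}
    meta: dict[str, VariableMeta] = {}
    blocks: dict[str, list[str]] = {}
    clusters: dict[str, list[str]] = {}
    domain_cycle = list(DOMAINS)

    for b in range(design.n_blocks):
        factor = rng.standard_normal(n)
        X = _equicorrelated(rng, factor, design.within_block_r,
                            design.block_size)
        names = [f"blk{b:02d}_v{j}" for j in range(design.block_size)]
        dom = domain_cycle[b % len(domain_cycle)]
        for j, name in enumerate(names):
            cols[name] = X[:, j]
            meta[name] = VariableMeta(name, dom, description="autocorrelate block member")
        blocks[f"blk{b:02d}"] = names

    deprivation = rng.standard_normal(n)
    for c in range(design.n_clusters):
        factor = deprivation if c == 0 else rng.standard_normal(n)
        X = _equicorrelated(rng, factor, design.cluster_r, design.cluster_size)
        names = [f"clu{c:02d}_v{j}" for j in range(design.cluster_size)]
        # cluster 1 is the deprivation cluster; its variables are social-domain
        dom = "social" if c == 0 else domain_cycle[c % len(domain_cycle)]
        for j, name in enumerate(names):
            cols[name] = X[:, j]
            meta[name] = VariableMeta(name, dom, description="planted cluster member")
        clusters[f"clu{c:02d}"] = names

    noise = rng.standard_normal((n, design.n_noise_vars))
    for j in range(design.n_noise_vars):
        name = f"noise_v{j:03d}"
        cols[name] = noise[:, j]
        meta[name] = VariableMeta(name, domain_cycle[j % len(domain_cycle)],
                                  description="independent noise variable")

    table = ExposomeTable(pd.DataFrame(cols, index=pd.Index(fips, name="fips")),
                          meta)

    # outcomes: births partitioned by race shares, Poisson deaths
    bmin, bmax = design.births_range
    births_total = rng.integers(bmin, bmax + 1, size=n)
    shares = rng.dirichlet(_SHARE_ALPHA, size=n)  # white, black, hisp, other
    log_ratio = (
        log(design.base_ratio)
        + design.outcome_effect * deprivation
        + design.log_ratio_noise * rng.standard_normal(n)
    )
    ratio = np.exp(log_ratio)

    rows = []
    stratum_births = {
        "nh_white": np.round(births_total * shares[:, 0]).astype(int),
        "nh_black": np.round(births_total * shares[:, 1]).astype(int),
        "hispanic": np.round(births_total * shares[:, 2]).astype(int),
    }
    other_births = births_total - sum(stratum_births.values())
    other_births = np.maximum(other_births, 0)
    deaths = {}
    for s, b in stratum_births.items():
        deaths[s] = rng.poisson(b * ratio * _STRATUM_RATE[s] / PER)
    deaths_other = rng.poisson(other_births * ratio / PER)
    deaths_total = sum(deaths.values()) + deaths_other
    for i, f in enumerate(fips):
        rows.append(dict(fips=f, stratum="total",
                         deaths_4yr=int(deaths_total[i]),
                         births_4yr=int(births_total[i])))
        for s in ("nh_white", "nh_black", "hispanic"):
            rows.append(dict(fips=f, stratum=s,
                             deaths_4yr=int(deaths[s][i]),
                             births_4yr=int(stratum_births[s][i])))
    outcomes = apply_inclusion(pd.DataFrame(rows))

    truth = TruthRecord(
        blocks=blocks,
        clusters=clusters,
        signal_variables=list(clusters["clu00"]),
        design_corr_outcome=design.design_correlation(),
        design_corr_latent=design.latent_correlation(),
        deprivation=pd.Series(deprivation, index=fips, name="deprivation"),
    )
    logger.info(
        "synthetic generate: %d counties, %d variables, inclusion counts %s",
        n, len(table.variables), outcomes.inclusion_counts(),
    )
    return table, outcomes, truth


_MOE_SUFFIXES = (" margin of error", " 95% confidence limit")


def plant_moe_variables(
    table: ExposomeTable,
    fraction: float,
    seed: int = 0,
) -> tuple[ExposomeTable, list[str]]:
    """Append margin-of-error / confidence-limit copies of random variables.

    Gives the reduction stage's name filter known targets: each planted
    column is a renamed copy of an existing variable, its name matching the
    default filter patterns. Returns the augmented table and the planted
    names.
    """
    if not 0 <= fraction < 1:
        raise DataModelError("fraction must lie in [0, 1)")
    k = int(round(fraction * len(table.variables)))
    if k == 0:
        return table, []
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(table.variables, size=k, replace=False))
    vals = table.values.copy()
    meta = dict(table.meta)
    planted = []
    for i, src in enumerate(chosen):
        new = src + _MOE_SUFFIXES[i % len(_MOE_SUFFIXES)]
        vals[new] = vals[src]
        meta[new] = VariableMeta(new, table.meta[src].domain,
                                 description=f"uncertainty companion of {src}")
        planted.append(new)
    return ExposomeTable(vals, meta), planted
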