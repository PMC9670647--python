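"""Supervised screening: sorted correlation lists per outcome and domain.

For each PRM ratio variable (one per demographic stratum), every exposure
variable is correlated with the outcome over the stratum's included
counties. The entries are sorted by |r| descending (printed lists
interleave signs in descending magnitude, so magnitude is the sort key;
ties break alphabetically), subdivided into the five exposome-domain
sublists, and flagged as retained when |r| exceeds the retention threshold
(default 0.15, strict). Top-k extraction feeds the network-learning stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DOMAINS, DataModelError, ExposomeTable
from .reduction import DEFAULT_MIN_PAIRS, pearson

logger = logging.getLogger("exposcreen")

DEFAULT_RETENTION_R = 0.15
DEFAULT_TOP_K = 20


@dataclass
class ScreenEntry:
    variable: str
    domain: str
    r: float
    n_pairs: int
    retained: bool


@dataclass
class ScreenResult:
    """One sorted correlation list (combined or single-domain)."""

    outcome: str
    entries: list[ScreenEntry]
    retention_r: float = DEFAULT_RETENTION_R
    domain: str | None = None  # None for the combined list

    @property
    def retained(self) -> list[ScreenEntry]:
        return [e for e in self.entries if e.retained]

    def variable_names(self, retained_only: bool = False) -> list[str]:
        src = self.retained if retained_only else self.entries
        return [e.variable for e in src]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": e.variable,
                    "domain": e.domain,
                    "r": e.r,
                    "n_pairs": e.n_pairs,
                    "retained": e.retained,
                }
                for e in self.entries
            ]
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _sort_key(e: ScreenEntry) -> tuple[float, str]:
    return (-abs(e.r), e.variable)


def screen(
    table: ExposomeTable,
    outcome_name: str,
    retention_r: float = DEFAULT_RETENTION_R,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> ScreenResult:
    """Correlate every exposure variable with the outcome column.

    Entries with fewer than ``min_pairs`` complete pairs (or a constant
    margin) are dropped with a log line. Retention is strict: |r| >
    retention_r.
    """
    if outcome_name not in table.variables:
        raise DataModelError(f"outcome column {outcome_name!r} not in table")
    y = table.values[outcome_name].to_numpy(dtype=float)
    y_ok = y[~np.isnan(y)]
    if y_ok.size == 0 or np.ptp(y_ok) == 0:
        raise DataModelError(f"outcome {outcome_name!r} is constant")
    entries: list[ScreenEntry] = []
    dropped = []
    for name in table.variables:
        if name == outcome_name:
            continue
        x = table.values[name].to_numpy(dtype=float)
        r = pearson(x, y, min_pairs=min_pairs)
        if r is None:
            dropped.append(name)
            continue
        n_pairs = int((~(np.isnan(x) | np.isnan(y))).sum())
        entries.append(
            ScreenEntry(
                variable=name,
                domain=table.domain_of(name),
                r=r,
                n_pairs=n_pairs,
                retained=abs(r) > retention_r,
            )
        )
    if dropped:
        logger.info(
            "screen(%s): dropped %d variables with undefined correlation "
            "(e.g. %s)", outcome_name, len(dropped), dropped[:3],
        )
    entries.sort(key=_sort_key)
    return ScreenResult(outcome=outcome_name, entries=entries,
                        retention_r=retention_r)


def domain_sublists(result: ScreenResult) -> dict[str, ScreenResult]:
    """Split a combined list into the five domain sublists.

    Order and retention flags are preserved; the union of the sublists is
    the combined list. An empty domain yields an empty sublist, not an
    error.
    """
    for e in result.entries:
        if e.domain not in DOMAINS:
            raise DataModelError(
                f"variable {e.variable!r} has unknown domain {e.domain!r}"
            )
    return {
        d: ScreenResult(
            outcome=result.outcome,
            entries=[e for e in result.entries if e.domain == d],
            retention_r=result.retention_r,
            domain=d,
        )
        for d in DOMAINS
    }


def top_k(result: ScreenResult, k: int = DEFAULT_TOP_K) -> list[str]:
    """First min(k, length) variable names in the sort order."""
    if k < 1:
        raise DataModelError("k must be >= 1")
    return [e.variable for e in result.entries[:k]]
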