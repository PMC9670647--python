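"""Pregnancy-related mortality ratios and the birth-count inclusion rule.

The outcome is the county-level pregnancy-related mortality (PRM) ratio:
deaths related to or aggravated by pregnancy, per 100,000 live births,
with deaths and births each summed over a 4-year window. To stabilise the
ratio, a county enters the analysis for a given demographic stratum only
when it recorded at least ``min_births`` (default 1000) live births for
that stratum over the window; no exclusion ever depends on the number of
deaths, so zero-death counties are retained with a ratio of 0.
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

from .data_model import DataModelError, OutcomeSet

PER = 100_000  # ratio scale: deaths per 100,000 live births
DEFAULT_MIN_BIRTHS = 1000


def compute_prm(deaths_4yr: int, births_4yr: int) -> float:
    """Deaths per 100,000 live births, exact rational arithmetic until the end.

    >>> compute_prm(5, 20000)
    25.0
    """
    if deaths_4yr < 0 or births_4yr < 0:
        raise DataModelError("counts must be non-negative")
    if births_4yr == 0:
        raise DataModelError("PRM ratio undefined for zero births")
    return float(Fraction(deaths_4yr) * PER / Fraction(births_4yr))


def sum_years(per_year_counts: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-year (fips, stratum, deaths, births) rows over the window.

    Trivial helper for callers holding yearly counts; the pipeline proper
    consumes pre-aggregated 4-year totals.
    """
    return (
        per_year_counts.groupby(["fips", "stratum"], as_index=False)[
            ["deaths", "births"]
        ]
        .sum()
        .rename(columns={"deaths": "deaths_4yr", "births": "births_4yr"})
    )


def apply_inclusion(counts: pd.DataFrame | OutcomeSet,
                    min_births: int = DEFAULT_MIN_BIRTHS) -> OutcomeSet:
    """Flag included counties and compute PRM ratios for them.

    ``included`` is ``births_4yr >= min_births`` (the boundary is
    inclusive: a "minimum of 1000 live births" admits exactly 1000).
    Ratios are computed only for included rows; excluded rows carry no
    ratio. Deaths never influence inclusion.
    """
    if isinstance(counts, OutcomeSet):
        df = counts.df.drop(columns=["prm_ratio", "included"])
    else:
        df = counts.copy()
    for col in ("deaths_4yr", "births_4yr"):
        if col not in df.columns:
            raise DataModelError(f"counts missing column {col!r}")
        if (pd.to_numeric(df[col]) < 0).any():
            raise DataModelError(f"negative values in {col}")
    if min_births < 0:
        raise DataModelError("min_births must be non-negative")
    df = df.copy()
    df["included"] = df["births_4yr"].astype(int) >= min_births
    df["prm_ratio"] = [
        compute_prm(int(d), int(b)) if inc else float("nan")
        for d, b, inc in zip(df["deaths_4yr"], df["births_4yr"], df["included"])
    ]
    return OutcomeSet(df)
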