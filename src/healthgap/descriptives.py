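"""Weighted frequency distributions, prevalence by characteristic, chi-square.

Weighted counts are sums of sampling weights per level; with weights
normalised to mean 1 these read like sample counts. Chi-square association
tests between each characteristic and the binary outcome use classical
Pearson statistics on unweighted counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalysisDataset, DataError


class DegenerateMarginError(DataError):
    """A contingency-table row or column margin is zero."""


@dataclass
class FrequencyTable:
    """Weighted level counts and percents for one covariate (or the group)."""

    covariate: str
    table: pd.DataFrame  # columns: level, weighted_count, percent
    total_n: float

    def render(self, decimals: int = 1) -> str:
        df = self.table.copy()
        df["weighted_count"] = df["weighted_count"].round(0).astype(int)
        df["percent"] = df["percent"].map(lambda p: _round_half_up(p, decimals))
        return df.to_string(index=False)


@dataclass
class PrevalenceTable:
    """Weighted outcome prevalence per level plus a chi-square association test.

    ``chi2``/``df``/``p_value`` refer to the levels x outcome Pearson test on
    unweighted counts; prevalence uses weighted counts.
    """

    covariate: str
    table: pd.DataFrame  # columns: level, outcome_count, prevalence_percent
    chi2: float
    df: int
    p_value: float

    def render(self, decimals: int = 1) -> str:
        df = self.table.copy()
        df["outcome_count"] = df["outcome_count"].round(0).astype(int)
        df["prevalence_percent"] = df["prevalence_percent"].map(
            lambda p: _round_half_up(p, decimals)
        )
        lines = [df.to_string(index=False)]
        if np.isnan(self.chi2):
            lines.append("chi2 not defined (constant outcome)")
        else:
            lines.append(
                f"chi2 = {_round_half_up(self.chi2, 1)}  (df = {self.df}, "
                f"p {format_p(self.p_value)})"
            )
        return "\n".join(lines)


def _round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, as survey tables conventionally print."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p-value, flooring tiny values as "< 0.001"."""
    return f"< {floor}" if p < floor else f"= {p:.3f}"


def _levels_for(ds: AnalysisDataset, covariate: str) -> list[str]:
    if covariate == ds.schema.group_variable:
        return list(ds.schema.group_levels)
    return list(ds.schema.covariate(covariate).levels)


def weighted_frequency_table(ds: AnalysisDataset, covariate: str) -> FrequencyTable:
    """Weighted count and percent of records at each level of ``covariate``."""
    levels = _levels_for(ds, covariate)
    if not levels:
        raise DataError("empty level set")
    w = ds.weights
    values = ds.data[covariate].to_numpy()
    counts = np.array([w[values == lvl].sum() for lvl in levels])
    total = w.sum()
    return FrequencyTable(
        covariate=covariate,
        table=pd.DataFrame({
            "level": levels,
            "weighted_count": counts,
            "percent": 100.0 * counts / total,
        }),
        total_n=float(total),
    )


def prevalence_by_level(ds: AnalysisDataset, covariate: str) -> PrevalenceTable:
    """Weighted outcome prevalence per level, with a Pearson chi-square test.

    Includes an ``(overall)`` row. Levels with zero total weight get NaN
    prevalence and are flagged by exclusion from the chi-square table.
    """
    levels = _levels_for(ds, covariate)
    w, y = ds.weights, ds.outcome
    values = ds.data[covariate].to_numpy()
    rows, counts = [], []
    for lvl in levels:
        m = values == lvl
        tot = w[m].sum()
        pos = (w[m] * y[m]).sum()
        prev = 100.0 * pos / tot if tot > 0 else np.nan
        rows.append((lvl, pos, prev))
        # chi-square uses unweighted (unit-weight) counts
        counts.append(((y[m] == 1).sum(), (y[m] == 0).sum()))
    rows.append(("(overall)", (w * y).sum(), 100.0 * (w * y).sum() / w.sum()))

    observed = np.array([c for c in counts if sum(c) > 0])
    try:
        chi2, df, p = pearson_chi2(observed)
    except DegenerateMarginError:
        # a constant outcome leaves no association to test
        chi2, df, p = np.nan, len(observed) - 1, np.nan
    return PrevalenceTable(
        covariate=covariate,
        table=pd.DataFrame(rows, columns=["level", "outcome_count",
                                          "prevalence_percent"]),
        chi2=chi2, df=df, p_value=p,
    )


def pearson_chi2(observed: np.ndarray) -> tuple[float, int, float]:
    """Classical Pearson chi-square on a levels x 2 (or r x c) count table.

    Returns ``(statistic, df, p_value)`` with ``df = (rows-1)(cols-1)`` and
    the p-value from the chi-square upper tail; no continuity correction.
    """
    observed = np.asarray(observed, float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise DataError("need an r x c table with at least 2 rows and 2 columns")
    if np.any(observed < 0):
        raise DataError("counts must be non-negative")
    if np.any(observed.sum(axis=1) == 0) or np.any(observed.sum(axis=0) == 0):
        raise DegenerateMarginError("degenerate margin: a row or column sums to zero")
    res = stats.chi2_contingency(observed, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def all_frequency_tables(ds: AnalysisDataset) -> list[FrequencyTable]:
    """Frequency tables for the group variable and every schema covariate."""
    names = [ds.schema.group_variable, *ds.schema.covariate_names]
    return [weighted_frequency_table(ds, n) for n in names]


def all_prevalence_tables(ds: AnalysisDataset) -> list[PrevalenceTable]:
    names = [ds.schema.group_variable, *ds.schema.covariate_names]
    return [prevalence_by_level(ds, n) for n in names]


def frequency_frame(tables: list[FrequencyTable]) -> pd.DataFrame:
    """Stack frequency tables into one machine-readable frame."""
    frames = []
    for t in tables:
        df = t.table.copy()
        df.insert(0, "covariate", t.covariate)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def prevalence_frame(tables: list[PrevalenceTable]) -> pd.DataFrame:
    frames = []
    for t in tables:
        df = t.table.copy()
        df.insert(0, "covariate", t.covariate)
        df["chi2"] = t.chi2
        df["df"] = t.df
        df["p_value"] = t.p_value
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
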