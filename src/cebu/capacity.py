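"""Cell-specific buffering capacity, Bliss synergy and growth-rate fits.

The buffering capacity of a scored pair in one cell line is the cell's
G2 expression relative to a low-expression reference (the 25th percentile
across all cell lines), converted to dependency-score units by the
modified slope:

    capacity  = (expression - percentile_25) / slope_mod
    slope_mod = C-score * sd(G2 expression) / sd(G1 dependency)

Positive capacity: the cell expresses the buffering gene above the
reference, so the buffered gene's loss should be better tolerated there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cebu.datatypes import AlignedDataset

__all__ = [
    "CapacityRecord",
    "slope_mod",
    "buffering_capacity",
    "capacity_table",
    "tissue_mean_capacity",
    "bliss_score",
    "fit_growth_rate",
]


@dataclass(frozen=True)
class CapacityRecord:
    g1: str
    g2: str
    cell_line: str
    expression: float
    q25: float
    slope_mod: float
    capacity: float


def slope_mod(c_score: float, expr_profile, dep_profile) -> float:
    """C-score * sd(expression) / sd(dependency), sample (ddof=1) sds."""
    sd_e = float(np.std(expr_profile, ddof=1))
    sd_d = float(np.std(dep_profile, ddof=1))
    if sd_d == 0 or sd_e == 0:
        raise ValueError("zero-variance profile; slope_mod undefined")
    return c_score * sd_e / sd_d


def buffering_capacity(c_score: float, data: AlignedDataset, g1: str,
                       g2: str, cell_line: str,
                       percentile: float = 25.0) -> CapacityRecord:
    """Capacity of one pair in one cell line.

    ``percentile`` sets the low-expression reference (25 by default;
    shifting it rescales every capacity by a common additive offset, so
    rankings are unaffected).  Percentiles use linear interpolation
    between order statistics.
    """
    expr = data.expression.loc[g2].to_numpy(dtype=float)
    dep = data.dependency.loc[g1].to_numpy(dtype=float)
    sm = slope_mod(c_score, expr, dep)
    if sm == 0:
        raise ValueError("slope_mod is 0; capacity undefined")
    q = float(np.percentile(expr, percentile))
    e = float(data.expression.at[g2, cell_line])
    return CapacityRecord(g1=g1, g2=g2, cell_line=cell_line, expression=e,
                          q25=q, slope_mod=sm,
                          capacity=(e - q) / sm)


def capacity_table(records: pd.DataFrame, data: AlignedDataset,
                   percentile: float = 25.0) -> pd.DataFrame:
    """Capacities for every (scored pair, cell line) combination.

    Vectorised across cell lines; one row per pair per cell line with
    columns g1, g2, cell_line, capacity (plus slope_mod and q25).
    """
    cells = np.asarray(data.cell_lines)
    n = cells.size
    cols: dict[str, list] = {k: [] for k in ("g1", "g2", "expression",
                                             "q25", "slope_mod",
                                             "capacity")}
    for row in records.itertuples():
        expr = data.expression.loc[row.g2].to_numpy(dtype=float)
        dep = data.dependency.loc[row.g1].to_numpy(dtype=float)
        sm = slope_mod(row.c_score, expr, dep)
        q = float(np.percentile(expr, percentile))
        cols["g1"].append(np.repeat(row.g1, n))
        cols["g2"].append(np.repeat(row.g2, n))
        cols["expression"].append(expr)
        cols["q25"].append(np.full(n, q))
        cols["slope_mod"].append(np.full(n, sm))
        cols["capacity"].append((expr - q) / sm)
    if not cols["g1"]:
        return pd.DataFrame(columns=["g1", "g2", "cell_line", "expression",
                                     "q25", "slope_mod", "capacity"])
    out = {k: np.concatenate(v) for k, v in cols.items()}
    out["cell_line"] = np.tile(cells, len(records))
    return pd.DataFrame(out)[["g1", "g2", "cell_line", "expression",
                              "q25", "slope_mod", "capacity"]]


def tissue_mean_capacity(capacities: pd.DataFrame,
                         annotation: pd.Series) -> pd.Series:
    """Mean capacity per tissue over all (pair, cell line) records."""
    tissue = capacities["cell_line"].map(annotation)
    if tissue.isna().any():
        raise ValueError("capacity records reference unannotated cell lines")
    means = capacities.groupby(tissue.rename("tissue"))["capacity"].mean()
    return means.sort_values(ascending=False)


def bliss_score(e_a: float, e_b: float, e_ab: float) -> float:
    """Bliss ratio (E_A + E_B - E_A*E_B) / E_AB on relative growth.

    The effects are relative cell-growth fold-changes under suppression
    of A alone, B alone and both.  A ratio below 1 flags potential
    synergy.  (The classical Bliss model is stated for inhibition
    fractions in [0, 1]; here growth ratios enter the formula directly —
    see docs/methods.md for the caveat.)
    """
    if e_ab == 0:
        raise ValueError("combined effect E_AB must be nonzero")
    return (e_a + e_b - e_a * e_b) / e_ab


def fit_growth_rate(times, confluence) -> dict:
    """Exponential growth rate from a confluence time course.

    Least-squares fit of log(confluence) against time (hours); returns
    the rate (per hour) and the fitted fold-change over the observation
    window.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(confluence, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if (c <= 0).any():
        raise ValueError("confluence must be positive for a log fit")
    rate, intercept = np.polyfit(t, np.log(c), 1)
    window = float(t.max() - t.min())
    return {"rate": float(rate),
            "fold_change": float(np.exp(rate * window)),
            "log_intercept": float(intercept)}
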