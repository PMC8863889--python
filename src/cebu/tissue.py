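"""Tissue specificity and the normalized C-score plot geometry.

tau quantifies how tissue-restricted a gene's expression is:

    tau = sum_i (1 - x_i / x_max) / (N - 1),

over N per-tissue mean expression values x_i (means below 1 log2 TPM are
floored to 0 first).  tau = 0 for uniform expression, 1 for expression in
a single tissue.

The normalized C-score plot maps each cell line of a pair onto
[-1, 0] x [0, 1] by rank-normalising G1 dependency (most essential -> -1)
and G2 expression (highest -> 1), then slices the quadrant into nine
equal 10-degree sectors R1..R9 radiating from the origin: R1 hugs the
expression axis (high expression, weak dependency — strong buffering),
R9 hugs the dependency axis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from cebu.datatypes import AlignedDataset
from cebu.cscore import benjamini_hochberg

__all__ = [
    "compute_tau",
    "tau_contrast",
    "normalize_pair_plot",
    "assign_region",
    "region_tissue_enrichment",
]

TAU_EXPRESSION_FLOOR = 1.0  #: per-tissue means below this log2 TPM count as 0


def compute_tau(expression: pd.DataFrame, annotation: pd.Series,
                floor: float = TAU_EXPRESSION_FLOOR) -> pd.DataFrame:
    """Tissue-specificity tau per gene.

    Cell lines are grouped by tissue and expression averaged within each
    tissue; means below ``floor`` are set to 0 before applying the
    formula.  Genes whose thresholded means are all 0 have undefined tau
    (NaN, flagged in the ``defined`` column).

    Returns a DataFrame indexed by gene with columns ``tau``,
    ``n_tissues``, ``x_max`` and ``defined``.
    """
    annotation = annotation.reindex(expression.columns)
    if annotation.isna().any():
        raise ValueError("every expression cell line needs a tissue label")
    tissues = annotation.unique()
    if len(tissues) < 2:
        raise ValueError("tau requires at least 2 tissues (N - 1 > 0)")
    means = expression.T.groupby(annotation).mean().T  # gene x tissue
    x = means.to_numpy(copy=True)
    x[x < floor] = 0.0
    x_max = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / x_max[:, None]).sum(axis=1) / (n - 1)
    defined = x_max > 0
    tau[~defined] = np.nan
    return pd.DataFrame({"tau": tau, "n_tissues": n, "x_max": x_max,
                         "defined": defined}, index=expression.index)


def tau_contrast(g1_taus, g2_taus) -> dict:
    """Paired-t contrast of tau between the G2 and G1 of each pair.

    Positive mean difference = G2 (buffering) more tissue-specific than
    G1 (buffered), the expected direction.  Returns mean_diff, t, p, n.
    """
    g1 = np.asarray(g1_taus, dtype=float)
    g2 = np.asarray(g2_taus, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("paired tau vectors must have equal length")
    diff = g2 - g1
    if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
        return {"mean_diff": 0.0, "t": 0.0, "p": 1.0, "n": diff.size}
    t, p = stats.ttest_rel(g2, g1)
    return {"mean_diff": float(diff.mean()), "t": float(t), "p": float(p),
            "n": diff.size}


def normalize_pair_plot(g1_profile, g2_profile) -> pd.DataFrame:
    """Rank-normalise a pair's profiles onto [-1, 0] x [0, 1].

    x_norm: the most negative dependency score maps to -1, the least to
    0.  y_norm: the lowest expression maps to 0, the highest to 1.  Ties
    take average ranks.  Constant profiles are rejected.
    """
    x = np.asarray(g1_profile, dtype=float)
    y = np.asarray(g2_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile cannot be rank-normalised")
    n = x.size
    x_norm = -1.0 + (stats.rankdata(x) - 1.0) / (n - 1)
    y_norm = (stats.rankdata(y) - 1.0) / (n - 1)
    return pd.DataFrame({"x_norm": x_norm, "y_norm": y_norm})


_BOUNDARY_SNAP = 1e-9  #: degrees; snap fp-noise onto exact sector borders


def assign_region(x_norm, y_norm) -> np.ndarray:
    """Sector R1..R9 of normalized points, radiating from the origin.

    theta is the angle from the positive-y (expression) axis toward the
    negative-x (dependency) axis; sector k covers ((k-1)*10, k*10]
    degrees, so boundary angles at exact multiples of 10 degrees belong
    to the lower-index region.  The origin is unassignable and yields 0.
    """
    x = np.atleast_1d(np.asarray(x_norm, dtype=float))
    y = np.atleast_1d(np.asarray(y_norm, dtype=float))
    if ((x < -1) | (x > 0)).any() or ((y < 0) | (y > 1)).any():
        raise ValueError("points must lie in [-1, 0] x [0, 1]")
    theta = np.degrees(np.arctan2(-x, y))
    # snap angles a hair above a sector border back onto it
    nearest = np.round(theta / 10.0) * 10.0
    theta = np.where(np.abs(theta - nearest) < _BOUNDARY_SNAP, nearest,
                     theta)
    region = np.ceil(theta / 10.0).astype(int)
    region = np.clip(region, 1, 9)
    region[(x == 0) & (y == 0)] = 0
    if np.isscalar(x_norm) and np.isscalar(y_norm):
        return int(region[0])
    return region


def region_tissue_enrichment(records: pd.DataFrame, data: AlignedDataset,
                             cutoff: float = 0.25,
                             alpha: float = 0.05,
                             min_tissue_size: int = 3) -> pd.DataFrame:
    """Region x tissue share of enriched pairs (percentage heatmap).

    For every pair above ``cutoff``, each cell line is placed in a region
    of the pair's normalized plot.  A pair is *enriched* for
    (region, tissue) when that tissue's cell lines are over-represented
    among the cell lines in the region (upper-tail hypergeometric over
    all cell lines), at BH-adjusted p < ``alpha`` within the region.
    The returned 9 x tissue table gives, per region, each tissue's share
    of enriched pairs; rows sum to 100 where any pair is enriched.
    """
    ann = data.annotation
    sizes = ann.value_counts()
    small = sizes[sizes < min_tissue_size]
    if len(small):
        import logging
        logging.getLogger(__name__).warning(
            "excluding tissues with < %d cell lines: %s", min_tissue_size,
            list(small.index))
    tissues = sorted(sizes[sizes >= min_tissue_size].index)
    cells_total = data.n_cell_lines
    tissue_codes = pd.Categorical(ann, categories=tissues).codes
    kept = records[records["c_score"] >= cutoff]
    if kept.empty:
        raise ValueError("no pair above cutoff")

    dep = data.dependency
    expr = data.expression
    n_tissue = len(tissues)
    tissue_sizes = np.array([int(sizes[t]) for t in tissues])
    valid = tissue_codes >= 0
    # one hypergeometric test per (pair, region, tissue) with k > 0,
    # assembled into flat arrays and evaluated in a single vectorised call
    t_region, t_tissue, t_k, t_n = [], [], [], []
    for row in kept.itertuples():
        norm = normalize_pair_plot(dep.loc[row.g1].to_numpy(),
                                   expr.loc[row.g2].to_numpy())
        regions = assign_region(norm["x_norm"].to_numpy(),
                                norm["y_norm"].to_numpy())
        counts = np.zeros((10, n_tissue), dtype=int)
        np.add.at(counts, (regions[valid], tissue_codes[valid]), 1)
        n_region = counts.sum(axis=1)
        for r in range(1, 10):
            if n_region[r] == 0:
                continue
            hit = np.nonzero(counts[r])[0]
            t_region.extend([r] * hit.size)
            t_tissue.extend(hit)
            t_k.extend(counts[r, hit])
            t_n.extend([n_region[r]] * hit.size)

    t_region = np.asarray(t_region)
    t_tissue = np.asarray(t_tissue)
    pvals = stats.hypergeom.sf(np.asarray(t_k) - 1, cells_total,
                               tissue_sizes[t_tissue], np.asarray(t_n))

    shares = pd.DataFrame(0.0, index=pd.RangeIndex(1, 10, name="region"),
                          columns=tissues)
    for r in range(1, 10):
        mask = t_region == r
        if not mask.any():
            continue
        enriched = benjamini_hochberg(pvals[mask]) < alpha
        total = int(enriched.sum())
        if total == 0:
            continue
        counts_per_tissue = np.bincount(t_tissue[mask][enriched],
                                        minlength=n_tissue)
        shares.loc[r] = counts_per_tissue * 100.0 / total
    return shares
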