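"""Validation of buffering predictions against external ground truths.

Two ground-truth families:

* combinatorial-screen genetic interactions (GI): a negative GI score
  marks a buffering (synthetic-sick) pair.  Each experimental pair is
  assigned the larger of its two directional C-scores (either gene can
  play G1), then capacity/score performance is read off ROC curves and
  a rank-based Mann-Whitney test.
* expression-based patient prognosis: genes whose higher expression
  carries a significantly positive Cox coefficient (poorer prognosis)
  should show higher tissue-matched buffering capacity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from cebu.cscore import benjamini_hochberg
from cebu.datatypes import PairList

logger = logging.getLogger(__name__)

__all__ = [
    "assign_pair_cscore",
    "roc_auc",
    "capacity_gi_correlation",
    "prognosis_auc",
]


def assign_pair_cscore(gi: PairList, records: pd.DataFrame) -> pd.DataFrame:
    """Label GI rows and attach the max directional C-score.

    Each row of the GI table is looked up in both orientations
    ((a buffered by b) and (b buffered by a)); the larger C-score wins,
    a missing orientation counts as -inf, and rows absent in both
    orientations are dropped (with a logged count).  ``label`` is True
    for strictly negative GI scores (buffering); a GI score of exactly 0
    is non-buffering.
    """
    index: dict[tuple[str, str], float] = {
        (g1, g2): c for g1, g2, c in zip(records["g1"], records["g2"],
                                         records["c_score"])}
    rows = []
    dropped = 0
    for row in gi.table.itertuples():
        fwd = index.get((row.gene_a, row.gene_b), -np.inf)
        rev = index.get((row.gene_b, row.gene_a), -np.inf)
        c = max(fwd, rev)
        if not np.isfinite(c):
            dropped += 1
            continue
        rows.append({"cell_line": row.cell_line, "gene_a": row.gene_a,
                     "gene_b": row.gene_b, "gi_score": float(row.score),
                     "assigned_cscore": c,
                     "label": bool(row.score < 0)})
    if dropped:
        logger.info("%d GI pairs absent from the scored set in both "
                    "orientations; dropped", dropped)
    return pd.DataFrame(rows)


def roc_auc(scores, labels) -> dict:
    """AUC by the rank (Mann-Whitney) formulation with tie correction.

    One-sided p-value for AUC > 0.5 (positives score higher).  Both
    classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative examples")
    res = stats.mannwhitneyu(s[y], s[~y], alternative="greater")
    return {"auc": float(res.statistic / (n_pos * n_neg)),
            "p": float(res.pvalue), "n_pos": n_pos, "n_neg": n_neg}


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) points of the ROC curve, threshold descending."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    tpr = np.concatenate([[0.0], np.cumsum(y) / max(y.sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(~y) / max((~y).sum(), 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def capacity_gi_correlation(capacities: pd.DataFrame, gi: pd.DataFrame,
                            cutoff: float = 0.25) -> dict:
    """Pearson correlation between capacity and GI score above a cutoff.

    ``gi`` is the output of :func:`assign_pair_cscore`; records are
    matched on (gene_a, gene_b, cell_line) against the capacity table in
    either orientation, restricted to assigned_cscore >= cutoff.  Under
    buffering, stronger (more negative) GI should coincide with larger
    capacity, so the expected correlation is negative.
    """
    selected = gi[gi["assigned_cscore"] >= cutoff]
    cap_index = {(r.g1, r.g2, r.cell_line): r.capacity
                 for r in capacities.itertuples()}
    xs, ys = [], []
    for row in selected.itertuples():
        cap = cap_index.get((row.gene_a, row.gene_b, row.cell_line))
        if cap is None:
            cap = cap_index.get((row.gene_b, row.gene_a, row.cell_line))
        if cap is not None:
            xs.append(cap)
            ys.append(row.gi_score)
    if len(xs) < 3:
        raise ValueError("fewer than 3 matched (capacity, GI) records")
    if np.ptp(ys) == 0 or np.ptp(xs) == 0:
        raise ValueError("zero variance in matched records; correlation "
                         "undefined")
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n": len(xs)}


def per_gene_capacity(capacities: pd.DataFrame, annotation: pd.Series,
                      tissue: str, records: pd.DataFrame, cutoff: float,
                      aggregate: str = "max") -> pd.Series:
    """Tissue-matched capacity per G2 gene.

    For each gene appearing as G2 in pairs with C-score >= cutoff, take
    the mean capacity over the tissue's cell lines for each pair, then
    aggregate across its pairs (max by default, mean optional).
    """
    qualifying = set(records.loc[records["c_score"] >= cutoff, "g2"])
    cells = annotation.index[annotation == tissue]
    sub = capacities[capacities["cell_line"].isin(set(cells))
                     & capacities["g2"].isin(qualifying)]
    per_pair = sub.groupby(["g2", "g1"])["capacity"].mean()
    if per_pair.empty:
        return pd.Series(dtype=float)
    agg = {"max": "max", "mean": "mean"}[aggregate]
    return per_pair.groupby("g2").agg(agg)


def prognosis_auc(prognosis: pd.DataFrame, capacities: pd.DataFrame,
                  annotation: pd.Series, records: pd.DataFrame,
                  cancer_tissue: dict[str, str], cutoffs,
                  min_positive: int = 50, significance: float = 0.1,
                  aggregate: str = "max") -> pd.DataFrame:
    """Survival-prediction AUC per cancer type and C-score cutoff.

    Labels: gene has positive Cox sign AND adjusted p below
    ``significance`` (poorer prognosis with higher expression).  Scores:
    tissue-matched per-gene buffering capacity.  Cancers with fewer than
    ``min_positive`` positive genes are skipped; Mann-Whitney p-values
    are BH-adjusted across all (cancer, cutoff) results.
    """
    rows = []
    for cancer, sub in prognosis.groupby("cancer_type"):
        tissue = cancer_tissue.get(cancer)
        if tissue is None:
            logger.info("cancer %s has no matched tissue; skipped", cancer)
            continue
        labels_all = ((sub["cox_sign"] > 0)
                      & (sub["adjusted_p"] < significance))
        n_pos = int(labels_all.sum())
        if n_pos < min_positive:
            logger.info("cancer %s skipped: only %d positive genes",
                        cancer, n_pos)
            continue
        for cutoff in cutoffs:
            cap = per_gene_capacity(capacities, annotation, tissue,
                                    records, cutoff, aggregate)
            matched = sub[sub["gene"].isin(cap.index)]
            if matched.empty:
                continue
            y = ((matched["cox_sign"] > 0)
                 & (matched["adjusted_p"] < significance)).to_numpy()
            if y.all() or not y.any():
                continue
            s = cap.loc[matched["gene"]].to_numpy()
            res = roc_auc(s, y)
            rows.append({"cancer_type": cancer, "cutoff": cutoff,
                         "auc": res["auc"], "p": res["p"],
                         "n_pos": int(y.sum()),
                         "n_neg": int((~y).sum())})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out
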