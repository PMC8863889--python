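"""Synthetic DepMap-like data with planted expression-buffering structure.

The generator emulates the statistical skeleton of a dependency screen
crossed with an expression panel: cell lines fall into tissue blocks, each
expression gene has a tissue-specific mean (tissue-blocked expression),
and a subset of (G1, G2) pairs is planted so that the G1 dependency score
tracks the G2 expression linearly.  Dependency is generated *conditional
on* expression,

    D = intercept + (E - mean(E)) / true_slope + Normal(0, dep_noise),

so the slope of expression regressed on dependency is a directly
controlled, recoverable parameter.  Background G1s are pure noise around a
negative baseline, independent of every G2.  No attempt is made to mimic
real DepMap marginal distributions, copy-number structure or mutations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cebu.datatypes import AlignedDataset, PairList, SyntheticConfig, SyntheticTruth

__all__ = ["generate", "emit_ground_truths"]


def generate(config: SyntheticConfig) -> tuple[AlignedDataset, SyntheticTruth]:
    """Generate an aligned dataset with planted buffering pairs.

    Pair i of the planted set couples dependency gene ``G1_i`` with
    expression gene ``G2_i``.  All randomness flows from one generator
    seeded with ``config.seed``: identical configs give bit-identical
    output.

    Returns
    -------
    (AlignedDataset, SyntheticTruth)
        Dataset plus the planted-pair table, tissue assignment and
        per-gene tissue means needed to recompute expected regressions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cells = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    tissues = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    # contiguous tissue blocks, remainder spread over the first blocks
    assignment = np.sort(np.arange(config.n_cell_lines) % config.n_tissues)
    tissue_of = pd.Series([tissues[t] for t in assignment], index=cells,
                          name="tissue_type")

    g1_genes = [f"G1_{i:04d}" for i in range(config.n_g1)]
    g2_genes = [f"G2_{i:04d}" for i in range(config.n_g2)]

    # tissue-specific expression means, floored at 0 like the data they mimic
    mean_values = (config.expression_baseline
                   + rng.normal(0.0, config.tissue_effect_sd,
                                size=(config.n_g2, config.n_tissues)))
    # the first tissue is the designated high-buffering tissue: planted
    # G2s express higher there, giving it the largest buffering capacity
    boosted = tissues[0] if config.n_planted_pairs else None
    mean_values[:config.n_planted_pairs, 0] += config.tissue_boost
    tissue_means = pd.DataFrame(np.maximum(mean_values, 0.0),
                                index=g2_genes, columns=tissues)

    expr = (tissue_means.to_numpy()[:, assignment]
            + rng.normal(0.0, config.expression_noise_sd,
                         size=(config.n_g2, config.n_cell_lines)))
    np.maximum(expr, 0.0, out=expr)

    dep = (config.baseline_dependency
           + rng.normal(0.0, config.dependency_noise_sd,
                        size=(config.n_g1, config.n_cell_lines)))

    planted_rows = []
    for i in range(config.n_planted_pairs):
        e = expr[i]
        intercept = config.baseline_dependency
        dep[i] = (intercept + (e - e.mean()) / config.planted_slope
                  + rng.normal(0.0, config.dependency_noise_sd,
                               size=config.n_cell_lines))
        planted_rows.append((g1_genes[i], g2_genes[i],
                             config.planted_slope, intercept))

    planted = pd.DataFrame(planted_rows,
                           columns=["g1", "g2", "true_slope",
                                    "true_intercept"])
    dataset = AlignedDataset(
        pd.DataFrame(dep, index=g1_genes, columns=cells),
        pd.DataFrame(expr, index=g2_genes, columns=cells),
        tissue_of)
    truth = SyntheticTruth(planted=planted, tissue_of=tissue_of,
                           tissue_means=tissue_means,
                           boosted_tissue=boosted)
    return dataset, truth


def emit_ground_truths(truth: SyntheticTruth, config: SyntheticConfig,
                       fraction_duplicated: float = 0.5,
                       gi_sd: float = 0.1,
                       planted_gi_mean: float = -0.5,
                       n_background_gi: int = 200,
                       prognosis_p: float = 0.01,
                       seed: int | None = None) -> dict[str, PairList | pd.DataFrame]:
    """Companion ground-truth tables for a generated dataset.

    * ``duplicated``: the first ``fraction_duplicated`` share of planted
      pairs flagged as duplicated genes.
    * ``gi``: a genetic-interaction table; planted pairs draw negative GI
      scores (mean ``planted_gi_mean``) in their higher-expression cell
      lines, background pairs draw scores centred on 0.
    * ``prognosis``: planted G2s marked as poorer prognosis (positive Cox
      sign) with adjusted p ``prognosis_p``; background G2s nonsignificant.
    """
    if not 0.0 <= fraction_duplicated <= 1.0:
        raise ValueError("fraction_duplicated must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    planted = truth.planted

    n_dup = int(round(fraction_duplicated * len(planted)))
    dup = planted.iloc[:n_dup][["g1", "g2"]].rename(
        columns={"g1": "gene_a", "g2": "gene_b"})
    duplicated = PairList(dup, kind="duplicated")

    cells = truth.tissue_of.index.to_numpy()
    gi_rows = []
    for _, row in planted.iterrows():
        # pick one higher-expression cell line per planted pair
        means = truth.tissue_means.loc[row.g2]
        best_tissue = means.idxmax()
        pool = cells[truth.tissue_of.to_numpy() == best_tissue]
        cl = pool[rng.integers(len(pool))]
        gi_rows.append((cl, row.g1, row.g2,
                        rng.normal(planted_gi_mean, gi_sd)))
    all_g1 = [f"G1_{i:04d}" for i in range(config.n_g1)]
    all_g2 = [f"G2_{i:04d}" for i in range(config.n_g2)]
    planted_set = truth.planted_pairs
    n_bg = 0
    while n_bg < n_background_gi:
        a = all_g1[rng.integers(config.n_g1)]
        b = all_g2[rng.integers(config.n_g2)]
        if (a, b) in planted_set:
            continue
        cl = cells[rng.integers(len(cells))]
        gi_rows.append((cl, a, b, rng.normal(0.0, gi_sd)))
        n_bg += 1
    gi = PairList(pd.DataFrame(gi_rows, columns=["cell_line", "gene_a",
                                                 "gene_b", "score"]),
                  kind="gi")

    planted_g2 = set(planted["g2"])
    prog_rows = []
    for g in all_g2:
        if g in planted_g2:
            prog_rows.append(("synthetic_cancer", g, +1, prognosis_p))
        else:
            prog_rows.append(("synthetic_cancer", g,
                              int(rng.choice([-1, 1])),
                              float(rng.uniform(0.2, 1.0))))
    prognosis = pd.DataFrame(prog_rows, columns=["cancer_type", "gene",
                                                 "cox_sign", "adjusted_p"])
    return {"duplicated": duplicated, "gi": gi, "prognosis": prognosis}
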