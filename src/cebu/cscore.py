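"""C-score model: candidate filtering, per-pair regression, slope_min,
genome-wide scoring, shuffled-expression null and significance.

The C-score of a directed pair (G1 buffered, G2 buffering) is

    C = rho * (1 + b * slope_min / slope),

with rho the Pearson correlation of G1 dependency vs G2 expression and
slope the least-squares slope of expression regressed on dependency.
Because slope = rho * sd(expr) / sd(dep), the score is equivalently

    C = rho + b * slope_min * sd(dep) / sd(expr)        (rho != 0),

a rank-one offset per pair that the matrix path uses: it is numerically
stable near rho = 0 and lets a G1-block x all-G2 score matrix be computed
with one standardized matrix product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cebu.datatypes import AlignedDataset, NullModel, PairRegression

logger = logging.getLogger(__name__)

__all__ = [
    "filter_candidates",
    "pair_regression",
    "compute_slope_min",
    "compute_cscore",
    "CScoreModel",
    "CScoreResults",
]

MIN_EXPRESSION = 0.5  #: log2 TPM floor for a gene to count as expressed (G2)


def filter_candidates(data: AlignedDataset,
                      min_expression: float = MIN_EXPRESSION
                      ) -> tuple[list[str], list[str]]:
    """Select buffered (G1) and buffering (G2) candidate genes.

    G1s are dependency genes with strictly negative mean dependency score;
    G2s are expression genes with mean expression >= ``min_expression``
    log2 TPM.  A mean dependency of exactly 0 is excluded.
    """
    g1 = data.dependency.index[data.dependency.mean(axis=1) < 0].tolist()
    g2 = data.expression.index[
        data.expression.mean(axis=1) >= min_expression].tolist()
    if not g1:
        raise ValueError("no G1 candidates (all mean dependency scores >= 0)")
    if not g2:
        raise ValueError("no G2 candidates (all mean expression below "
                         f"{min_expression} log2 TPM)")
    return g1, g2


def pair_regression(g1_profile: np.ndarray, g2_profile: np.ndarray,
                    g1: str = "G1", g2: str = "G2") -> PairRegression:
    """Pearson correlation and OLS slope of expression on dependency.

    ``g1_profile`` is the dependency vector (x), ``g2_profile`` the
    expression vector (y); slope is in log2 TPM per dependency unit.
    """
    x = np.asarray(g1_profile, dtype=float)
    y = np.asarray(g2_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 cell lines")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"zero-variance profile for pair ({g1}, {g2})")
    res = stats.pearsonr(x, y)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    return PairRegression(g1=g1, g2=g2, rho=float(res.statistic),
                          slope=float(slope), p_rho=float(res.pvalue), n=n)


def compute_slope_min(regressions, alpha: float = 0.05) -> float:
    """Minimum slope over pairs with a significant positive correlation.

    Pairs qualify when rho > 0 and the two-sided correlation p-value is
    below ``alpha`` (no multiplicity correction, by design: this is a
    normaliser, not a test).
    """
    slopes = [r.slope for r in regressions if r.rho > 0 and r.p_rho < alpha]
    if not slopes:
        raise ValueError("no pair with a significant positive correlation")
    return float(min(slopes))


def compute_cscore(reg: PairRegression, slope_min: float,
                   b: float = 1.0) -> dict:
    """Score one pair: C = rho * (1 + b * slope_min / slope)."""
    if reg.slope == 0:
        raise ValueError(f"slope is 0 for pair ({reg.g1}, {reg.g2}); "
                         "C-score undefined")
    c = reg.rho * (1.0 + b * slope_min / reg.slope)
    return {"g1": reg.g1, "g2": reg.g2, "c_score": float(c), "rho": reg.rho,
            "slope": reg.slope, "b": b, "slope_min_used": slope_min,
            "n": reg.n}


# --------------------------------------------------------------------------
# vectorised internals


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centred and scaled to unit population norm; returns (Z, sd1)
    with sd1 the sample (ddof=1) standard deviation per row."""
    centred = values - values.mean(axis=1, keepdims=True)
    norm = np.sqrt((centred ** 2).sum(axis=1))
    sd1 = norm / np.sqrt(values.shape[1] - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centred / norm[:, None]
    return z, sd1


def _rho_critical(n: int, alpha: float) -> float:
    """Two-sided Pearson significance threshold on |rho| at level alpha."""
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit ** 2))


class CScoreModel:
    """Genome-wide expression-buffering screen over an aligned dataset.

    Parameters
    ----------
    data : AlignedDataset
        Dependency + expression panels on a shared cell-line axis.
    b : float
        Weight of the normalized-slope term (1 for pan-cancer analysis;
        0 collapses the score to the Pearson correlation).
    alpha : float
        Two-sided significance level defining the slope_min pair set.
    min_expression : float
        Mean-expression floor for G2 candidates (log2 TPM).

    Examples
    --------
    >>> model = CScoreModel(dataset, b=1.0)
    >>> results = model.fit(threshold=0.25)
    >>> null = model.fit_null(n_shuffles=5, seed=17,
    ...                       slope_min=results.slope_min)
    >>> results.add_significance(null)
    >>> print(results.summary())
    """

    def __init__(self, data: AlignedDataset, b: float = 1.0,
                 alpha: float = 0.05,
                 min_expression: float = MIN_EXPRESSION,
                 block_size: int = 512):
        self.data = data
        self.b = b
        self.alpha = alpha
        self.block_size = block_size
        self.g1_genes, self.g2_genes = filter_candidates(data, min_expression)
        n = data.n_cell_lines
        if n < 3:
            raise ValueError("need at least 3 aligned cell lines")
        self._dep = data.dependency.loc[self.g1_genes].to_numpy(float)
        self._expr = data.expression.loc[self.g2_genes].to_numpy(float)
        self._n = n
        # self-pair mask applies only where a gene is both G1 and G2
        g2_pos = {g: j for j, g in enumerate(self.g2_genes)}
        self._self_pairs = [(i, g2_pos[g])
                            for i, g in enumerate(self.g1_genes)
                            if g in g2_pos]

    # -- low-level blockwise sweep -------------------------------------

    def _sweep(self, expr: np.ndarray):
        """Yield (i0, rho_block, slope_block) over G1 row blocks.

        Constant profiles produce NaN rho/slope and are excluded
        downstream.  Self-pairs are set to NaN.
        """
        zd, sd_d = _standardize(self._dep)
        ze, sd_e = _standardize(expr)
        self_pairs = dict()
        for i, j in self._self_pairs:
            self_pairs.setdefault(i, []).append(j)
        for i0 in range(0, len(self.g1_genes), self.block_size):
            i1 = min(i0 + self.block_size, len(self.g1_genes))
            rho = zd[i0:i1] @ ze.T
            np.clip(rho, -1.0, 1.0, out=rho)
            with np.errstate(invalid="ignore", divide="ignore"):
                slope = rho * (sd_e[None, :] / sd_d[i0:i1, None])
            for i in range(i0, i1):
                for j in self_pairs.get(i, ()):
                    rho[i - i0, j] = np.nan
                    slope[i - i0, j] = np.nan
            yield i0, rho, slope

    def _slope_min(self, expr: np.ndarray) -> float:
        """slope_min over the full pair universe for a given expression
        panel (self-pairs excluded first)."""
        rcrit = _rho_critical(self._n, self.alpha)
        best = np.inf
        for _, rho, slope in self._sweep(expr):
            qual = rho > rcrit
            if qual.any():
                best = min(best, float(np.nanmin(np.where(qual, slope,
                                                          np.inf))))
        if not np.isfinite(best):
            raise ValueError("no pair with a significant positive "
                             "correlation; slope_min undefined")
        return best

    def _cscores(self, expr: np.ndarray, slope_min: float):
        """Yield (i0, c) blocks: c = rho + b*slope_min*sd_d/sd_e."""
        _, sd_d = _standardize(self._dep)
        _, sd_e = _standardize(expr)
        with np.errstate(invalid="ignore", divide="ignore"):
            offsets = self.b * slope_min * (sd_d[:, None] / sd_e[None, :])
        for i0, rho, slope in self._sweep(expr):
            c = rho + offsets[i0:i0 + rho.shape[0]]
            c[np.isnan(slope)] = np.nan
            yield i0, c, rho, slope

    # -- public API ----------------------------------------------------

    def fit(self, threshold: float = 0.25,
            slope_min: float | None = None) -> "CScoreResults":
        """Score every (G1, G2) pair and materialise records >= threshold.

        slope_min is computed once from the same pair universe unless
        supplied.  The full score universe is streamed blockwise;
        ``threshold=-inf`` materialises everything (feasible only for
        small panels).
        """
        if slope_min is None:
            slope_min = self._slope_min(self._expr)
        frames = []
        n_scored = 0
        for i0, c, rho, slope in self._cscores(self._expr, slope_min):
            n_scored += np.isfinite(c).sum()
            keep = np.nonzero(np.isfinite(c) & (c >= threshold))
            if keep[0].size:
                frames.append(pd.DataFrame({
                    "g1": np.asarray(self.g1_genes)[keep[0] + i0],
                    "g2": np.asarray(self.g2_genes)[keep[1]],
                    "c_score": c[keep], "rho": rho[keep],
                    "slope": slope[keep]}))
        records = (pd.concat(frames, ignore_index=True) if frames
                   else pd.DataFrame(columns=["g1", "g2", "c_score", "rho",
                                              "slope"]))
        records = records.sort_values("c_score", ascending=False,
                                      kind="mergesort",
                                      ignore_index=True)
        records["b"] = self.b
        records["slope_min_used"] = slope_min
        return CScoreResults(self, records, slope_min=slope_min,
                             threshold=threshold, n_scored=int(n_scored))

    def score_universe(self, slope_min: float | None = None) -> pd.DataFrame:
        """Dense score table for every pair (small panels only)."""
        res = self.fit(threshold=-np.inf, slope_min=slope_min)
        return res.records

    def fit_null(self, n_shuffles: int = 5, seed: int = 0,
                 slope_min: float | None = None) -> NullModel:
        """Shuffled-expression null: each G2's expression values are
        permuted independently across cell lines, C-scores recomputed with
        the real-data slope_min, and a normal distribution fitted to the
        pooled shuffled scores."""
        if n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if slope_min is None:
            slope_min = self._slope_min(self._expr)
        rng = np.random.default_rng(seed)
        pooled_n = 0
        pooled_sum = 0.0
        pooled_sq = 0.0
        per_shuffle = []
        for _ in range(n_shuffles):
            shuffled = self._expr.copy()
            for row in shuffled:
                rng.shuffle(row)
            s_n, s_sum, s_sq = 0, 0.0, 0.0
            for _, c, _, _ in self._cscores(shuffled, slope_min):
                v = c[np.isfinite(c)]
                s_n += v.size
                s_sum += v.sum()
                s_sq += (v ** 2).sum()
            mu_i = s_sum / s_n
            var_i = s_sq / s_n - mu_i ** 2
            per_shuffle.append((float(mu_i), float(np.sqrt(var_i))))
            pooled_n += s_n
            pooled_sum += s_sum
            pooled_sq += s_sq
        mu = pooled_sum / pooled_n
        sigma = float(np.sqrt(pooled_sq / pooled_n - mu ** 2))
        return NullModel(mu=float(mu), sigma=sigma, n_shuffles=n_shuffles,
                         n_samples=int(pooled_n), per_shuffle=per_shuffle)


class CScoreResults:
    """Fitted screen: scored records, slope_min and significance.

    ``records`` is a DataFrame with columns g1, g2, c_score, rho, slope
    (plus p and q after :meth:`add_significance`), sorted by descending
    C-score.
    """

    def __init__(self, model: CScoreModel, records: pd.DataFrame,
                 slope_min: float, threshold: float, n_scored: int):
        self.model = model
        self.records = records
        self.slope_min = slope_min
        self.threshold = threshold
        self.n_scored = n_scored
        self.null: NullModel | None = None

    def add_significance(self, null: NullModel) -> "CScoreResults":
        """Attach upper-tail normal p-values and Benjamini-Hochberg q."""
        self.null = null
        p = np.asarray(null.sf(self.records["c_score"].to_numpy()))
        self.records["p"] = p
        self.records["q"] = benjamini_hochberg(p)
        return self

    def lookup(self, g1: str, g2: str) -> float:
        """C-score of a directed pair; NaN when not materialised."""
        hit = self.records[(self.records["g1"] == g1)
                           & (self.records["g2"] == g2)]
        return float(hit["c_score"].iloc[0]) if len(hit) else float("nan")

    def summary(self) -> str:
        lines = [
            "C-score screen summary",
            "=" * 46,
            f"cell lines           {self.model.data.n_cell_lines:>10d}",
            f"G1 candidates        {len(self.model.g1_genes):>10d}",
            f"G2 candidates        {len(self.model.g2_genes):>10d}",
            f"pairs scored         {self.n_scored:>10d}",
            f"slope_min            {self.slope_min:>10.5g}",
            f"b                    {self.model.b:>10.3g}",
            f"threshold            {self.threshold:>10.3g}",
            f"records kept         {len(self.records):>10d}",
        ]
        if self.null is not None:
            lines += [
                f"null mu              {self.null.mu:>10.4g}",
                f"null sigma           {self.null.sigma:>10.4g}",
                f"records q < 0.05     {int((self.records['q'] < 0.05).sum()):>10d}",
            ]
        if len(self.records):
            top = self.records.iloc[0]
            lines.append(f"top pair             {top.g1}->{top.g2} "
                         f"(C = {top.c_score:.3f})")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
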