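# Methods

## Model

The screen asks, for every ordered gene pair (G1, G2), whether the
knockout dependency of G1 across cell lines is linearly coupled to the
expression of G2. Writing x for the G1 dependency profile (CERES-style
score, more negative = more essential) and y for the G2 expression profile
(log2(TPM+1)), the per-pair regression is of **y on x**: ρ is the Pearson
correlation and slope = cov(x, y)/var(x), in log2 TPM per dependency unit.
The index is

    C = ρ · (1 + b · slope_min / slope),

where slope_min is the minimum slope among pairs with ρ > 0 and an
unadjusted two-sided correlation p < α (α = 0.05 by default, configurable).
slope_min is a normaliser, not a test, hence no multiplicity correction.
Because slope = ρ · sd(y)/sd(x), the index is algebraically

    C = ρ + b · slope_min · sd(x)/sd(y)     (ρ ≠ 0),

a per-pair constant offset added to the correlation. The implementation
uses this identity: it is stable as ρ → 0 (the ρ·slope_min/slope form is
0/0-like) and lets a whole G1-block × G2 score matrix be computed as one
standardized matrix product plus a rank-one offset. A pair with exactly
zero slope (a constant profile) is undefined and excluded; candidate
filters require mean(x) < 0 (strictly — a mean of exactly 0 is out) and
mean(y) ≥ 0.5 log2 TPM; self-pairs are excluded before slope_min is
computed.

Directionality matters: (G1 buffered by G2) and (G2 buffered by G1) are
different regressions with different C-scores; consumers that need one
number per unordered pair (the genetic-interaction validation) take the
maximum of the two orientations.

## Null model and significance

The null shuffles each G2's expression values independently across cell
lines (preserving every gene's expression multiset and hence its sd),
recomputes all C-scores with the *real-data* slope_min, pools the scores of
all shuffles (5 by default) and fits a normal distribution by moments.
Per-shuffle moments are retained for inspection. p is the upper-tail
probability of a real C-score under this normal; q is Benjamini–Hochberg
across the evaluated set. With b = 1 the null mean is not zero: it equals
the average of the deterministic offsets b·slope_min·sd(x)/sd(y), which
shuffling cannot remove. Calibration is unaffected — the offset enters real
and shuffled scores identically, so on structureless data ~5% of pairs fall
below p = 0.05. The b = 0 collapse (a pure Pearson screen) has a null
centred on zero, which is the cleaner diagnostic of shuffling itself.

## Synthetic study conditions

The generator emulates the statistical skeleton of a dependency screen
crossed with an expression panel. Defaults (one `SyntheticConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| n_cell_lines | 200 | cells, split into contiguous tissue blocks |
| n_tissues | 10 | tissue labels |
| n_g1 × n_g2 | 100 × 100 | pair universe of 10,000 (disjoint namespaces, no self-pairs) |
| n_planted_pairs | 50 | pair i couples G1_i with G2_i |
| planted_slope | 0.01 | log2 TPM per dependency unit |
| dependency_noise_sd | 0.1 | Gaussian noise on dependency |
| expression_noise_sd | 0.5 | Gaussian noise on expression |
| tissue_effect_sd | 1.0 | spread of per-gene tissue means |
| expression_baseline | 4.0 | mean log2 TPM, a mid-range expressed gene |
| baseline_dependency | −0.5 | mean D.S. of G1s (negative: essential) |
| tissue_boost | 1.5 | extra planted-G2 expression in the first tissue |

Expression for gene g in cell c is tissue_mean(g, tissue(c)) + noise,
floored at 0 to respect log2(TPM+1) ≥ 0. Dependency is generated
*conditional on* expression — D = intercept + (E − mean(E))/planted_slope +
noise — so the regression slope of expression on dependency is a directly
controlled, recoverable parameter. Background G1s are noise around the
negative baseline, independent of every G2. The first tissue receives a
+1.5 log2 TPM boost on planted G2s, making it the designated high-buffering
tissue; this is what the capacity ranking checks recover. One integer seed
drives a single generator stream: identical configs are bit-reproducible.

What the generator does **not** emulate: real DepMap marginal
distributions, copy-number and mutation structure, correlated gene modules
beyond tissue blocks, or realistic dependency magnitudes for planted pairs
(conditioning D on E at slope 0.01 spreads planted dependency scores over
tens of units, far wider than CERES scores; the coupling, not the scale, is
the tested property). Tests passing on this generator therefore demonstrate
correctness of the inference machinery under the planted model, not
recovery performance on real screens.

Companion ground truths: a duplicated-pair list (a configurable fraction of
planted pairs), a genetic-interaction table (planted pairs draw GI ~
N(−0.5, 0.1) in a high-expression cell line; background pairs draw
N(0, 0.1) — so the *sign* of a background draw is an intentionally noisy
label), and a prognosis table marking planted G2s as significantly
poorer-prognosis (positive Cox sign, adjusted p = 0.01).

## Downstream statistics

**Enrichment.** Duplicated-pair enrichment above a cutoff is the standard
upper-tail hypergeometric test on the scored-pair universe. Pair-set
enrichment is log[(e_ac/e_a)/(e_c/e_t)] with log base 2 by default
(configurable); e_ac = 0 reports −∞ rather than an error. Annotation
membership is symmetric in (g1, g2). The buffering network has one directed
edge G2 → G1 per retained pair; nodes are classed buffered / buffering /
both; exports are SIF and GraphML.

**Tissue specificity.** τ = Σ(1 − x_i/x_max)/(N − 1) over per-tissue mean
expression, with means below 1 log2 TPM floored to 0 first; all-zero genes
are flagged undefined rather than assigned a value. The G1-vs-G2 contrast
is a paired t-test, positive = G2 more tissue-specific.

**Normalized C-score plot.** Both axes are rank-normalized (average ranks
on ties): dependency onto [−1, 0] (most essential → −1) and expression onto
[0, 1] (highest → 1). Rank normalization is used for both axes for
symmetry; min–max is a configurable alternative. The quadrant is cut into
nine 10° sectors radiating from the origin, R1 along the expression axis
through R9 along the dependency axis. The angle θ is measured from the
+y axis; sector k covers ((k−1)·10°, k·10°], so boundary angles at exact
multiples of 10° belong to the lower-index sector (angles within 1e-9
degrees of a boundary are snapped to it first, making the rule robust to
floating-point noise). The origin is unassignable and yields the sentinel
0. Per (pair, region, tissue), enrichment of a tissue's cell lines among
the region's cell lines is an upper-tail hypergeometric test with BH at
0.05 within each region — the per-pair "enriched" criterion is a documented
package choice, and the reported table is each tissue's share of enriched
pairs per region (rows sum to 100%).

**Buffering capacity.** capacity = (cell expression − 25th percentile of
the G2's expression) / slope_mod, slope_mod = C · sd(expr)/sd(dep). Sample
(ddof = 1) standard deviations are used — the choice is a convention;
population sds rescale every capacity by a common factor without changing
any ranking. Percentiles interpolate linearly between order statistics.
Moving the reference percentile shifts all of a pair's capacities by a
common additive amount, preserving rankings.

**Bliss.** E_bliss = (E_A + E_B − E_A·E_B)/E_AB on relative-growth
fold-changes, with < 1 flagged as potential synergy. Caveat: the classical
Bliss model is stated for inhibition fractions in [0, 1]; applied verbatim
to growth fold-changes that can exceed 1, the synergy direction of the
ratio is not guaranteed to match the classical interpretation. The formula
is kept as-is deliberately.

**Validation.** GI rows get the max directional C-score (missing
orientation = −∞; missing both = dropped and counted); label = strictly
negative GI (a GI of exactly 0 is non-buffering). AUC uses the rank
(Mann–Whitney) formulation with tie correction and a one-sided p for
AUC > 0.5. Prognosis labels are (positive Cox sign AND adjusted p < 0.1);
scores are tissue-matched per-gene capacities, aggregated over a gene's
qualifying pairs by max (mean available); cancers with < 50 positive genes
are skipped; BH at 0.1 across all (cancer, cutoff) results.

## Numerical choices and degenerate inputs

- Pearson significance thresholds are applied as |ρ| > ρ_crit(n, α)
  derived from the t-distribution, equivalent to p < α without computing
  1e8 p-values.
- Correlations are clipped to [−1, 1] after the matrix product to absorb
  rounding.
- Constant profiles are errors wherever a correlation, slope, rank
  normalization or sd is required; they cannot be scored.
- Scores are streamed over G1 blocks (default 512 rows); only records at
  or above the report threshold are materialized, so the full pair
  universe is never held row-wise in memory.
- Alignment orders cell lines lexicographically, making shuffle seeds and
  output files deterministic; dependency genes with any missing value are
  dropped (counted and reported), missing expression is floored to 0.

## Problem sizes

The default test and reproduction conditions are the synthetic study above
(10,000 pairs × 200 cell lines); the slope-recovery summary uses 100
independent generator draws; the null uses 5 shuffles of the full panel.
These sizes keep a complete run in seconds on one CPU while leaving every
statistic far from its small-sample regime.

## Known limitations

- Real-data headline numbers require the DepMap/CCLE/ENSEMBL inputs and
  are out of scope for the shipped test data; the pipeline accepts such
  panels through the same CSV/TSV readers.
- The normal fit to the shuffled null is a modelling choice; extreme-tail
  p-values inherit its tail behaviour.
- The per-pair region-enrichment criterion (hypergeometric + per-region
  BH) is one defensible definition among several; all knobs are exposed.
- Tissue-specific weighting of the slope term (b varying by tissue) is not
  implemented; b is a scalar.
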