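import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cebu.datatypes import AlignedDataset
from cebu.tissue import (assign_region, compute_tau, normalize_pair_plot,
                         region_tissue_enrichment, tau_contrast)


def _expr_from_tissue_means(means_per_gene, cells_per_tissue=2):
    """Expression matrix whose within-tissue values equal the given
    tissue means exactly (no noise)."""
    genes = list(means_per_gene)
    n_tissues = len(next(iter(means_per_gene.values())))
    cells, labels, cols = [], [], []
    for t in range(n_tissues):
        for c in range(cells_per_tissue):
            cells.append(f"t{t}c{c}")
            labels.append(f"tissue{t}")
            cols.append([means_per_gene[g][t] for g in genes])
    expr = pd.DataFrame(np.array(cols).T, index=genes, columns=cells)
    ann = pd.Series(labels, index=cells)
    return expr, ann


class TestTau:
    @pytest.mark.parametrize("means,expected", [
        ((0, 0, 4), 1.0),       # single-tissue expression
        ((2, 2, 2), 0.0),       # uniform expression
        ((0.5, 2, 4), 0.75),    # sub-floor mean thresholded to 0
    ])
    def test_direct_formula(self, means, expected):
        expr, ann = _expr_from_tissue_means({"g": means})
        out = compute_tau(expr, ann)
        assert out.loc["g", "tau"] == pytest.approx(expected, abs=1e-12)

    def test_single_tissue_errors(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        ann = pd.Series(["t0", "t0"], index=["a", "b"])
        with pytest.raises(ValueError, match="2 tissues"):
            compute_tau(expr, ann)

    def test_all_below_floor_undefined(self):
        expr, ann = _expr_from_tissue_means({"g": (0.2, 0.5, 0.9)})
        out = compute_tau(expr, ann)
        assert not out.loc["g", "defined"]
        assert np.isnan(out.loc["g", "tau"])

    def test_scale_invariance_post_threshold(self):
        base = (1.5, 3.0, 6.0)
        expr1, ann = _expr_from_tissue_means({"g": base})
        expr3, _ = _expr_from_tissue_means(
            {"g": tuple(3 * x for x in base)})
        t1 = compute_tau(expr1, ann).loc["g", "tau"]
        t3 = compute_tau(expr3, ann).loc["g", "tau"]
        assert t1 == pytest.approx(t3, abs=1e-12)


class TestTauContrast:
    def test_identical_vectors_null(self):
        out = tau_contrast([0.2, 0.5, 0.8], [0.2, 0.5, 0.8])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_positive_difference_matches_hand_formula(self):
        # differences (+0.1, +0.1): sd = 0, so t diverges
        out = tau_contrast([0.1, 0.2], [0.2, 0.3])
        assert out["mean_diff"] == pytest.approx(0.1)
        assert np.isinf(out["t"]) or out["t"] > 1e10

    def test_hand_computed_t(self):
        g1 = np.array([0.1, 0.3, 0.2, 0.4])
        g2 = np.array([0.35, 0.5, 0.3, 0.7])
        out = tau_contrast(g1, g2)
        d = g2 - g1
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert out["t"] == pytest.approx(t_oracle, abs=1e-12)

    def test_synthetic_direction_g2_more_specific(self):
        """G2s tissue-restricted, G1s broadly expressed: the paired
        contrast must be positive and significant."""
        rng = np.random.default_rng(0)
        n_pairs = 30
        g1_means = {f"g1_{i}": tuple(4 + 0.1 * rng.standard_normal(5))
                    for i in range(n_pairs)}
        g2_means = {}
        for i in range(n_pairs):
            m = [0.0] * 5
            m[i % 5] = 6.0
            g2_means[f"g2_{i}"] = tuple(m)
        expr, ann = _expr_from_tissue_means({**g1_means, **g2_means})
        tau = compute_tau(expr, ann)
        out = tau_contrast(tau.loc[list(g1_means), "tau"].to_numpy(),
                           tau.loc[list(g2_means), "tau"].to_numpy())
        assert out["mean_diff"] > 0
        assert out["p"] < 0.01

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            tau_contrast([0.1], [0.1, 0.2])


class TestNormalizePairPlot:
    def test_rank_map_monotone_profile(self):
        out = normalize_pair_plot([-5, -4, -3, -2, -1],
                                  [1, 2, 3, 4, 5])
        assert np.allclose(out["x_norm"], [-1, -0.75, -0.5, -0.25, 0])
        assert np.allclose(out["y_norm"], [0, 0.25, 0.5, 0.75, 1])

    def test_constant_profile_errors(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_pair_plot([-1, -2, -3], [2, 2, 2])

    def test_ties_use_average_ranks(self):
        # all-tied-but-one: average-rank oracle via scipy rankdata
        x = np.array([-1.0, -1.0, -1.0, -2.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = normalize_pair_plot(x, y)
        expected = -1.0 + (stats.rankdata(x) - 1) / 3.0
        assert np.allclose(out["x_norm"], expected)
        assert out["x_norm"].iloc[3] == -1.0


class TestAssignRegion:
    def test_near_expression_axis_is_r1(self):
        assert assign_region(-0.01, 1.0) == 1

    def test_near_dependency_axis_is_r9(self):
        assert assign_region(-1.0, 0.01) == 9

    def test_diagonal_is_r5(self):
        assert assign_region(-1.0, 1.0) == 5

    @pytest.mark.parametrize("deg", [10, 20, 30, 40, 50, 60, 70, 80])
    def test_boundary_angles_assign_to_lower_region(self, deg):
        rad = np.radians(deg)
        x, y = -np.sin(rad), np.cos(rad)
        assert assign_region(x, y) == deg // 10

    def test_origin_unassigned(self):
        assert assign_region(0.0, 0.0) == 0

    def test_partition_of_random_points(self):
        rng = np.random.default_rng(123)
        x = -rng.random(10_000)
        y = rng.random(10_000)
        regions = assign_region(x, y)
        assert regions.shape == (10_000,)
        assert ((regions >= 1) & (regions <= 9)).all()
        assert np.bincount(regions, minlength=10).sum() == 10_000

    def test_monotone_in_angle(self):
        thetas = np.linspace(0.5, 89.5, 200)
        regions = assign_region(-np.sin(np.radians(thetas)),
                                np.cos(np.radians(thetas)))
        assert (np.diff(regions) >= 0).all()

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            assign_region(0.5, 0.5)


class TestRegionTissueEnrichment:
    def _dataset(self, n_special=3, n_other=18):
        """Tissue 'special' cells carry both the highest expression and
        the weakest dependency of the planted pair: they land in R1."""
        n = n_special + n_other
        cells = [f"c{i}" for i in range(n)]
        rng = np.random.default_rng(5)
        dep_row = np.concatenate([
            np.linspace(-0.05, -0.01, n_special),       # least essential
            np.linspace(-1.0, -0.5, n_other)])
        expr_row = np.concatenate([
            np.linspace(9.0, 10.0, n_special),          # highest expression
            rng.uniform(1.0, 5.0, n_other)])
        dep = pd.DataFrame([dep_row], index=["g1"], columns=cells)
        expr = pd.DataFrame([expr_row], index=["g2"], columns=cells)
        labels = (["special"] * n_special
                  + ["bulk"] * (n_other // 2)
                  + ["other"] * (n_other - n_other // 2))
        ann = pd.Series(labels, index=cells)
        return AlignedDataset(dep, expr, ann)

    def test_constructed_tissue_dominates_r1(self):
        data = self._dataset()
        records = pd.DataFrame({"g1": ["g1"], "g2": ["g2"],
                                "c_score": [0.9]})
        shares = region_tissue_enrichment(records, data, cutoff=0.5)
        assert shares.loc[1, "special"] == pytest.approx(100.0)

    def test_rows_sum_to_100_or_0(self):
        data = self._dataset()
        records = pd.DataFrame({"g1": ["g1"], "g2": ["g2"],
                                "c_score": [0.9]})
        shares = region_tissue_enrichment(records, data, cutoff=0.5)
        sums = shares.sum(axis=1).to_numpy()
        assert np.all(np.isclose(sums, 100.0) | np.isclose(sums, 0.0))

    def test_no_pair_above_cutoff_errors(self):
        data = self._dataset()
        records = pd.DataFrame({"g1": ["g1"], "g2": ["g2"],
                                "c_score": [0.1]})
        with pytest.raises(ValueError, match="cutoff"):
            region_tissue_enrichment(records, data, cutoff=0.5)

    def test_region_counts_partition_cell_lines(self, default_bundle):
        _, data, truth, _ = default_bundle
        row = truth.planted.iloc[0]
        from cebu.tissue import normalize_pair_plot as npp
        norm = npp(data.dependency.loc[row.g1].to_numpy(),
                   data.expression.loc[row.g2].to_numpy())
        regions = assign_region(norm["x_norm"].to_numpy(),
                                norm["y_norm"].to_numpy())
        assert regions.size == data.n_cell_lines
        assert np.bincount(regions, minlength=10).sum() == data.n_cell_lines
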