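import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cebu.cscore import (CScoreModel, benjamini_hochberg, compute_cscore,
                         compute_slope_min, filter_candidates,
                         pair_regression)
from cebu.datatypes import AlignedDataset, PairRegression


def _aligned(dep_rows, expr_rows, dep_names=None, expr_names=None):
    n = len(dep_rows[0])
    cells = [f"c{i}" for i in range(n)]
    dep = pd.DataFrame(dep_rows, columns=cells,
                       index=dep_names or [f"d{i}"
                                           for i in range(len(dep_rows))])
    expr = pd.DataFrame(expr_rows, columns=cells,
                        index=expr_names or [f"e{i}"
                                             for i in range(len(expr_rows))])
    ann = pd.Series("t0", index=cells)
    return AlignedDataset(dep, expr, ann)


class TestFilterCandidates:
    def test_positive_mean_dependency_excluded(self, tiny_dataset):
        data = tiny_dataset
        data.dependency.loc["d1"] = 0.1
        g1, _ = filter_candidates(data)
        assert "d1" not in g1

    def test_zero_mean_dependency_excluded(self, tiny_dataset):
        data = tiny_dataset
        data.dependency.loc["d1"] = 0.0
        g1, _ = filter_candidates(data)
        assert "d1" not in g1

    def test_low_expression_excluded(self, tiny_dataset):
        data = tiny_dataset
        data.expression.loc["e1"] = 0.4
        _, g2 = filter_candidates(data)
        assert "e1" not in g2
        data.expression.loc["e1"] = 0.5
        _, g2 = filter_candidates(data)
        assert "e1" in g2


class TestPairRegression:
    def test_exact_linear(self):
        r = pair_regression([-3, -2, -1], [1, 2, 3])
        assert r.rho == pytest.approx(1.0)
        assert r.slope == pytest.approx(1.0)

    def test_sign_symmetry(self):
        r = pair_regression([-3, -2, -1], [3, 2, 1])
        assert r.rho == pytest.approx(-1.0)
        assert r.slope == pytest.approx(-1.0)

    def test_matches_closed_form_ols_oracle(self):
        x = np.array([-0.9, -0.5, -0.2, -0.1])
        y = np.array([2.0, 3.1, 3.9, 4.2])
        r = pair_regression(x, y)
        # independent closed-form oracle from the normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert r.slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert r.rho == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-12)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pair_regression([1, 1, 1], [1, 2, 3])


class TestSlopeMin:
    def test_singleton(self):
        regs = [PairRegression("a", "b", 0.5, 0.5, 0.01, 10)]
        assert compute_slope_min(regs) == 0.5

    def test_filter_then_min_enumeration(self):
        regs = [PairRegression("a", "b", 0.5, 0.2, 0.01, 10),
                PairRegression("a", "c", 0.3, 0.05, 0.2, 10),
                PairRegression("a", "d", -0.7, -0.1, 0.001, 10)]
        assert compute_slope_min(regs) == 0.2

    def test_no_qualifying_pair_errors(self):
        regs = [PairRegression("a", "b", -0.5, -0.2, 0.01, 10)]
        with pytest.raises(ValueError, match="significant positive"):
            compute_slope_min(regs)


class TestComputeCScore:
    def _reg(self, rho, slope):
        return PairRegression("a", "b", rho, slope, 0.01, 10)

    def test_slope_equals_slope_min_doubles_rho(self):
        rec = compute_cscore(self._reg(0.5, 0.3), slope_min=0.3, b=1.0)
        assert rec["c_score"] == pytest.approx(1.0)

    def test_b_zero_identity(self):
        rec = compute_cscore(self._reg(0.6, 0.3), slope_min=0.1, b=0.0)
        assert rec["c_score"] == pytest.approx(0.6)

    def test_double_slope(self):
        rec = compute_cscore(self._reg(0.5, 0.6), slope_min=0.3, b=1.0)
        assert rec["c_score"] == pytest.approx(0.75)

    def test_zero_slope_errors(self):
        with pytest.raises(ValueError, match="slope"):
            compute_cscore(self._reg(0.5, 0.0), slope_min=0.3)

    @pytest.mark.parametrize("slopes", [(0.1, 0.2, 0.4, 0.8)])
    def test_monotone_decreasing_in_slope(self, slopes):
        scores = [compute_cscore(self._reg(0.5, s), slope_min=0.05,
                                 b=1.0)["c_score"] for s in slopes]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestCScoreMatrix:
    def test_matrix_matches_per_pair_formula(self, tiny_dataset):
        model = CScoreModel(tiny_dataset)
        res = model.fit(threshold=-np.inf)
        for row in res.records.itertuples():
            reg = pair_regression(
                tiny_dataset.dependency.loc[row.g1].to_numpy(),
                tiny_dataset.expression.loc[row.g2].to_numpy(),
                row.g1, row.g2)
            rec = compute_cscore(reg, res.slope_min, b=1.0)
            assert row.c_score == pytest.approx(rec["c_score"], abs=1e-10)
            assert row.rho == pytest.approx(reg.rho, abs=1e-10)
            assert row.slope == pytest.approx(reg.slope, abs=1e-10)

    def test_b_zero_reduces_to_pearson(self, tiny_dataset):
        res = CScoreModel(tiny_dataset, b=0.0).fit(threshold=-np.inf)
        for row in res.records.itertuples():
            rho = stats.pearsonr(
                tiny_dataset.dependency.loc[row.g1],
                tiny_dataset.expression.loc[row.g2]).statistic
            assert row.c_score == pytest.approx(rho, abs=1e-12)

    def test_self_pair_excluded(self):
        rng = np.random.default_rng(0)
        dep = rng.normal(-1, 0.5, size=(3, 10))
        expr = rng.uniform(1, 5, size=(3, 10))
        data = _aligned(dep, expr, dep_names=["shared", "d1", "d2"],
                        expr_names=["shared", "e1", "e2"])
        res = CScoreModel(data).fit(threshold=-np.inf, slope_min=0.1)
        assert not ((res.records["g1"] == "shared")
                    & (res.records["g2"] == "shared")).any()
        assert ((res.records["g1"] == "shared")
                & (res.records["g2"] == "e1")).any()

    def test_directional_scores_differ(self, default_bundle):
        """Swapping the roles (dependency of B vs expression of A) is a
        different regression; both orientations compute but disagree."""
        _, data, truth, _ = default_bundle
        fwd = CScoreModel(data).fit(threshold=-np.inf)
        swapped = AlignedDataset(
            data.expression * -1.0 - 0.5,  # make means negative for G1 filter
            (data.dependency - data.dependency.to_numpy().min()),
            data.annotation)
        rev = CScoreModel(swapped).fit(threshold=-np.inf)
        assert len(fwd.records) and len(rev.records)
        row = truth.planted.iloc[0]
        assert not np.isclose(fwd.lookup(row.g1, row.g2),
                              rev.lookup(row.g2, row.g1))

    def test_planted_pairs_occupy_top_ranks(self, default_bundle, fitted):
        _, _, truth, _ = default_bundle
        _, res = fitted
        top = set(zip(res.records["g1"][:len(truth.planted)],
                      res.records["g2"][:len(truth.planted)]))
        assert top == truth.planted_pairs


class TestNullAndSignificance:
    def test_null_seeded_reproducible(self, tiny_dataset):
        model = CScoreModel(tiny_dataset)
        n1 = model.fit_null(n_shuffles=3, seed=5)
        n2 = model.fit_null(n_shuffles=3, seed=5)
        assert (n1.mu, n1.sigma) == (n2.mu, n2.sigma)
        n3 = model.fit_null(n_shuffles=3, seed=6)
        assert n1.mu != n3.mu

    def test_p_at_mu_is_half_and_tail_is_tiny(self, fitted):
        model, res = fitted
        null = model.fit_null(n_shuffles=2, seed=1,
                              slope_min=res.slope_min)
        assert null.sf(null.mu) == pytest.approx(0.5)
        assert null.sf(null.mu + 10 * null.sigma) < 1e-15

    def test_bh_step_up_enumeration(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_significance_attaches_p_and_q(self, fitted):
        model, res = fitted
        null = model.fit_null(n_shuffles=2, seed=3,
                              slope_min=res.slope_min)
        res.add_significance(null)
        assert {"p", "q"}.issubset(res.records.columns)
        # planted pairs are far in the null tail
        assert (res.records["q"][:50] < 1e-10).all()
        # BH never decreases a p-value
        assert (res.records["q"] >= res.records["p"] - 1e-15).all()

    def test_summary_mentions_key_quantities(self, fitted):
        model, res = fitted
        text = res.summary()
        assert "slope_min" in text and "pairs scored" in text
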