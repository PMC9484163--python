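"""Boosting closed forms, descriptor ranking and the attention readout."""

import numpy as np
import pytest

from molscreen import descriptor_branch as desc
from molscreen.descriptor_branch import (
    DescriptorRanking,
    DescriptorTable,
    NumericDomainError,
    ReadoutParameters,
    Standardizer,
    descriptor_attention_weights,
    descriptor_readout,
    leaf_weight,
    rank_descriptors,
    split_gain,
    structure_score,
)


class TestBoostingClosedForms:
    def test_zero_gradient_gives_zero_weight(self):
        for H, lam in [(1.0, 0.0), (5.0, 2.0), (0.1, 10.0)]:
            assert leaf_weight(0.0, H, lam) == 0.0

    def test_squared_error_leaf_weight_is_mean_residual(self):
        # half-squared-error on residual targets {1, 3} from prediction 0:
        # g_i = -(y_i), h_i = 1 -> G = -4, H = 2, weight = -G/H = 2
        assert leaf_weight(-4.0, 2.0, 0.0) == pytest.approx(2.0)

    def test_shrinkage_is_monotone_in_lambda(self):
        values = [abs(leaf_weight(-4.0, 2.0, lam)) for lam in (0.0, 1.0, 10.0, 1e6)]
        assert values == sorted(values, reverse=True)
        assert values[-1] < 1e-5

    def test_invalid_hessian_domain(self):
        with pytest.raises(NumericDomainError):
            leaf_weight(1.0, -2.0, 1.0)

    def test_single_leaf_zero_gradient_score_is_gamma(self):
        assert structure_score([(0.0, 3.0)], 1.0, 0.7) == pytest.approx(0.7)

    def test_two_leaf_rational_value(self):
        # -(1/2) * (16/3 + 36/4) = -43/6
        got = structure_score([(-4.0, 2.0), (6.0, 3.0)], 1.0, 0.0)
        assert got == pytest.approx(-43.0 / 6.0)

    def test_large_gamma_rejects_any_split(self):
        left, right = (-4.0, 2.0), (6.0, 3.0)
        assert split_gain(left, right, 1.0, gamma=1e6) < 0


class TestRanking:
    def make_table(self, rng, n=300, p=40):
        values = rng.normal(size=(n, p))
        names = [f"D{j:03d}" for j in range(p)]
        ids = [f"c{i}" for i in range(n)]
        return DescriptorTable(ids, names, values)

    def test_exact_copy_column_ranks_first(self, rng):
        table = self.make_table(rng, n=500)
        target = table.values[:, 7].copy()
        ranking = rank_descriptors(table, target, k=5, seed=0)
        assert ranking.ranked_names[0] == "D007"

    def test_k_equals_p_is_a_permutation(self, rng):
        table = self.make_table(rng, n=100, p=20)
        target = table.values[:, 0] + rng.normal(size=100)
        ranking = rank_descriptors(table, target, k=20, seed=0)
        assert sorted(ranking.ranked_names) == sorted(table.names)
        assert np.all(np.diff(ranking.scores) <= 1e-12)

    def test_constant_target_falls_back_to_variance(self, rng):
        table = self.make_table(rng, n=50, p=10)
        with pytest.warns(UserWarning, match="constant target"):
            ranking = rank_descriptors(table, np.ones(50), k=3, seed=0)
        assert ranking.degenerate
        variances = table.values.var(axis=0)
        assert ranking.ranked_names[0] == table.names[int(np.argmax(variances))]

    def test_column_order_invariance(self, rng):
        table = self.make_table(rng, n=400, p=15)
        target = table.values[:, 3] * 2 + table.values[:, 8] + rng.normal(size=400) * 0.1
        ranking = rank_descriptors(table, target, k=15, seed=0)
        perm = rng.permutation(15)
        shuffled = DescriptorTable(
            table.compound_ids,
            [table.names[j] for j in perm],
            table.values[:, perm],
        )
        ranking2 = rank_descriptors(shuffled, target, k=15, seed=0)
        # the booster enumerates features in column order, so near-tied noise
        # columns may swap; the informative descriptors and their gains are
        # stable under permutation
        assert set(ranking.ranked_names[:2]) == set(ranking2.ranked_names[:2]) == {"D003", "D008"}
        lookup = dict(zip(ranking2.ranked_names, ranking2.scores))
        for name in ("D003", "D008"):
            idx = ranking.ranked_names.index(name)
            assert lookup[name] == pytest.approx(ranking.scores[idx], rel=1e-3)

    def test_ranking_tsv_round_trip(self, rng, tmp_path):
        table = self.make_table(rng, n=100, p=10)
        ranking = rank_descriptors(table, table.values[:, 0], k=4, seed=0)
        path = tmp_path / "ranking.tsv"
        ranking.to_tsv(str(path))
        loaded = DescriptorRanking.from_tsv(str(path), k=4)
        assert loaded.ranked_names == ranking.ranked_names
        assert loaded.top_k() == ranking.top_k()

    def test_median_imputation(self):
        values = np.array([[1.0, np.nan], [3.0, 4.0], [np.nan, 8.0]])
        table = DescriptorTable(["a", "b", "c"], ["x", "y"], values)
        with pytest.warns(UserWarning, match="imputed"):
            fixed = table.impute_median()
        assert fixed.values[2, 0] == 2.0  # median of 1, 3
        assert fixed.values[0, 1] == 6.0  # median of 4, 8


class TestReadout:
    def oracle(self, m, w):
        att_hidden = np.tanh(np.outer(m, w["att_w"].value) + w["att_b"].value)
        e = (att_hidden @ w["att_c"].value).ravel()
        p = np.exp(e - e.max())
        p /= p.sum()
        return (p * m) @ w["proj_W"].value + w["proj_b"].value

    def test_matches_loop_oracle(self, rng):
        params = ReadoutParameters.init(rng, k=5, out_dim=4)
        m = rng.normal(size=5)
        expected = self.oracle(m, params.weights)
        assert np.abs(descriptor_readout(m, params) - expected).max() < 1e-9

    def test_equal_logits_give_uniform_weights(self, rng):
        params = ReadoutParameters.init(rng, k=6, out_dim=4)
        params.weights["att_w"].value[:] = 0.0  # e_j independent of m_j
        weights = descriptor_attention_weights(rng.normal(size=6), params)
        assert np.abs(weights - 1 / 6).max() < 1e-12

    def test_zero_projection_returns_bias(self, rng):
        params = ReadoutParameters.init(rng, k=5, out_dim=3)
        params.weights["proj_W"].value[:] = 0.0
        params.weights["proj_b"].value[:] = np.array([1.0, -2.0, 0.5])
        out = descriptor_readout(rng.normal(size=5), params)
        assert np.allclose(out, [1.0, -2.0, 0.5])

    def test_attention_weights_sum_to_one(self, rng):
        params = ReadoutParameters.init(rng, k=8, out_dim=4)
        for _ in range(5):
            w = descriptor_attention_weights(rng.normal(size=8) * 3, params)
            assert np.all(w >= 0) and abs(w.sum() - 1.0) < 1e-9

    def test_nonfinite_input_rejected(self, rng):
        params = ReadoutParameters.init(rng, k=3, out_dim=2)
        with pytest.raises(ValueError):
            descriptor_readout(np.array([1.0, np.inf, 0.0]), params)

    def test_standardization_makes_readout_affine_invariant(self, rng):
        params = ReadoutParameters.init(rng, k=4, out_dim=3)
        raw = rng.normal(size=(50, 4))
        scaled = raw * np.array([2.0, 0.5, 10.0, 1.0]) + np.array([5, -3, 0, 1])
        a = Standardizer.fit(raw).transform(raw)
        b = Standardizer.fit(scaled).transform(scaled)
        for i in range(5):
            assert np.abs(
                descriptor_readout(a[i], params) - descriptor_readout(b[i], params)
            ).max() < 1e-9
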