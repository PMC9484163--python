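"""Gated propagation, readout and attention fusion against loop oracles.

Every oracle below is a plain-Python scalar/loop evaluation of the update
equations — no shared code with the tensor implementation under test.
"""

import numpy as np
import pytest
from rdkit import Chem

from molscreen import ggnn
from molscreen.ggnn import GgnnParameters, attention_weights, fuse_subgraphs, propagate, readout
from molscreen.molgraph import MolecularGraph, mol_from_smiles


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_graph(adjacency, features):
    adjacency = np.asarray(adjacency, float)
    features = np.asarray(features, float)
    return MolecularGraph(
        smiles="synthetic", atom_count=features.shape[0],
        atom_features=features, adjacency=adjacency,
    )


def oracle_propagate(A, H0, w, steps):
    """Hand-unrolled per-node loop over the gated update equations."""
    h = np.array(H0, dtype=float)
    n, d = h.shape
    for _ in range(steps):
        o = np.zeros_like(h)
        for i in range(n):
            agg = np.zeros(d)
            for j in range(n):
                agg += A[i][j] * h[j]
            o[i] = agg @ w["W_o"] + w["b_o"]
        nxt = np.zeros_like(h)
        for i in range(n):
            z = _sigmoid(o[i] @ w["W_z"] + h[i] @ w["U_z"] + w["b_z"])
            r = _sigmoid(o[i] @ w["W_r"] + h[i] @ w["U_r"] + w["b_r"])
            cand = np.tanh(o[i] @ w["W_h"] + (r * h[i]) @ w["U_h"] + w["b_h"])
            nxt[i] = cand * z + h[i] * (1.0 - z)
        h = nxt
    return h


def oracle_readout(states, w, pooling="fusion"):
    def mlp(x, prefix):
        return np.tanh(x @ w[f"{prefix}_W1"] + w[f"{prefix}_b1"]) @ w[f"{prefix}_W2"] + w[f"{prefix}_b2"]

    gated = np.array(
        [_sigmoid(mlp(s, "f1")) * np.tanh(mlp(s, "f2")) for s in states]
    )
    mean_part = gated.sum(axis=0) / (len(states) + 1)
    max_part = gated.max(axis=0)
    if pooling == "mean":
        return mean_part
    if pooling == "max":
        return max_part
    return mean_part + max_part


def oracle_fusion(h_graph, sub_vectors, w):
    cand = np.vstack([h_graph] + list(sub_vectors))
    e = (np.tanh(cand @ w["att_W"] + w["att_b"]) @ w["att_c"]).ravel()
    p = np.exp(e - e.max())
    p /= p.sum()
    return (p[:, None] * cand).sum(axis=0), p


@pytest.fixture()
def params(rng):
    return GgnnParameters.init(rng, hidden_dim=3, interaction_steps=2)


def weight_values(params):
    return {k: v.value for k, v in params.weights.items()}


def test_propagation_matches_scalar_loop_oracle(rng, params):
    A = np.array([[0, 1, 0], [1, 0, 2], [0, 2, 0]], float)  # path with a double bond
    H0 = rng.normal(size=(3, 3))
    g = make_graph(A, H0)
    expected = oracle_propagate(A, H0, weight_values(params), steps=2)
    assert np.abs(propagate(g, params) - expected).max() < 1e-6


def test_forced_zero_update_gate_freezes_states(rng):
    params = GgnnParameters.init(rng, hidden_dim=3, interaction_steps=3)
    params.weights["W_z"].value[:] = 0.0
    params.weights["U_z"].value[:] = 0.0
    params.weights["b_z"].value[:] = -1e6  # sigmoid -> 0, so h_t = h_{t-1}
    H0 = rng.normal(size=(4, 3))
    g = make_graph(np.zeros((4, 4)), H0)
    assert np.abs(propagate(g, params) - H0).max() < 1e-12


def test_isolated_atom_evolves_as_bias_driven_gru_cell(rng, params):
    H0 = rng.normal(size=(1, 3))
    g = make_graph(np.zeros((1, 1)), H0)
    expected = oracle_propagate(np.zeros((1, 1)), H0, weight_values(params), steps=2)
    assert np.abs(propagate(g, params) - expected).max() < 1e-9


def test_zero_interaction_steps_is_identity(rng):
    params = GgnnParameters.init(rng, hidden_dim=3, interaction_steps=0)
    H0 = rng.normal(size=(5, 3))
    g = make_graph(np.zeros((5, 5)), H0)
    assert np.array_equal(propagate(g, params), H0)


def test_readout_matches_loop_oracle(rng, params):
    states = rng.normal(size=(4, 3))
    expected = oracle_readout(states, weight_values(params))
    assert np.abs(readout(states, params) - expected).max() < 1e-6


def test_readout_singleton_is_half_mean_plus_max(rng, params):
    states = rng.normal(size=(1, 3))
    w = weight_values(params)
    g = oracle_readout(states, w, pooling="mean") * 2  # the single gated vector
    assert np.abs(readout(states, params) - (g / 2 + oracle_readout(states, w, "max"))).max() < 1e-9


def test_readout_identical_nodes_closed_form(rng, params):
    state = rng.normal(size=3)
    n = 5
    states = np.tile(state, (n, 1))
    w = weight_values(params)
    gated = oracle_readout(states[:1], w, pooling="max")  # the common gated vector
    expected = n * gated / (n + 1) + gated
    assert np.abs(readout(states, params) - expected).max() < 1e-9


@pytest.mark.parametrize("pooling", ["mean", "max", "fusion"])
def test_pooling_variants_match_oracle(rng, pooling):
    params = GgnnParameters.init(rng, hidden_dim=3, pooling=pooling)
    states = rng.normal(size=(6, 3))
    expected = oracle_readout(states, weight_values(params), pooling)
    assert np.abs(readout(states, params) - expected).max() < 1e-9


def test_readout_rejects_empty_node_set(params):
    with pytest.raises(ValueError):
        readout(np.zeros((0, 3)), params)


def test_fusion_matches_softmax_oracle(rng, params):
    h_graph = rng.normal(size=3)
    subs = [rng.normal(size=3) for _ in range(3)]
    expected, weights = oracle_fusion(h_graph, subs, weight_values(params))
    assert np.abs(fuse_subgraphs(h_graph, subs, params) - expected).max() < 1e-6
    got = attention_weights(h_graph, subs, params)
    assert np.abs(got - weights).max() < 1e-9
    assert abs(got.sum() - 1.0) < 1e-9


def test_fusion_empty_subgraph_list_returns_parent(rng, params):
    h_graph = rng.normal(size=3)
    assert np.abs(fuse_subgraphs(h_graph, [], params) - h_graph).max() < 1e-12


def test_fusion_identical_candidates_share_weight_equally(rng, params):
    v = rng.normal(size=3)
    weights = attention_weights(v, [v.copy()], params)
    assert np.abs(weights - 0.5).max() < 1e-12


def test_attention_weights_nonnegative_and_normalized(rng, params):
    for _ in range(10):
        weights = attention_weights(
            rng.normal(size=3) * 10,
            [rng.normal(size=3) * 10 for _ in range(4)],
            params,
        )
        assert np.all(weights >= 0)
        assert abs(weights.sum() - 1.0) < 1e-9


def test_readout_permutation_invariance(rng):
    params = GgnnParameters.init(rng, hidden_dim=39, interaction_steps=2)
    smiles = "CC(=O)Nc1ccc(O)cc1"
    g = mol_from_smiles(smiles)
    mol = Chem.MolFromSmiles(smiles)
    perm = [int(p) for p in rng.permutation(mol.GetNumAtoms())]
    alt = mol_from_smiles(
        Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
    )
    out_a = readout(propagate(g, params), params)
    out_b = readout(propagate(alt, params), params)
    assert np.abs(out_a - out_b).max() < 1e-6


def test_parameter_checkpoint_round_trip(tmp_path, rng):
    params = GgnnParameters.init(rng, hidden_dim=5, interaction_steps=3, pooling="max")
    path = tmp_path / "ggnn.npz"
    params.save(str(path))
    loaded = GgnnParameters.load(str(path))
    assert loaded.interaction_steps == 3
    assert loaded.pooling == "max"
    for name in params.weights:
        assert np.array_equal(loaded.weights[name].value, params.weights[name].value)


def test_checkpoint_hash_mismatch_is_detected(tmp_path, rng):
    params = GgnnParameters.init(rng, hidden_dim=4)
    path = tmp_path / "ggnn.npz"
    params.save(str(path))
    data = dict(np.load(str(path)))
    data["__meta__"] = np.array([4, 9, 0])  # altered config, stale hash
    np.savez_compressed(str(path), **data)
    with pytest.raises(ValueError, match="hash"):
        GgnnParameters.load(str(path))
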