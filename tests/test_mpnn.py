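"""Encoder correctness: hand-worked fixture, loop oracle, invariances."""

import numpy as np
import pytest
from rdkit import Chem

from dhtnn.activations import activation_factory
from dhtnn.autodiff import Tensor
from dhtnn.errors import DataError
from dhtnn.graphio import batch_graphs, featurize_molecule
from dhtnn.mpnn import (EncoderConfig, EncoderParams, atom_readout,
                        batch_normalize, encode, init_bond_hidden,
                        message_step, mole_ffn)
from dhtnn.synthetic import toy_graph_fixture

from oracles import encode_oracle


def _params(rng, d_atom=133, d_bond=14, h=8, depth=3, dropout=0.0,
            activation="beaf", aggregation="sum"):
    from dhtnn.activations import ActivationSpec
    cfg = EncoderConfig(d_atom=d_atom, d_bond=d_bond, hidden_size=h,
                        depth=depth, dropout=dropout,
                        activation=ActivationSpec(activation),
                        aggregation=aggregation)
    return EncoderParams(cfg, rng)


def _toy_params():
    """All-ones 1x2 / 1x1 weights matching the fixture's worked table."""
    _, table = toy_graph_fixture()
    rng = np.random.default_rng(0)
    p = _params(rng, d_atom=1, d_bond=1, h=1, depth=table["depth"])
    p.W_i.data = table["W_i"].astype(float)
    p.W_m.data = table["W_m"].astype(float)
    p.W_a.data = table["W_a"].astype(float)
    p.b_a.data = np.zeros(1)
    return p


# --------------------------------------------------------- hand-worked toy
def test_toy_fixture_bond_init():
    graph, table = toy_graph_fixture()
    p = _toy_params()
    h0 = init_bond_hidden(batch_graphs([graph]), p)
    np.testing.assert_array_equal(h0.data.ravel(), table["h0"])


def test_toy_fixture_message_step():
    graph, table = toy_graph_fixture()
    p = _toy_params()
    batch = batch_graphs([graph])
    h0 = init_bond_hidden(batch, p)
    h1 = message_step(h0, h0, batch, p)
    np.testing.assert_array_equal(h1.data.ravel(), table["h1"])


def test_toy_fixture_readout():
    graph, table = toy_graph_fixture()
    p = _toy_params()
    batch = batch_graphs([graph])
    h0 = init_bond_hidden(batch, p)
    h1 = message_step(h0, h0, batch, p)
    y = atom_readout(h1, batch, p)
    assert y.data.ravel()[0] == table["y"] == 15.0


def test_toy_fixture_zero_Wm_degenerates_to_skip():
    graph, _ = toy_graph_fixture()
    p = _toy_params()
    p.W_m.data = np.zeros((1, 1))
    batch = batch_graphs([graph])
    h0 = init_bond_hidden(batch, p)
    h = h0
    for _ in range(3):
        h = message_step(h, h0, batch, p)
        np.testing.assert_array_equal(h.data, np.maximum(h0.data, 0.0))


def test_leaf_bond_has_empty_message():
    # 2-atom path: the only incoming bond of A is the reverse bond
    g = featurize_molecule("CC", scheme="scalar")
    rng = np.random.default_rng(0)
    p = _params(rng, d_atom=1, d_bond=1, h=1, depth=1)
    p.W_i.data = np.ones((2, 1))
    p.W_m.data = np.ones((1, 1)) * 7.0  # must not matter: message is empty
    batch = batch_graphs([g])
    h0 = init_bond_hidden(batch, p)
    h1 = message_step(h0, h0, batch, p)
    np.testing.assert_array_equal(h1.data, h0.data)


def test_single_atom_molecule_readout():
    g = featurize_molecule("C", scheme="scalar")
    rng = np.random.default_rng(0)
    p = _params(rng, d_atom=1, d_bond=1, h=1, depth=2)
    p.W_a.data = np.array([[2.0], [3.0]])
    p.b_a.data = np.zeros(1)
    batch = batch_graphs([g])
    h0 = init_bond_hidden(batch, p)
    y = atom_readout(h0, batch, p)
    # m_v = 0, so y = relu(W_a . cat(1, 0)) = 2
    assert y.data.ravel()[0] == 2.0


# ------------------------------------------------------------- loop oracle
@pytest.mark.parametrize("activation", ["beaf", "relu"])
def test_encode_matches_loop_oracle(small_molecules, activation):
    rng = np.random.default_rng(42)
    graphs = [featurize_molecule(s) for s in small_molecules[:20]]
    p = _params(rng, h=8, depth=3, dropout=0.0, activation=activation)
    got = encode(batch_graphs(graphs), p, mode="train",
                 rng=np.random.default_rng(0))
    want = encode_oracle(
        graphs, p.W_i.data, p.W_m.data, p.W_a.data, p.b_a.data,
        p.bn_gamma.data, p.bn_beta.data, p.config.bn_eps,
        p.ffn_W1.data, p.ffn_b1.data, p.ffn_W2.data, p.ffn_b2.data,
        activation_factory(activation), depth=3)
    np.testing.assert_allclose(got.data, want, rtol=1e-5, atol=1e-8)


def test_encode_mean_aggregation_matches_oracle(small_molecules):
    rng = np.random.default_rng(7)
    graphs = [featurize_molecule(s) for s in small_molecules[:6]]
    p = _params(rng, h=4, depth=2, aggregation="mean")
    got = encode(batch_graphs(graphs), p, mode="train")
    want = encode_oracle(
        graphs, p.W_i.data, p.W_m.data, p.W_a.data, p.b_a.data,
        p.bn_gamma.data, p.bn_beta.data, p.config.bn_eps,
        p.ffn_W1.data, p.ffn_b1.data, p.ffn_W2.data, p.ffn_b2.data,
        activation_factory("beaf"), depth=2, aggregation="mean")
    np.testing.assert_allclose(got.data, want, rtol=1e-5, atol=1e-8)


# ------------------------------------------------------------- invariances
def test_permutation_invariance(rng):
    smiles = "c1ccncc1CC(O)C"
    p = _params(np.random.default_rng(3), h=8, depth=3)
    base = featurize_molecule(smiles)
    mol = Chem.MolFromSmiles(smiles)
    out0 = encode(batch_graphs([base]), p, mode="eval")
    for _ in range(3):
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        alt = featurize_molecule(
            Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False))
        out = encode(batch_graphs([alt]), p, mode="eval")
        np.testing.assert_allclose(out.data, out0.data, atol=1e-6)


def test_locality_y_is_batch_independent_but_YD_is_not():
    p = _params(np.random.default_rng(5), h=8, depth=3)
    a = featurize_molecule("c1ccccc1CC")
    b = featurize_molecule("CCO")
    c = featurize_molecule("C1CCNCC1Br")

    def y_of(graphs):
        batch = batch_graphs(graphs)
        h0 = init_bond_hidden(batch, p)
        h = h0
        for _ in range(p.config.depth):
            h = message_step(h, h0, batch, p)
        return atom_readout(h, batch, p)

    y_ab = y_of([a, b])
    y_ac = y_of([a, c])
    np.testing.assert_allclose(y_ab.data[0], y_ac.data[0], atol=1e-12)

    yd_ab = batch_normalize(y_ab, p, mode="train").data[0]
    yd_ac = batch_normalize(y_ac, p, mode="train").data[0]
    assert np.max(np.abs(yd_ab - yd_ac)) > 1e-8  # batch stats mix molecules


# -------------------------------------------------------------- batch norm
def test_batch_normalize_constant_feature_maps_to_beta():
    p = _params(np.random.default_rng(0), h=3)
    y = Tensor(np.ones((4, 3)) * 5.0)
    out = batch_normalize(y, p, mode="train")
    np.testing.assert_allclose(out.data, 0.0, atol=1e-3)  # eps-dominated
    p.bn_gamma.data = np.zeros(3)
    p.bn_beta.data = np.array([1.0, 2.0, 3.0])
    out = batch_normalize(y, p, mode="train")
    np.testing.assert_allclose(out.data, [[1, 2, 3]] * 4)


def test_batch_normalize_two_point_closed_form():
    p = _params(np.random.default_rng(0), h=1)
    p.config.bn_eps = 1e-12
    out = batch_normalize(Tensor([[0.0], [2.0]]), p, mode="train")
    np.testing.assert_allclose(out.data.ravel(), [-1.0, 1.0], atol=1e-6)


def test_batch_normalize_batch_of_one_rejected():
    p = _params(np.random.default_rng(0), h=2)
    with pytest.raises(DataError):
        batch_normalize(Tensor([[1.0, 2.0]]), p, mode="train")


def test_batch_normalize_eval_uses_running_stats():
    p = _params(np.random.default_rng(0), h=2)
    p.bn_running_mean = np.array([1.0, -1.0])
    p.bn_running_var = np.array([4.0, 0.25])
    p.config.bn_eps = 0.0
    out = batch_normalize(Tensor([[3.0, 0.0]]), p, mode="eval")
    np.testing.assert_allclose(out.data.ravel(), [1.0, 2.0])


# ----------------------------------------------------------------- MoleFFN
def test_mole_ffn_zero_weights_zero_output():
    p = _params(np.random.default_rng(0), h=4)
    p.ffn_W1.data = np.zeros((4, 4))
    p.ffn_W2.data = np.zeros((4, 4))
    out = mole_ffn(Tensor(np.random.default_rng(1).normal(size=(3, 4))),
                   p, mode="eval")
    # beaf(0) = -0.002 passes through the zero second linear -> 0
    np.testing.assert_allclose(out.data, 0.0)


def test_mole_ffn_eval_ignores_dropout_rate():
    rng = np.random.default_rng(2)
    x = Tensor(rng.normal(size=(5, 4)))
    p1 = _params(np.random.default_rng(9), h=4, dropout=0.0)
    p2 = _params(np.random.default_rng(9), h=4, dropout=0.9)
    np.testing.assert_array_equal(mole_ffn(x, p1, "eval").data,
                                  mole_ffn(x, p2, "eval").data)


def test_mole_ffn_composes_beaf_value():
    # identity-like weights: first linear is I, second multiplies by 2
    p = _params(np.random.default_rng(0), h=1, dropout=0.0)
    p.ffn_W1.data = np.eye(1)
    p.ffn_b1.data = np.zeros(1)
    p.ffn_W2.data = np.eye(1) * 2.0
    p.ffn_b2.data = np.zeros(1)
    out = mole_ffn(Tensor([[1.0]]), p, mode="eval")
    assert out.data[0, 0] == pytest.approx(2 * 0.8630983882673103, abs=1e-12)


# ------------------------------------------------------ residual & overall
def test_encode_residual_identity_when_ffn_zero(small_molecules):
    p = _params(np.random.default_rng(1), h=6, depth=2)
    p.ffn_W1.data[:] = 0.0
    p.ffn_W2.data[:] = 0.0
    graphs = [featurize_molecule(s) for s in small_molecules[:4]]
    batch = batch_graphs(graphs)
    got = encode(batch, p, mode="train")
    # recompute y alone
    h0 = init_bond_hidden(batch, p)
    h = h0
    for _ in range(2):
        h = message_step(h, h0, batch, p)
    y = atom_readout(h, batch, p)
    np.testing.assert_allclose(got.data, y.data, atol=1e-12)


def test_encode_eval_deterministic(small_molecules):
    p = _params(np.random.default_rng(1), h=6, depth=2, dropout=0.3)
    batch = batch_graphs([featurize_molecule(s)
                          for s in small_molecules[:5]])
    a = encode(batch, p, mode="eval").data
    b = encode(batch, p, mode="eval").data
    np.testing.assert_array_equal(a, b)


def test_gradient_health_over_training_steps(small_molecules):
    """All parameter gradients stay finite across 100 optimization steps."""
    from dhtnn.training import Adam
    rng = np.random.default_rng(0)
    p = _params(rng, h=8, depth=3, dropout=0.1)
    graphs = [featurize_molecule(s) for s in small_molecules[:16]]
    batch = batch_graphs(graphs)
    target = Tensor(np.random.default_rng(1).normal(size=(len(graphs), 8)))
    opt = Adam(p.parameters(), lr=1e-3)
    droprng = np.random.default_rng(2)
    for _ in range(100):
        out = encode(batch, p, mode="train", rng=droprng)
        loss = ((out - target) ** 2).mean()
        opt.zero_grad()
        loss.backward()
        for param in p.parameters():
            assert param.grad is None or np.all(np.isfinite(param.grad))
        opt.step()
    assert np.isfinite(loss.item())
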