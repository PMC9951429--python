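"""Transformer stage: layer norm, two-head attention, droppath, residuals."""

import numpy as np
import pytest

from dhtnn.activations import ActivationSpec
from dhtnn.autodiff import Tensor
from dhtnn.errors import ConfigurationError
from dhtnn.graphio import batch_graphs, featurize_molecule
from dhtnn.transformer import (BlockConfig, BlockParams, attention_sublayer,
                               attention_weights, double_head_attention,
                               droppath, layer_normalize, mlp_sublayer,
                               predict_head, transformer_stack)

from oracles import double_head_attention_oracle, layer_norm_oracle


def _block(rng=None, h=4, n_tasks=1, droppath_rate=0.0, mlp_expansion=2):
    cfg = BlockConfig(hidden_size=h, n_tasks=n_tasks,
                      droppath_rate=droppath_rate,
                      mlp_expansion=mlp_expansion,
                      activation=ActivationSpec("beaf"))
    return BlockParams(cfg, rng or np.random.default_rng(0))


# -------------------------------------------------------------- layer norm
def test_layer_norm_constant_row_is_zero():
    g, b = Tensor(np.ones(3)), Tensor(np.zeros(3))
    out = layer_normalize(Tensor(np.full((2, 3), 7.0)), g, b, eps=1e-5)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-2)


def test_layer_norm_two_point_closed_form():
    g, b = Tensor(np.ones(2)), Tensor(np.zeros(2))
    out = layer_normalize(Tensor([[0.0, 2.0]]), g, b, eps=1e-12)
    np.testing.assert_allclose(out.data.ravel(), [-1.0, 1.0], atol=1e-6)


def test_layer_norm_gamma_zero_gives_beta():
    g, b = Tensor(np.zeros(3)), Tensor(np.array([1.0, 2.0, 3.0]))
    out = layer_normalize(Tensor(np.random.default_rng(0).normal(size=(4, 3))),
                          g, b)
    np.testing.assert_allclose(out.data, [[1, 2, 3]] * 4)


def test_layer_norm_matches_row_loop_oracle(rng):
    Y = rng.normal(size=(5, 8))
    gamma, beta = rng.normal(size=8), rng.normal(size=8)
    out = layer_normalize(Tensor(Y), Tensor(gamma), Tensor(beta), eps=1e-5)
    want = layer_norm_oracle(Y, gamma, beta, 1e-5)
    np.testing.assert_allclose(out.data, want, rtol=1e-10)


# --------------------------------------------------------------- attention
def test_attention_single_token_is_v_Wo(rng):
    p = _block(h=4)
    Y = Tensor(rng.normal(size=(1, 4)))
    got = double_head_attention(Y, p)
    want = (Y.data @ p.W_v.data) @ p.W_o.data
    np.testing.assert_allclose(got.data, want, atol=1e-12)


def test_attention_rows_sum_to_one(rng):
    p = _block(h=8)
    Y = Tensor(rng.normal(size=(5, 8)) * 3.0)
    for w in attention_weights(Y, p):
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


@pytest.mark.parametrize("n_tokens,h", [(2, 4), (3, 4), (4, 8), (3, 8)])
def test_attention_matches_dense_oracle(n_tokens, h, rng):
    p = _block(np.random.default_rng(n_tokens * h), h=h)
    Y = Tensor(rng.normal(size=(n_tokens, h)))
    got = double_head_attention(Y, p)
    want = double_head_attention_oracle(Y.data, p.W_q.data, p.W_k.data,
                                        p.W_v.data, p.W_o.data)
    np.testing.assert_allclose(got.data, want, rtol=1e-5, atol=1e-10)


def test_attention_row_permutation_equivariance(rng):
    p = _block(h=6)
    # h=6 with 2 heads -> d_k = 3
    Y = rng.normal(size=(4, 6))
    perm = np.array([2, 0, 3, 1])
    out = double_head_attention(Tensor(Y), p).data
    out_perm = double_head_attention(Tensor(Y[perm]), p).data
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)


def test_attention_odd_width_rejected():
    with pytest.raises(ConfigurationError):
        BlockConfig(hidden_size=5, n_heads=2)


def test_attention_width_preserved(rng):
    p = _block(h=8)
    Y = Tensor(rng.normal(size=(6, 8)))
    assert double_head_attention(Y, p).shape == (6, 8)


# ---------------------------------------------------------------- droppath
def test_droppath_eval_identity(rng):
    Y = Tensor(rng.normal(size=(4, 3)))
    out = droppath(Y, rate=0.7, mode="eval")
    assert out is Y


def test_droppath_rate_zero_identity(rng):
    Y = Tensor(rng.normal(size=(4, 3)))
    out = droppath(Y, rate=0.0, mode="train", rng=rng)
    assert out is Y


def test_droppath_expectation_preserving():
    rng = np.random.default_rng(77)
    total = 0.0
    trials = 10_000
    for _ in range(trials):
        out = droppath(Tensor([[1.0]]), rate=0.5, mode="train", rng=rng)
        total += out.data[0, 0]
    assert 0.97 <= total / trials <= 1.03


def test_droppath_zeroes_whole_rows():
    rng = np.random.default_rng(5)
    Y = Tensor(np.ones((200, 3)))
    out = droppath(Y, rate=0.5, mode="train", rng=rng).data
    zero_rows = np.all(out == 0.0, axis=1)
    kept_rows = np.all(out == 2.0, axis=1)  # scaled by 1/(1-rate)
    assert np.all(zero_rows | kept_rows)
    assert 40 < zero_rows.sum() < 160


def test_droppath_bad_rate_rejected():
    with pytest.raises(ConfigurationError):
        droppath(Tensor([[1.0]]), rate=1.0, mode="train",
                 rng=np.random.default_rng(0))


# ---------------------------------------------------------------- sublayers
def test_attention_sublayer_residual_identity_with_zero_values(rng):
    p = _block(h=4)
    p.W_v.data[:] = 0.0
    Y = Tensor(rng.normal(size=(3, 4)))
    out = attention_sublayer(Y, p, mode="eval")
    np.testing.assert_allclose(out.data, Y.data, atol=1e-12)


def test_mlp_sublayer_residual_identity_with_zero_weights(rng):
    p = _block(h=4)
    p.mlp_W1.data[:] = 0.0
    p.mlp_W2.data[:] = 0.0
    p.mlp_b1.data[:] = 0.0
    p.mlp_b2.data[:] = 0.0
    Y = Tensor(rng.normal(size=(3, 4)))
    out = mlp_sublayer(Y, p, mode="eval")
    np.testing.assert_allclose(out.data, Y.data, atol=1e-12)


def test_sublayer_chain_matches_sequential_oracle(rng):
    """2-token case: the full sublayer equals the hand-chained equations."""
    p = _block(np.random.default_rng(8), h=4)
    Y = rng.normal(size=(2, 4))
    got = attention_sublayer(Tensor(Y), p, mode="eval").data
    ln = layer_norm_oracle(Y, p.ln1.gamma.data, p.ln1.beta.data, p.ln1.eps)
    att = double_head_attention_oracle(ln, p.W_q.data, p.W_k.data,
                                       p.W_v.data, p.W_o.data)
    np.testing.assert_allclose(got, Y + att, rtol=1e-6)


def test_shape_preserved_through_block(rng):
    p = _block(h=8)
    Y = Tensor(rng.normal(size=(5, 8)))
    out = mlp_sublayer(attention_sublayer(Y, p, "eval"), p, "eval")
    assert out.shape == (5, 8)


# ----------------------------------------------------------- predict head
def test_predict_head_zero_weights_gives_bias(rng):
    p = _block(h=4, n_tasks=3)
    p.out_W.data[:] = 0.0
    p.out_b.data = np.array([1.0, -2.0, 0.5])
    out = predict_head(Tensor(rng.normal(size=(4, 4))), p)
    np.testing.assert_allclose(out.data, [[1.0, -2.0, 0.5]] * 4)


def test_predict_head_task_columns(rng):
    p = _block(h=4, n_tasks=5)
    assert predict_head(Tensor(rng.normal(size=(3, 4))), p).shape == (3, 5)


# ------------------------------------------------------------ full forward
def _tiny_model(n_tasks=1, droppath_rate=0.0):
    from dhtnn.model import DHTNNModel, ModelConfig
    cfg = ModelConfig(n_tasks=n_tasks, hidden_size=8, depth=2,
                      dropout=0.0, droppath_rate=droppath_rate,
                      mlp_expansion=2)
    return DHTNNModel(cfg, seed=0)


def test_forward_single_molecule_well_defined():
    m = _tiny_model()
    batch = batch_graphs([featurize_molecule("c1ccccc1")])
    out = m.forward(batch, mode="eval", context="batch")
    assert out.shape == (1, 1) and np.isfinite(out.data).all()


def test_forward_eval_reproducible(small_molecules):
    m = _tiny_model()
    batch = batch_graphs([featurize_molecule(s)
                          for s in small_molecules[:4]])
    a = m.forward(batch, mode="eval", context="batch").data
    b = m.forward(batch, mode="eval", context="batch").data
    np.testing.assert_array_equal(a, b)


def test_forward_full_pipeline_matches_chained_oracle(small_molecules):
    """End-to-end eval forward equals manual stage chaining with oracles."""
    from dhtnn.mpnn import encode
    m = _tiny_model()
    graphs = [featurize_molecule(s) for s in small_molecules[:3]]
    batch = batch_graphs(graphs)
    got = m.forward(batch, mode="eval", context="batch").data

    Y_R = encode(batch, m.encoder, mode="eval").data
    p = m.blocks[0]
    ln1 = layer_norm_oracle(Y_R, p.ln1.gamma.data, p.ln1.beta.data, p.ln1.eps)
    Y_Rpa = Y_R + double_head_attention_oracle(
        ln1, p.W_q.data, p.W_k.data, p.W_v.data, p.W_o.data)
    ln2 = layer_norm_oracle(Y_Rpa, p.ln2.gamma.data, p.ln2.beta.data,
                            p.ln2.eps)
    from dhtnn.activations import beaf
    mlp = beaf(ln2 @ p.mlp_W1.data + p.mlp_b1.data) @ p.mlp_W2.data \
        + p.mlp_b2.data
    Y_RPm = Y_Rpa + mlp
    ln3 = layer_norm_oracle(Y_RPm, p.ln3.gamma.data, p.ln3.beta.data,
                            p.ln3.eps)
    want = ln3 @ p.out_W.data + p.out_b.data
    np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-10)


def test_single_context_equals_looped_single_molecule_eval(small_molecules):
    """context='single' must equal processing each molecule alone."""
    m = _tiny_model()
    graphs = [featurize_molecule(s) for s in small_molecules[:5]]
    batch = batch_graphs(graphs)
    joint = m.forward(batch, mode="eval", context="single").data
    singles = np.vstack([
        m.forward(batch_graphs([g]), mode="eval", context="batch").data
        for g in graphs])
    np.testing.assert_allclose(joint, singles, atol=1e-10)


def test_batched_context_differs_from_single(small_molecules):
    m = _tiny_model()
    graphs = [featurize_molecule(s) for s in small_molecules[:5]]
    batch = batch_graphs(graphs)
    joint = m.forward(batch, mode="eval", context="batch").data
    single = m.forward(batch, mode="eval", context="single").data
    assert np.max(np.abs(joint - single)) > 1e-10  # attention mixes tokens


def test_transformer_stack_rejects_bad_context(rng):
    p = _block(h=4)
    with pytest.raises(ConfigurationError):
        transformer_stack(Tensor(rng.normal(size=(2, 4))), [p],
                          context="bogus")
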