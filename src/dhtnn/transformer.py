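"""Transformer stage with two-head self-attention over molecule tokens.

Each molecule's encoder vector Y_R is one token; a pre-norm transformer
block mixes tokens of the processing set and a linear head emits per-task
predictions:

    attention sublayer   Y_Rpa = Y_R + DropPath(DoubleHead(LN(Y_R)))
    MLP sublayer         Y_RPm = Y_Rpa + DropPath(MLP(LN(Y_Rpa)))
    prediction head      Y     = Linear(LN(Y_RPm))

DoubleHead splits q, k, v column-wise into two equal heads (d_k = h/2
each), runs scaled dot-product attention per head, concatenates and mixes
with W_o, preserving the token width h.  DropPath (stochastic depth) zeroes
an entire residual branch per token with the configured probability during
training and rescales survivors by 1/(1-rate); it is the identity at
evaluation.

Because attention mixes tokens, batched-context evaluation makes a
molecule's prediction depend on its batch mates.  Default evaluation
therefore processes each molecule alone (N = 1, where attention
degenerates to Y_DH = v . W_o); batched context is available via
``context="batch"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .activations import ActivationSpec, activation_factory
from .autodiff import Tensor, concat
from .errors import ConfigurationError
from .graphio import BatchGraph
from .mpnn import EncoderParams, _glorot, encode

__all__ = [
    "BlockConfig",
    "BlockParams",
    "layer_normalize",
    "double_head_attention",
    "droppath",
    "attention_sublayer",
    "mlp_sublayer",
    "predict_head",
    "dhtnn_forward",
]


@dataclass
class BlockConfig:
    """Hyperparameters of the transformer stage."""

    hidden_size: int = 300
    n_tasks: int = 1
    n_heads: int = 2                    # two heads; config integer for ablation
    mlp_expansion: int = 4
    droppath_rate: float = 0.1
    ln_eps: float = 1e-5
    n_blocks: int = 1
    activation: ActivationSpec = field(default_factory=ActivationSpec)

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ConfigurationError(
                f"hidden_size {self.hidden_size} not divisible by "
                f"{self.n_heads} heads")
        if not (0.0 <= self.droppath_rate < 1.0):
            raise ConfigurationError("droppath_rate must lie in [0, 1)")


class _LayerNormParams:
    def __init__(self, h: int, eps: float):
        self.gamma = Tensor(np.ones(h), requires_grad=True)
        self.beta = Tensor(np.zeros(h), requires_grad=True)
        self.eps = eps


class BlockParams:
    """Learnable state of one attention+MLP block plus the prediction head.

    The three layer-norms carry independent (gamma, beta) pairs.
    """

    def __init__(self, config: BlockConfig, rng: np.random.Generator):
        c = config
        h = c.hidden_size
        self.config = c
        self.W_q = Tensor(_glorot(rng, h, h), requires_grad=True)
        self.W_k = Tensor(_glorot(rng, h, h), requires_grad=True)
        self.W_v = Tensor(_glorot(rng, h, h), requires_grad=True)
        self.W_o = Tensor(_glorot(rng, h, h), requires_grad=True)
        self.ln1 = _LayerNormParams(h, c.ln_eps)
        self.ln2 = _LayerNormParams(h, c.ln_eps)
        self.ln3 = _LayerNormParams(h, c.ln_eps)
        self.mlp_W1 = Tensor(_glorot(rng, h, c.mlp_expansion * h),
                             requires_grad=True)
        self.mlp_b1 = Tensor(np.zeros(c.mlp_expansion * h), requires_grad=True)
        self.mlp_W2 = Tensor(_glorot(rng, c.mlp_expansion * h, h),
                             requires_grad=True)
        self.mlp_b2 = Tensor(np.zeros(h), requires_grad=True)
        self.out_W = Tensor(_glorot(rng, h, c.n_tasks), requires_grad=True)
        self.out_b = Tensor(np.zeros(c.n_tasks), requires_grad=True)
        self.act: Callable = activation_factory(c.activation)

    def parameters(self) -> list[Tensor]:
        ps = [self.W_q, self.W_k, self.W_v, self.W_o,
              self.mlp_W1, self.mlp_b1, self.mlp_W2, self.mlp_b2,
              self.out_W, self.out_b]
        for ln in (self.ln1, self.ln2, self.ln3):
            ps += [ln.gamma, ln.beta]
        return ps


def layer_normalize(Y: Tensor, gamma: Tensor, beta: Tensor,
                    eps: float = 1e-5) -> Tensor:
    """Per-row (per data point) normalization over the feature axis."""
    mean = Y.mean(axis=1, keepdims=True)
    var = ((Y - mean) ** 2).mean(axis=1, keepdims=True)
    return (Y - mean) * ((var + eps) ** -0.5) * gamma + beta


def _softmax_rows(scores: Tensor) -> Tensor:
    shift = scores.data.max(axis=1, keepdims=True)  # constant; softmax is shift-invariant
    z = (scores - Tensor(shift)).exp()
    return z / z.sum(axis=1, keepdims=True)


def double_head_attention(Y_L: Tensor, params: BlockParams) -> Tensor:
    """Two-head scaled dot-product self-attention over token rows."""
    c = params.config
    h = c.hidden_size
    if Y_L.shape[1] != h:
        raise ConfigurationError(
            f"token width {Y_L.shape[1]} != hidden_size {h}")
    q = Y_L @ params.W_q
    k = Y_L @ params.W_k
    v = Y_L @ params.W_v
    d_k = h // c.n_heads
    heads = []
    for i in range(c.n_heads):
        lo, hi = i * d_k, (i + 1) * d_k
        qi, ki, vi = q.cols(lo, hi), k.cols(lo, hi), v.cols(lo, hi)
        attn = _softmax_rows((qi @ ki.T) * (1.0 / np.sqrt(d_k)))
        heads.append(attn @ vi)
    return concat(heads, axis=1) @ params.W_o


def attention_weights(Y_L: Tensor, params: BlockParams) -> list[np.ndarray]:
    """Per-head softmax attention matrices (diagnostic; no gradient)."""
    c = params.config
    d_k = c.hidden_size // c.n_heads
    q = (Y_L @ params.W_q).data
    k = (Y_L @ params.W_k).data
    out = []
    for i in range(c.n_heads):
        lo, hi = i * d_k, (i + 1) * d_k
        s = q[:, lo:hi] @ k[:, lo:hi].T / np.sqrt(d_k)
        z = np.exp(s - s.max(axis=1, keepdims=True))
        out.append(z / z.sum(axis=1, keepdims=True))
    return out


def droppath(Y: Tensor, rate: float, mode: str = "train",
             rng: np.random.Generator | None = None) -> Tensor:
    """Stochastic depth: zero a whole token's branch w.p. `rate` in training."""
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError(f"droppath rate must lie in [0, 1); got {rate}")
    if mode == "eval" or rate == 0.0:
        return Y
    if rng is None:
        raise ConfigurationError("train-mode droppath needs an rng")
    keep = (rng.random((Y.shape[0], 1)) >= rate).astype(np.float64) / (1.0 - rate)
    return Y * Tensor(keep)


def attention_sublayer(Y_R: Tensor, params: BlockParams, mode: str = "train",
                       rng: np.random.Generator | None = None) -> Tensor:
    """Y_Rpa = Y_R + DropPath(DoubleHead(LN(Y_R)))."""
    ln = params.ln1
    branch = double_head_attention(
        layer_normalize(Y_R, ln.gamma, ln.beta, ln.eps), params)
    return Y_R + droppath(branch, params.config.droppath_rate, mode, rng)


def mlp_sublayer(Y_Rpa: Tensor, params: BlockParams, mode: str = "train",
                 rng: np.random.Generator | None = None) -> Tensor:
    """Y_RPm = Y_Rpa + DropPath(MLP(LN(Y_Rpa)))."""
    ln = params.ln2
    z = layer_normalize(Y_Rpa, ln.gamma, ln.beta, ln.eps)
    z = params.act(z @ params.mlp_W1 + params.mlp_b1)
    z = z @ params.mlp_W2 + params.mlp_b2
    return Y_Rpa + droppath(z, params.config.droppath_rate, mode, rng)


def predict_head(Y_RPm: Tensor, params: BlockParams,
                 task: str = "regression") -> Tensor:
    """Final layer-norm then linear map to n_tasks outputs.

    Regression returns raw values; classification returns logits (the
    logistic map is applied by losses/metrics downstream).
    """
    ln = params.ln3
    z = layer_normalize(Y_RPm, ln.gamma, ln.beta, ln.eps)
    return z @ params.out_W + params.out_b


def transformer_stack(Y_R: Tensor, blocks: list[BlockParams],
                      mode: str = "train",
                      rng: np.random.Generator | None = None,
                      context: str = "batch") -> Tensor:
    """Apply the attention+MLP sublayers of every block.

    ``context="single"`` replaces attention with its exact N=1 degenerate
    form (Y_DH = v . W_o per token), making each row's output independent
    of its batch mates — the default at evaluation.
    """
    if context not in ("batch", "single"):
        raise ConfigurationError(f"context must be batch|single, got {context!r}")
    z = Y_R
    for params in blocks:
        if context == "single":
            ln = params.ln1
            branch = (layer_normalize(z, ln.gamma, ln.beta, ln.eps)
                      @ params.W_v) @ params.W_o
            z = z + droppath(branch, params.config.droppath_rate, mode, rng)
        else:
            z = attention_sublayer(z, params, mode, rng)
        z = mlp_sublayer(z, params, mode, rng)
    return z


def dhtnn_forward(batch: BatchGraph, encoder: EncoderParams,
                  blocks: BlockParams | list[BlockParams],
                  mode: str = "train",
                  rng: np.random.Generator | None = None,
                  task: str = "regression",
                  context: str = "batch") -> Tensor:
    """Complete pipeline: encoder -> transformer block(s) -> prediction head."""
    if isinstance(blocks, BlockParams):
        blocks = [blocks]
    Y_R = encode(batch, encoder, mode, rng)
    Y_RPm = transformer_stack(Y_R, blocks, mode, rng, context)
    return predict_head(Y_RPm, blocks[-1], task)
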