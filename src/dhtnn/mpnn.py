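"""Residual directed message-passing encoder.

Pipeline per batch of molecular graphs (hidden width h, depth T):

1. bond init      h0_vw = tau(W_i . cat(x_v, e_vw))
2. T message steps  m_vw = sum_{k in N(v)\\{w}} h_kv ;  h_vw = tau(h0_vw + W_m m_vw)
   (incoming-bond convention: the message into v->w sums states of directed
   bonds entering v, excluding the reverse bond w->v)
3. readout        m_v = sum_{(w->v)} h_wv ;  h_v = tau(W_a . cat(x_v, m_v));
                  y = sum_{v in G} h_v  (per molecule; mean optional)
4. batch norm     Y_D = gamma * (y - E[y]) / sqrt(Var[y] + eps) + beta
5. MoleFFN        Y_F = dropout(W2 . dropout(act(W1 . Y_D)))
                  (linear -> activation -> dropout -> linear -> dropout)
6. residual       Y_R = y + Y_F   (the skip carries y, pre-batch-norm)

tau defaults to ReLU throughout the encoder; the configurable activation
(Beaf by default) applies inside MoleFFN.  The residual keeps gradients
finite as depth grows and lets the FFN learn only the correction to y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .activations import ActivationSpec, activation_factory
from .autodiff import Tensor, concat
from .errors import ConfigurationError, DataError
from .graphio import BatchGraph

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "init_bond_hidden",
    "message_step",
    "atom_readout",
    "batch_normalize",
    "mole_ffn",
    "encode",
]


@dataclass
class EncoderConfig:
    """Hyperparameters of the encoder; defaults follow the directed-MPNN family."""

    d_atom: int = 133
    d_bond: int = 14
    hidden_size: int = 300
    depth: int = 3                      # message-passing steps T
    dropout: float = 0.1
    aggregation: str = "sum"            # readout over atoms: sum | mean
    activation: ActivationSpec = field(default_factory=ActivationSpec)
    tau: str = "relu"                   # encoder-internal activation
    bias_Wa: bool = True
    bias_ffn: bool = True
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigurationError("depth T must be >= 1")
        if self.aggregation not in ("sum", "mean"):
            raise ConfigurationError("aggregation must be 'sum' or 'mean'")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class EncoderParams:
    """Learnable state of the encoder (weights + batch-norm running stats)."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        c = config
        h = c.hidden_size
        self.config = c
        self.W_i = Tensor(_glorot(rng, c.d_atom + c.d_bond, h), requires_grad=True)
        self.W_m = Tensor(_glorot(rng, h, h), requires_grad=True)
        self.W_a = Tensor(_glorot(rng, c.d_atom + h, h), requires_grad=True)
        self.b_a = Tensor(np.zeros(h), requires_grad=True) if c.bias_Wa else None
        self.bn_gamma = Tensor(np.ones(h), requires_grad=True)
        self.bn_beta = Tensor(np.zeros(h), requires_grad=True)
        self.bn_running_mean = np.zeros(h)
        self.bn_running_var = np.ones(h)
        self.ffn_W1 = Tensor(_glorot(rng, h, h), requires_grad=True)
        self.ffn_W2 = Tensor(_glorot(rng, h, h), requires_grad=True)
        if c.bias_ffn:
            self.ffn_b1 = Tensor(np.zeros(h), requires_grad=True)
            self.ffn_b2 = Tensor(np.zeros(h), requires_grad=True)
        else:
            self.ffn_b1 = self.ffn_b2 = None
        self.tau: Callable = activation_factory(c.tau)
        self.act: Callable = activation_factory(c.activation)

    def parameters(self) -> list[Tensor]:
        ps = [self.W_i, self.W_m, self.W_a, self.bn_gamma, self.bn_beta,
              self.ffn_W1, self.ffn_W2]
        for b in (self.b_a, self.ffn_b1, self.ffn_b2):
            if b is not None:
                ps.append(b)
        return ps


def init_bond_hidden(batch: BatchGraph, params: EncoderParams) -> Tensor:
    """h0_vw = tau(W_i . cat(x_v, e_vw)) for every directed bond."""
    if batch.n_mols == 0:
        raise DataError("empty batch")
    x = Tensor(batch.atom_features)
    e = Tensor(batch.bond_features)
    if batch.n_dir_bonds == 0:
        return Tensor(np.zeros((0, params.config.hidden_size)))
    bond_x = x.take_rows(batch.bond_origin)
    return params.tau(concat([bond_x, e], axis=1) @ params.W_i)


def message_step(h_t: Tensor, h0: Tensor, batch: BatchGraph,
                 params: EncoderParams) -> Tensor:
    """One directed message-passing update.

    m_vw sums hidden states of bonds entering v, excluding the reverse bond
    w->v; computed as (sum of all bonds into v) minus h_{w->v}.
    """
    if batch.n_dir_bonds == 0:
        return h_t
    into_atom = h_t.scatter_sum(batch.bond_target, batch.n_atoms)
    m = into_atom.take_rows(batch.bond_origin) - h_t.take_rows(batch.reverse_index)
    return params.tau(h0 + m @ params.W_m)


def atom_readout(h_T: Tensor, batch: BatchGraph, params: EncoderParams) -> Tensor:
    """Bond states -> atom states -> one vector y per molecule."""
    x = Tensor(batch.atom_features)
    h = params.config.hidden_size
    if batch.n_dir_bonds:
        m_v = h_T.scatter_sum(batch.bond_target, batch.n_atoms)
    else:
        m_v = Tensor(np.zeros((batch.n_atoms, h)))
    h_v = concat([x, m_v], axis=1) @ params.W_a
    if params.b_a is not None:
        h_v = h_v + params.b_a
    h_v = params.tau(h_v)
    y = h_v.scatter_sum(batch.atom_to_mol, batch.n_mols)
    if params.config.aggregation == "mean":
        counts = np.bincount(batch.atom_to_mol, minlength=batch.n_mols)
        y = y * Tensor((1.0 / counts)[:, None])
    return y


def batch_normalize(y: Tensor, params: EncoderParams, mode: str = "train") -> Tensor:
    """Per-feature batch normalization with running statistics.

    Train mode normalizes by batch mean and (population) variance and
    updates the running estimates; eval mode uses the running estimates.
    """
    if mode not in ("train", "eval"):
        raise ConfigurationError(f"mode must be train|eval, got {mode!r}")
    eps = params.config.bn_eps
    if mode == "train":
        n = y.shape[0]
        if n < 2:
            raise DataError("batch normalization in train mode needs batch >= 2")
        mean = y.mean(axis=0, keepdims=True)
        var = ((y - mean) ** 2).mean(axis=0, keepdims=True)
        mom = params.config.bn_momentum
        with np.errstate(all="ignore"):
            unbiased = var.data[0] * n / max(n - 1, 1)
        params.bn_running_mean = ((1 - mom) * params.bn_running_mean
                                  + mom * mean.data[0])
        params.bn_running_var = (1 - mom) * params.bn_running_var + mom * unbiased
        norm = (y - mean) * ((var + eps) ** -0.5)
    else:
        mean = Tensor(params.bn_running_mean[None, :])
        var = Tensor(params.bn_running_var[None, :])
        norm = (y - mean) * ((var + eps) ** -0.5)
    return norm * params.bn_gamma + params.bn_beta


def _dropout(x: Tensor, rate: float, mode: str,
             rng: np.random.Generator | None) -> Tensor:
    if mode == "eval" or rate == 0.0:
        return x
    if rng is None:
        raise ConfigurationError("train-mode dropout needs an rng")
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * Tensor(keep)


def mole_ffn(Y_D: Tensor, params: EncoderParams, mode: str = "train",
             rng: np.random.Generator | None = None) -> Tensor:
    """MoleFFN: linear -> activation -> dropout -> linear -> dropout."""
    rate = params.config.dropout
    z = Y_D @ params.ffn_W1
    if params.ffn_b1 is not None:
        z = z + params.ffn_b1
    z = _dropout(params.act(z), rate, mode, rng)
    z = z @ params.ffn_W2
    if params.ffn_b2 is not None:
        z = z + params.ffn_b2
    return _dropout(z, rate, mode, rng)


def encode(batch: BatchGraph, params: EncoderParams, mode: str = "train",
           rng: np.random.Generator | None = None) -> Tensor:
    """Full encoder: message passing, readout, BN, MoleFFN, residual -> Y_R."""
    h = init_bond_hidden(batch, params)
    h0 = h
    for _ in range(params.config.depth):
        h = message_step(h, h0, batch, params)
    y = atom_readout(h, batch, params)
    Y_D = batch_normalize(y, params, mode)
    Y_F = mole_ffn(Y_D, params, mode, rng)
    return y + Y_F
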