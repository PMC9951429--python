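"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Python loops, dense
materialization, arbitrary-precision arithmetic — and never shares code
with the package's vectorized implementations.
"""

from __future__ import annotations

import mpmath
import numpy as np

mpmath.mp.dps = 50


# --------------------------------------------------------------------------
# Beaf, arbitrary precision
# --------------------------------------------------------------------------

def beaf_mp(x: float, c: float) -> float:
    """x*tanh(ln(1+e^x)) - c at 50 significant digits."""
    xm = mpmath.mpf(repr(float(x)))
    return float(xm * mpmath.tanh(mpmath.log(1 + mpmath.exp(xm)))
                 - mpmath.mpf(repr(float(c))))


# --------------------------------------------------------------------------
# loop-based encoder (bond init, message passing, readout, BN, FFN, residual)
# --------------------------------------------------------------------------

def _relu(v):
    return np.maximum(v, 0.0)


def encode_oracle(graphs, W_i, W_m, W_a, b_a, bn_gamma, bn_beta, bn_eps,
                  ffn_W1, ffn_b1, ffn_W2, ffn_b2, act, depth,
                  aggregation="sum"):
    """Re-derive the encoder output with explicit per-bond/per-atom loops.

    Batch-norm uses batch (population) statistics, i.e. train-mode
    normalization with dropout off.
    """
    ys = []
    for g in graphs:
        h = W_i.shape[1]
        h0 = np.zeros((g.n_dir_bonds, h))
        for b in range(g.n_dir_bonds):
            v = g.bond_origin[b]
            feat = np.concatenate([g.atom_features[v], g.bond_features[b]])
            h0[b] = _relu(feat @ W_i)
        ht = h0.copy()
        for _ in range(depth):
            nxt = np.zeros_like(ht)
            for b in range(g.n_dir_bonds):
                v, w = g.bond_origin[b], g.bond_target[b]
                m = np.zeros(h)
                for k in range(g.n_dir_bonds):
                    # incoming bond (x -> v) excluding the reverse (w -> v)
                    if g.bond_target[k] == v and g.bond_origin[k] != w:
                        m += ht[k]
                nxt[b] = _relu(h0[b] + m @ W_m)
            ht = nxt
        atom_h = np.zeros((g.n_atoms, W_a.shape[1]))
        for v in range(g.n_atoms):
            m_v = np.zeros(h)
            for b in range(g.n_dir_bonds):
                if g.bond_target[b] == v:
                    m_v += ht[b]
            z = np.concatenate([g.atom_features[v], m_v]) @ W_a
            if b_a is not None:
                z = z + b_a
            atom_h[v] = _relu(z)
        y = atom_h.sum(axis=0)
        if aggregation == "mean":
            y = y / g.n_atoms
        ys.append(y)
    y = np.stack(ys)
    mean = y.mean(axis=0)
    var = y.var(axis=0)  # population variance
    Y_D = (y - mean) / np.sqrt(var + bn_eps) * bn_gamma + bn_beta
    z = act(Y_D @ ffn_W1 + (ffn_b1 if ffn_b1 is not None else 0.0))
    Y_F = z @ ffn_W2 + (ffn_b2 if ffn_b2 is not None else 0.0)
    return y + Y_F


# --------------------------------------------------------------------------
# dense two-head attention with arbitrary-precision softmax
# --------------------------------------------------------------------------

def double_head_attention_oracle(Y_L, W_q, W_k, W_v, W_o, n_heads=2):
    n, h = Y_L.shape
    d_k = h // n_heads
    q, k, v = Y_L @ W_q, Y_L @ W_k, Y_L @ W_v
    heads = []
    for i in range(n_heads):
        lo, hi = i * d_k, (i + 1) * d_k
        qi, ki, vi = q[:, lo:hi], k[:, lo:hi], v[:, lo:hi]
        out = np.zeros((n, d_k))
        for r in range(n):
            scores = [mpmath.mpf(repr(float(qi[r] @ ki[s] / np.sqrt(d_k))))
                      for s in range(n)]
            exps = [mpmath.exp(s) for s in scores]
            total = mpmath.fsum(exps)
            weights = [float(e / total) for e in exps]
            for s in range(n):
                out[r] += weights[s] * vi[s]
        heads.append(out)
    return np.concatenate(heads, axis=1) @ W_o


def layer_norm_oracle(Y, gamma, beta, eps):
    out = np.zeros_like(Y)
    for r in range(Y.shape[0]):
        mu = Y[r].mean()
        var = Y[r].var()
        out[r] = (Y[r] - mu) / np.sqrt(var + eps) * gamma + beta
    return out


# --------------------------------------------------------------------------
# pairwise ROC-AUC (Mann-Whitney with half-ties)
# --------------------------------------------------------------------------

def roc_auc_pairwise(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    total = 0.0
    for p in pos:
        for q in neg:
            if scores[p] > scores[q]:
                total += 1.0
            elif scores[p] == scores[q]:
                total += 0.5
    return total / (len(pos) * len(neg))
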