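"""Activation functions: Beaf and the standard references.

Beaf is the softplus–tanh activation used throughout this package's
transformer head and feed-forward blocks:

    f(x) = x * tanh(softplus(x)) - c,   softplus(x) = ln(1 + e^x)

with a fixed downward shift ``c`` in (0, 0.004], default 0.002.  Unlike tanh
it does not saturate for large positive inputs (f(x) -> x - c); unlike ReLU
it maps the negative half-axis smoothly (f(x) -> -c as x -> -inf, with a
pronounced dip near x ~ -1 that keeps negative inputs distinguishable).

Every activation here accepts either a plain NumPy array/scalar or an
autodiff :class:`~dhtnn.activations.Tensor`; gradients of the Tensor path
come from the autodiff engine (Beaf is an everywhere-differentiable
composite, so no custom derivative is needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.special import erf

from .autodiff import Tensor

__all__ = [
    "ActivationSpec",
    "softplus_stable",
    "beaf",
    "elu",
    "gelu",
    "relu",
    "activation_factory",
    "BEAF_C_DEFAULT",
    "BEAF_C_MAX",
]

BEAF_C_DEFAULT = 0.002
BEAF_C_MAX = 0.004

ArrayLike = Union[float, np.ndarray, Tensor]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _check_c(c: float) -> float:
    c = float(c)
    if not (0.0 < c <= BEAF_C_MAX):
        raise ValueError(f"Beaf shift c must lie in (0, {BEAF_C_MAX}]; got {c}")
    return c


def softplus_stable(x: ArrayLike) -> ArrayLike:
    """ln(1 + e^x) without overflow, as max(x, 0) + log1p(e^-|x|)."""
    if isinstance(x, Tensor):
        return x.softplus()
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("softplus_stable requires finite input")
    out = np.maximum(arr, 0.0) + np.log1p(np.exp(-np.abs(arr)))
    return out if arr.ndim else float(out)


def beaf(x: ArrayLike, c: float = BEAF_C_DEFAULT) -> ArrayLike:
    """Beaf activation  x * tanh(softplus(x)) - c  (smooth, no clamping)."""
    c = _check_c(c)
    if isinstance(x, Tensor):
        return x * x.softplus().tanh() - c
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("beaf requires finite input")
    out = arr * np.tanh(np.maximum(arr, 0.0) + np.log1p(np.exp(-np.abs(arr)))) - c
    return out if arr.ndim else float(out)


def relu(x: ArrayLike) -> ArrayLike:
    if isinstance(x, Tensor):
        return x.relu()
    arr = np.asarray(x, dtype=np.float64)
    out = np.maximum(arr, 0.0)
    return out if arr.ndim else float(out)


def elu(x: ArrayLike, alpha: float = 1.0) -> ArrayLike:
    """ELU: x for x > 0, alpha * (e^x - 1) otherwise."""
    if isinstance(x, Tensor):
        data = x.data
        mask = data > 0
        ex = np.exp(np.minimum(data, 0.0))
        out_data = np.where(mask, data, alpha * (ex - 1.0))

        def backward(g):
            if x.requires_grad:
                x._accum(g * np.where(mask, 1.0, alpha * ex))

        return Tensor._make(out_data, (x,), backward)
    arr = np.asarray(x, dtype=np.float64)
    out = np.where(arr > 0, arr, alpha * (np.exp(np.minimum(arr, 0.0)) - 1.0))
    return out if arr.ndim else float(out)


def gelu(x: ArrayLike) -> ArrayLike:
    """Exact (erf-form) GELU: x * Phi(x)."""
    if isinstance(x, Tensor):
        data = x.data
        cdf = 0.5 * (1.0 + erf(data * _INV_SQRT2))
        out_data = data * cdf

        def backward(g):
            if x.requires_grad:
                pdf = _INV_SQRT2PI * np.exp(-0.5 * data ** 2)
                x._accum(g * (cdf + data * pdf))

        return Tensor._make(out_data, (x,), backward)
    arr = np.asarray(x, dtype=np.float64)
    out = arr * 0.5 * (1.0 + erf(arr * _INV_SQRT2))
    return out if arr.ndim else float(out)


def tanh(x: ArrayLike) -> ArrayLike:
    if isinstance(x, Tensor):
        return x.tanh()
    arr = np.asarray(x, dtype=np.float64)
    out = np.tanh(arr)
    return out if arr.ndim else float(out)


@dataclass(frozen=True)
class ActivationSpec:
    """Named activation with its hyperparameters.

    `c` applies to Beaf only and must lie in (0, 0.004].
    """

    name: str = "beaf"
    c: float = BEAF_C_DEFAULT

    def __post_init__(self):
        if self.name not in _REGISTRY:
            raise ValueError(
                f"unknown activation {self.name!r}; known: {sorted(_REGISTRY)}")
        if self.name == "beaf":
            _check_c(self.c)

    def build(self) -> Callable[[ArrayLike], ArrayLike]:
        return activation_factory(self)


_REGISTRY: dict[str, Callable[..., ArrayLike]] = {
    "beaf": beaf,
    "elu": elu,
    "gelu": gelu,
    "relu": relu,
    "tanh": tanh,
}


def activation_factory(spec: ActivationSpec | str,
                       c: float = BEAF_C_DEFAULT) -> Callable[[ArrayLike], ArrayLike]:
    """Return the elementwise callable for `spec` (usable on arrays or Tensors)."""
    if isinstance(spec, str):
        spec = ActivationSpec(name=spec, c=c)
    if spec.name == "beaf":
        cc = _check_c(spec.c)
        return lambda x: beaf(x, cc)
    return _REGISTRY[spec.name]
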