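"""Model container: encoder + transformer blocks behind one object.

`DHTNNModel` owns the parameter containers, seeds their initialization,
and exposes forward/predict plus flat (de)serialization of all arrays so a
trained model can be written to disk and reloaded bit-exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .activations import ActivationSpec
from .autodiff import Tensor, no_grad
from .errors import ConfigurationError
from .graphio import BatchGraph, MolGraph, batch_graphs, featurize_molecule
from .mpnn import EncoderConfig, EncoderParams
from .transformer import BlockConfig, BlockParams, dhtnn_forward

__all__ = ["ModelConfig", "DHTNNModel"]


@dataclass
class ModelConfig:
    """Every hyperparameter of the full architecture, JSON-serializable."""

    n_tasks: int = 1
    task: str = "regression"
    d_atom: int = 133
    d_bond: int = 14
    hidden_size: int = 300
    depth: int = 3
    dropout: float = 0.1
    aggregation: str = "sum"
    activation: str = "beaf"
    beaf_c: float = 0.002
    tau: str = "relu"
    n_heads: int = 2
    mlp_expansion: int = 4
    droppath_rate: float = 0.1
    n_blocks: int = 1
    ln_eps: float = 1e-5
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    feature_scheme: str = "dmpnn"

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ConfigurationError(f"unknown task {self.task!r}")

    def activation_spec(self) -> ActivationSpec:
        return ActivationSpec(name=self.activation, c=self.beaf_c)

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            d_atom=self.d_atom, d_bond=self.d_bond,
            hidden_size=self.hidden_size, depth=self.depth,
            dropout=self.dropout, aggregation=self.aggregation,
            activation=self.activation_spec(), tau=self.tau,
            bn_eps=self.bn_eps, bn_momentum=self.bn_momentum)

    def block_config(self) -> BlockConfig:
        return BlockConfig(
            hidden_size=self.hidden_size, n_tasks=self.n_tasks,
            n_heads=self.n_heads, mlp_expansion=self.mlp_expansion,
            droppath_rate=self.droppath_rate, ln_eps=self.ln_eps,
            n_blocks=self.n_blocks, activation=self.activation_spec())


class DHTNNModel:
    """Encoder + transformer block(s) + prediction head with one seed."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = EncoderParams(config.encoder_config(), rng)
        self.blocks = [BlockParams(config.block_config(), rng)
                       for _ in range(config.n_blocks)]

    # ------------------------------------------------------------- parameters
    def parameters(self) -> list[Tensor]:
        ps = self.encoder.parameters()
        for b in self.blocks:
            ps += b.parameters()
        return ps

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array map of all learnable and running state."""
        out = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        out["bn_running_mean"] = self.encoder.bn_running_mean
        out["bn_running_var"] = self.encoder.bn_running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ConfigurationError(
                    f"state p{i} has shape {arr.shape}, expected {p.data.shape}")
            p.data = arr.copy()
        self.encoder.bn_running_mean = np.asarray(
            state["bn_running_mean"], dtype=np.float64).copy()
        self.encoder.bn_running_var = np.asarray(
            state["bn_running_var"], dtype=np.float64).copy()

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    # ---------------------------------------------------------------- forward
    def forward(self, batch: BatchGraph, mode: str = "train",
                rng: np.random.Generator | None = None,
                context: str = "batch") -> Tensor:
        return dhtnn_forward(batch, self.encoder, self.blocks, mode, rng,
                             self.config.task, context)

    def predict(self, graphs: list[MolGraph] | BatchGraph,
                context: str = "single") -> np.ndarray:
        """Eval-mode predictions (default: batch-composition independent)."""
        batch = graphs if isinstance(graphs, BatchGraph) else batch_graphs(graphs)
        with no_grad():
            out = self.forward(batch, mode="eval", context=context)
        return out.data

    def predict_smiles(self, smiles: list[str],
                       context: str = "single") -> np.ndarray:
        graphs = [featurize_molecule(s, self.config.feature_scheme)
                  for s in smiles]
        return self.predict(graphs, context)

    # ------------------------------------------------------------------- disk
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(asdict(self.config)))
        np.savez(directory / "params.npz", **self.state_arrays())

    @classmethod
    def load(cls, directory: str | Path) -> "DHTNNModel":
        directory = Path(directory)
        config = ModelConfig(**json.loads((directory / "config.json").read_text()))
        model = cls(config, seed=0)
        with np.load(directory / "params.npz") as npz:
            model.load_state_arrays({k: npz[k] for k in npz.files})
        return model

    def clone(self) -> "DHTNNModel":
        other = DHTNNModel(copy.deepcopy(self.config), seed=0)
        other.load_state_arrays(self.snapshot())
        return other
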