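"""Losses, metrics, the training loop, and the activation-comparison harness.

Training is plain seeded mini-batch Adam on the masked multi-task loss
(MSE for regression, binary cross-entropy with logits for classification;
unobserved labels contribute nothing, in value or gradient).  Model
selection keeps the checkpoint with the best validation metric.  The
comparison harness retrains the same model under different activation
functions with identical splits and seed streams and reports mean +/- std
of the test metric across seeds — the shape used to compare Beaf against
ELU/GeLU.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .activations import ActivationSpec
from .autodiff import Tensor
from .errors import ConfigurationError, DataError, TrainingDivergedError
from .graphio import (MoleculeRecord, SplitIndices, batch_graphs,
                      featurize_molecule)
from .model import DHTNNModel, ModelConfig

__all__ = [
    "TrainConfig",
    "EvalReport",
    "TrainResult",
    "masked_loss",
    "rmse",
    "roc_auc",
    "prc_auc",
    "train_model",
    "evaluate",
    "compare_activations",
]


# --------------------------------------------------------------------------
# losses and metrics
# --------------------------------------------------------------------------

def masked_loss(predictions: Tensor, targets: np.ndarray, mask: np.ndarray,
                task: str = "regression") -> Tensor:
    """Mean loss over observed (task, molecule) entries only.

    Regression: squared error.  Classification: binary cross-entropy with
    logits, computed in the stable softplus form
    ``BCE(z, t) = softplus(z) - t*z``.
    """
    targets = np.asarray(targets, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if predictions.shape != targets.shape or targets.shape != mask.shape:
        raise ConfigurationError("predictions/targets/mask shapes must agree")
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise DataError("all labels masked; loss undefined")
    w = mask.astype(np.float64)
    if task == "regression":
        per = (predictions - Tensor(targets)) ** 2
    elif task == "classification":
        z = predictions
        per = z.softplus() - Tensor(targets) * z
    else:
        raise ConfigurationError(f"unknown task {task!r}")
    return (per * Tensor(w)).sum() * (1.0 / n_obs)


def rmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Root mean square error."""
    predictions = np.asarray(predictions, dtype=np.float64).ravel()
    targets = np.asarray(targets, dtype=np.float64).ravel()
    if predictions.size == 0:
        raise DataError("rmse of empty input")
    if predictions.shape != targets.shape:
        raise ConfigurationError("rmse: shape mismatch")
    return float(np.sqrt(np.mean((predictions - targets) ** 2)))


def _per_task_metric(scores, labels, mask, metric_fn, needs) -> float:
    """Average a binary metric over tasks, skipping undefined tasks."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[:, None]
    if labels.ndim == 1:
        labels = labels[:, None]
    if scores.shape != labels.shape:
        raise ConfigurationError("scores/labels shape mismatch")
    if mask is None:
        mask = np.ones_like(labels, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:
        mask = mask[:, None]
    vals = []
    for t in range(labels.shape[1]):
        m = mask[:, t]
        lab, sc = labels[m, t], scores[m, t]
        if not needs(lab):
            warnings.warn(f"task {t} skipped: metric undefined for its labels")
            continue
        vals.append(metric_fn(lab, sc))
    if not vals:
        raise DataError("metric undefined for every task")
    return float(np.mean(vals))


def roc_auc(scores, labels, mask=None) -> float:
    """ROC-AUC (Mann–Whitney statistic, ties count 1/2), task-averaged."""
    return _per_task_metric(scores, labels, mask, roc_auc_score,
                            needs=lambda lab: len(np.unique(lab)) == 2)


def prc_auc(scores, labels, mask=None) -> float:
    """PRC-AUC by step-wise average-precision summation, task-averaged."""
    return _per_task_metric(scores, labels, mask, average_precision_score,
                            needs=lambda lab: np.any(lab == 1))


_METRICS = {"rmse": rmse, "roc_auc": roc_auc, "prc_auc": prc_auc}


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moments."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# configs and reports
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Everything the training loop needs, with logged defaults.

    The metric defaults by task: rmse for regression, roc_auc for
    classification (prc_auc is the convention for sparse bioassay panels).
    """

    task: str = "regression"
    epochs: int = 30
    batch_size: int = 50
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    metric: str | None = None
    split_method: str = "random"
    eval_context: str = "single"
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.batch_size < 2:
            raise ConfigurationError(
                "batch_size must be >= 2 (train-mode batch norm)")
        if self.metric is None:
            self.metric = "rmse" if self.task == "regression" else "roc_auc"
        if self.task == "regression" and self.metric != "rmse":
            raise ConfigurationError("regression uses the rmse metric")
        if self.task == "classification" and self.metric == "rmse":
            raise ConfigurationError("rmse is not a classification metric")
        if self.metric not in _METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")
        self.model.task = self.task


@dataclass
class EvalReport:
    """Per-seed metric values with mean +/- std (std absent under 2 seeds)."""

    metric: str
    values: list[float]
    seeds: list[int]
    split_method: str
    dataset_id: str = ""
    activation: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def std(self) -> float | None:
        if len(self.values) < 2:
            return None
        return float(np.std(self.values, ddof=1))

    def as_dict(self) -> dict:
        return {**asdict(self), "mean": self.mean, "std": self.std}


@dataclass
class TrainResult:
    model: DHTNNModel
    history: list[dict]
    best_epoch: int
    best_val_metric: float


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _featurize_records(records: Sequence[MoleculeRecord],
                       scheme: str) -> list:
    return [featurize_molecule(r.smiles, scheme) for r in records]


def _stack_targets(records: Sequence[MoleculeRecord], idx: Sequence[int]):
    y = np.stack([records[i].targets for i in idx])
    m = np.stack([records[i].mask for i in idx])
    return y, m


def _metric_value(config: TrainConfig, preds: np.ndarray, y: np.ndarray,
                  mask: np.ndarray) -> float:
    if config.metric == "rmse":
        return rmse(preds[mask], y[mask])
    return _METRICS[config.metric](preds, y, mask)


def _metric_is_loss(metric: str) -> bool:
    return metric == "rmse"


def train_model(records: Sequence[MoleculeRecord], splits: SplitIndices,
                config: TrainConfig, seed: int = 0) -> TrainResult:
    """Seeded mini-batch training with best-validation checkpointing.

    Fully reproducible given (records, splits, config, seed): the same seed
    drives parameter init, batch shuffling, dropout and droppath.  A
    non-finite loss aborts with diagnostics rather than training on.
    """
    graphs = _featurize_records(records, config.model.feature_scheme)
    n_tasks = len(records[0].targets)
    config.model.n_tasks = n_tasks

    model = DHTNNModel(config.model, seed=seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(seed + 1)

    train_idx = np.asarray(splits.train, dtype=np.intp)
    val_idx = list(splits.valid)

    history: list[dict] = []
    best = (-1, np.inf if _metric_is_loss(config.metric) else -np.inf, None)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            chunk = train_idx[order[lo:lo + config.batch_size]]
            if len(chunk) < 2:
                continue  # train-mode batch norm needs >= 2 molecules
            batch = batch_graphs([graphs[i] for i in chunk])
            y, mask = _stack_targets(records, chunk)
            preds = model.forward(batch, mode="train", rng=rng)
            loss = masked_loss(preds, y, mask, config.task)
            lv = loss.item()
            if not np.isfinite(lv):
                raise TrainingDivergedError(
                    f"non-finite loss {lv} at step {step} (epoch {epoch}); "
                    f"lr={config.learning_rate}, batch={len(chunk)}",
                    step=step, loss=lv)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(lv)
            step += 1
        val_metric = np.nan
        if val_idx:
            try:
                val_metric = _evaluate_indices(model, records, graphs,
                                               val_idx, config)
            except DataError:
                # e.g. a single-class validation split: AUC undefined
                val_metric = np.nan
        entry = {"epoch": epoch,
                 "train_loss": float(np.mean(epoch_losses)) if epoch_losses
                 else np.nan,
                 "val_metric": float(val_metric)}
        history.append(entry)
        if val_idx:
            better = (val_metric < best[1] if _metric_is_loss(config.metric)
                      else val_metric > best[1])
            if better:
                best = (epoch, val_metric, model.snapshot())
    if best[2] is not None:
        model.load_state_arrays(best[2])
        best_epoch, best_val = best[0], float(best[1])
    else:  # no validation set: keep the final parameters
        best_epoch, best_val = config.epochs - 1, float("nan")
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_metric=best_val)


def _evaluate_indices(model: DHTNNModel, records, graphs,
                      idx: Sequence[int], config: TrainConfig) -> float:
    batch = batch_graphs([graphs[i] for i in idx])
    preds = model.predict(batch, context=config.eval_context)
    y, mask = _stack_targets(records, idx)
    return _metric_value(config, preds, y, mask)


def evaluate(model: DHTNNModel, records: Sequence[MoleculeRecord],
             indices: Sequence[int], config: TrainConfig) -> float:
    """Config metric on the given record indices (single-molecule context
    by default, so each prediction is independent of its batch mates)."""
    graphs = _featurize_records([records[i] for i in indices],
                                config.model.feature_scheme)
    batch = batch_graphs(graphs)
    preds = model.predict(batch, context=config.eval_context)
    y, mask = _stack_targets(records, list(indices))
    return _metric_value(config, preds, y, mask)


# --------------------------------------------------------------------------
# activation-comparison harness
# --------------------------------------------------------------------------

def compare_activations(records: Sequence[MoleculeRecord],
                        config: TrainConfig,
                        activations: Sequence[ActivationSpec | str],
                        seeds: Sequence[int],
                        splits: SplitIndices | None = None,
                        dataset_id: str = "") -> list[EvalReport]:
    """Retrain under each activation with everything else held fixed.

    Same splits and same per-seed init/shuffle streams for every
    activation; emits one mean +/- std row per activation.
    """
    if not activations:
        raise ConfigurationError("need at least one activation")
    if splits is None:
        from .graphio import random_split
        splits = random_split(len(records), seed=min(seeds, default=0))
    rows: list[EvalReport] = []
    for act in activations:
        spec = act if isinstance(act, ActivationSpec) else ActivationSpec(act)
        cfg = copy.deepcopy(config)
        cfg.model.activation = spec.name
        cfg.model.beaf_c = spec.c
        values = []
        for seed in seeds:
            result = train_model(records, splits, cfg, seed=seed)
            values.append(evaluate(result.model, records, splits.test, cfg))
        rows.append(EvalReport(metric=cfg.metric, values=values,
                               seeds=list(seeds),
                               split_method=splits.method,
                               dataset_id=dataset_id,
                               activation=spec.name))
    return rows


def format_comparison(rows: list[EvalReport]) -> str:
    """Render the comparison as an aligned text table."""
    lines = [f"{'activation':<12}{'metric':<10}{'mean':>10}{'std':>10}  per-seed"]
    for r in rows:
        std = "n/a" if r.std is None else f"{r.std:.4f}"
        per = ", ".join(f"{v:.4f}" for v in r.values)
        lines.append(f"{r.activation:<12}{r.metric:<10}{r.mean:>10.4f}"
                     f"{std:>10}  [{per}]")
    return "\n".join(lines)
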