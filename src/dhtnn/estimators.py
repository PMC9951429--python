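"""scikit-learn style estimators over the DHTNN pipeline.

`DHTNNRegressor` and `DHTNNClassifier` wrap the training loop behind the
fit/predict contract so the model composes with sklearn pipelines and
model selection.  X is a sequence of SMILES strings; y is an array of
shape (n,) or (n, n_tasks).  NaN entries of y are treated as unobserved
labels (masked out of loss and metrics).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DataError
from .graphio import MoleculeRecord, SplitIndices, random_split
from .model import ModelConfig
from .training import TrainConfig, train_model

__all__ = ["DHTNNRegressor", "DHTNNClassifier"]


class _BaseDHTNN(BaseEstimator):
    """Shared fit machinery; subclasses fix the task."""

    _task = "regression"

    def __init__(self, hidden_size=64, depth=3, dropout=0.1,
                 activation="beaf", beaf_c=0.002, tau="relu",
                 aggregation="sum", n_heads=2, mlp_expansion=4,
                 droppath_rate=0.1, n_blocks=1,
                 epochs=30, batch_size=50, learning_rate=1e-3,
                 validation_fraction=0.1, random_state=0):
        self.hidden_size = hidden_size
        self.depth = depth
        self.dropout = dropout
        self.activation = activation
        self.beaf_c = beaf_c
        self.tau = tau
        self.aggregation = aggregation
        self.n_heads = n_heads
        self.mlp_expansion = mlp_expansion
        self.droppath_rate = droppath_rate
        self.n_blocks = n_blocks
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _records(self, X: Sequence[str], y: np.ndarray) -> list[MoleculeRecord]:
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != y.shape[0]:
            raise ConfigurationError("X and y lengths differ")
        mask = np.isfinite(y)
        return [MoleculeRecord(smiles=s, targets=np.where(mask[i], y[i], 0.0),
                               mask=mask[i]) for i, s in enumerate(X)]

    def _train_config(self, n_tasks: int) -> TrainConfig:
        model = ModelConfig(
            n_tasks=n_tasks, task=self._task,
            hidden_size=self.hidden_size, depth=self.depth,
            dropout=self.dropout, aggregation=self.aggregation,
            activation=self.activation, beaf_c=self.beaf_c, tau=self.tau,
            n_heads=self.n_heads, mlp_expansion=self.mlp_expansion,
            droppath_rate=self.droppath_rate, n_blocks=self.n_blocks)
        return TrainConfig(task=self._task, epochs=self.epochs,
                           batch_size=self.batch_size,
                           learning_rate=self.learning_rate, model=model)

    def fit(self, X: Sequence[str], y):
        records = self._records(X, y)
        n = len(records)
        if n < 3:
            raise DataError("need at least 3 molecules to fit")
        n_tasks = records[0].targets.shape[0]
        if self.validation_fraction > 0:
            split = random_split(n, seed=self.random_state)
            # fold the 8:1:1 test part back into training: fit() holds
            # nothing out beyond the model-selection validation split
            split = SplitIndices(train=sorted(split.train + split.test),
                                 valid=split.valid, test=[],
                                 method="random", seed=self.random_state)
        else:
            split = SplitIndices(train=list(range(n)), valid=[], test=[],
                                 method="random", seed=self.random_state)
        config = self._train_config(n_tasks)
        result = train_model(records, split, config, seed=self.random_state)
        self.model_ = result.model
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.n_tasks_ = n_tasks
        self.n_features_in_ = 1  # one SMILES column
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise DataError("estimator is not fitted; call fit() first")

    def _raw(self, X: Sequence[str]) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict_smiles(list(X))


class DHTNNRegressor(_BaseDHTNN):
    """Molecular property regressor (RMSE-oriented)."""

    _task = "regression"

    def predict(self, X: Sequence[str]) -> np.ndarray:
        out = self._raw(X)
        return out[:, 0] if self.n_tasks_ == 1 else out

    def score(self, X: Sequence[str], y) -> float:
        """Negative RMSE (greater is better, sklearn convention)."""
        from .training import rmse
        y = np.asarray(y, dtype=np.float64)
        pred = np.asarray(self.predict(X), dtype=np.float64)
        m = np.isfinite(y)
        return -rmse(pred[m], y[m])


class DHTNNClassifier(_BaseDHTNN):
    """Molecular property classifier emitting per-task probabilities."""

    _task = "classification"

    def fit(self, X: Sequence[str], y):
        y = np.asarray(y, dtype=np.float64)
        obs = y[np.isfinite(y)]
        if not np.all(np.isin(obs, (0.0, 1.0))):
            raise DataError("classification labels must be 0/1 (NaN = missing)")
        super().fit(X, y)
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        out = self._raw(X)
        return out[:, 0] if self.n_tasks_ == 1 else out

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        if self.n_tasks_ == 1:
            return np.column_stack([1.0 - p, p])
        return p

    def predict(self, X: Sequence[str]) -> np.ndarray:
        z = self.decision_function(X)
        return (z > 0).astype(np.float64)

    def score(self, X: Sequence[str], y) -> float:
        """Task-averaged ROC-AUC on observed labels."""
        from .training import roc_auc
        y = np.asarray(y, dtype=np.float64)
        scores = self.decision_function(X)
        return roc_auc(scores, np.where(np.isfinite(y), y, 0.0),
                       np.isfinite(y))
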