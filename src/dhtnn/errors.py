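"""Exception taxonomy shared across the package."""


class DHTNNError(Exception):
    """Base class for package errors."""


class ConfigurationError(DHTNNError, ValueError):
    """Invalid configuration: bad column names, shapes, hyperparameter ranges."""


class DataError(DHTNNError, ValueError):
    """Input data cannot support the requested operation."""


class ParseError(DataError):
    """A SMILES string failed to parse."""


class TrainingDivergedError(DHTNNError, RuntimeError):
    """Loss became non-finite during training; carries diagnostics."""

    def __init__(self, message: str, step: int | None = None,
                 loss: float | None = None):
        super().__init__(message)
        self.step = step
        self.loss = loss
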