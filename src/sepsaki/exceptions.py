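"""Exception hierarchy.

All user-input problems derive from :class:`SepsakiError` so CLI code can
catch one type and exit with a readable message.
"""


class SepsakiError(Exception):
    """Base class for all package errors."""


class ValidationError(SepsakiError, ValueError):
    """Malformed or inconsistent input data (timelines, tables, triples)."""


class ConfigError(SepsakiError, ValueError):
    """Bad configuration: shape mismatches, negative hyperparameters,
    unknown config keys."""


class GraphLookupError(SepsakiError, KeyError):
    """Unknown entity or relation identifier."""


class SamplingError(SepsakiError, RuntimeError):
    """Negative sampling could not find a corruption within the retry
    budget (graph too dense)."""


class TrainingError(SepsakiError, RuntimeError):
    """Non-finite loss or other optimisation failure; carries the loss
    trace accumulated so far."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class NotFittedError(SepsakiError, RuntimeError):
    """Prediction requested from an untrained model."""


class MetricUndefinedError(SepsakiError, ValueError):
    """A requested metric is undefined for the given data
    (e.g. sensitivity with no positive labels)."""
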