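"""Exception hierarchy shared across pipeline stages."""


class RlmvpaError(Exception):
    """Base class for all package errors."""


class ConfigError(RlmvpaError, ValueError):
    """Invalid configuration (bad divisibility, probabilities, shapes...)."""


class ParameterError(RlmvpaError, ValueError):
    """Agent or model parameters outside their legal domain."""


class InputError(RlmvpaError, ValueError):
    """Malformed data handed to an operation (unordered trials, bad joins...)."""


class FitError(RlmvpaError, RuntimeError):
    """Optimizer failed on all restarts; carries diagnostics."""


class TrainingError(RlmvpaError, ValueError):
    """Decoder cannot be trained (e.g. single-class training set)."""


class DegenerateDesignError(RlmvpaError, ValueError):
    """A model term is inestimable (e.g. constant moderator)."""
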