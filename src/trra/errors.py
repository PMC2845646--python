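"""Exception hierarchy shared by all pipeline stages."""


class TrraError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TrraError):
    """Invalid generator or pipeline configuration."""


class InputError(TrraError):
    """Malformed input data (duplicate rows, missing records, broken references)."""


class StageError(TrraError):
    """Expression-matrix operation applied at the wrong processing stage."""


class TrainingError(TrraError):
    """Operon classifier cannot be trained from the given examples."""
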