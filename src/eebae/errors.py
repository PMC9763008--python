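"""Exception hierarchy for the adaptive-estimation engine."""


class EEBAEError(Exception):
    """Base class for all package errors."""


class ConfigError(EEBAEError):
    """Invalid experiment configuration (bad JSON schema, inverted range, ...)."""


class ModelError(EEBAEError):
    """Invalid psychometric-model input or a non-finite model output."""


class InferenceError(EEBAEError):
    """Posterior update failure (e.g. zero normalizing constant)."""


class EntropyBoundError(EEBAEError):
    """The information-theoretic bound max_d I(Theta;Y|d) <= H(Theta) was violated.

    This bound holds exactly for any discrete posterior and any stimulus; a
    violation beyond numerical tolerance indicates a defect, so it is raised
    rather than logged.
    """
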