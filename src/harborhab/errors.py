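"""Exception types shared across the pipeline stages."""


class HarborHabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HarborHabError):
    """Invalid user-supplied configuration (bad ranges, empty grids, ...)."""


class ConsistencyError(HarborHabError):
    """Inputs that violate a cross-table contract (e.g. a detection logged
    at a receiver outside any of its deployment windows), signalling
    upstream corruption rather than a modelling problem."""


class ModelDegenerateError(HarborHabError):
    """Raised when a model cannot be fit meaningfully, e.g. single-class
    training data for a presence/absence classifier."""
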