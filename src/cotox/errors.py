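"""Exception hierarchy for cotox."""


class CotoxError(Exception):
    """Base class for all cotox errors."""


class ModelFormatError(CotoxError):
    """Malformed model document (bad cell, duplicate label, ragged row)."""


class UnknownLabelError(CotoxError, KeyError):
    """A taxon/resource/toxin label not present in the model."""


class ParameterError(CotoxError, ValueError):
    """Invalid generation or configuration parameters."""


class CapacityError(CotoxError):
    """An exact combinatorial search would exceed its size cap."""


class InfeasibleError(CotoxError):
    """A required resource cannot be covered by any producer."""


class IntegrityError(CotoxError):
    """Inputs violate a contract (e.g. a claimed organization fails the predicate)."""


class InconsistencyError(CotoxError):
    """Measured data cannot be explained within the model class."""
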