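"""Exception hierarchy for grasspred."""


class GrassPredError(Exception):
    """Base class for all package errors."""


class InvalidModelError(GrassPredError, ValueError):
    """A simulation or statistical model was configured inconsistently."""


class InvalidParameterError(GrassPredError, ValueError):
    """A parameter value is outside its admissible range."""


class DataError(GrassPredError, ValueError):
    """Input data violate a precondition (ids, shapes, missingness)."""


class ConfigurationError(GrassPredError, ValueError):
    """A run/filter configuration references unavailable fields or files."""
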