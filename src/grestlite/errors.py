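"""Exception hierarchy."""


class GrestliteError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GrestliteError):
    """A file could not be parsed in the declared format."""


class ShapeError(GrestliteError):
    """Array/atom-count mismatch between related objects."""


class ValidationError(GrestliteError):
    """A domain object violates one of its invariants."""


class SelectionError(GrestliteError):
    """Solute selection cannot satisfy its postconditions."""


class ConstructionError(GrestliteError):
    """Toy-system construction parameters are infeasible."""


class ParameterError(GrestliteError):
    """A required physical parameter (radius, mass, ...) is unavailable."""


class IntegrationError(GrestliteError):
    """The propagator produced non-finite forces or coordinates."""
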