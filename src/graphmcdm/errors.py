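"""Exception taxonomy.

Three failure classes map onto the CLI exit codes: validation problems
(malformed inputs, bad configuration) exit 2, numerical degeneracies
(constant columns, all-identical points, zero information content) exit 3,
and I/O failures exit 4.
"""


class GraphMCDMError(Exception):
    """Base class for all package errors."""


class ValidationError(GraphMCDMError):
    """Malformed input or configuration; nothing was computed."""

    exit_code = 2


class DuplicateIdError(ValidationError):
    """An alternative or criterion identifier occurs more than once."""


class NonNumericCellError(ValidationError):
    """A decision-matrix cell could not be parsed as a finite number."""


class MissingDirectionError(ValidationError):
    """No benefit/cost direction was supplied for a criterion."""


class ShapeMismatchError(ValidationError):
    """Two objects that must share alternatives/criteria do not."""


class UnknownMethodError(ValidationError):
    """A method name is not one of the supported variants."""


class ConfigError(ValidationError):
    """A pipeline configuration field is outside its stated domain."""


class DegeneracyError(GraphMCDMError):
    """The input is valid but numerically degenerate for this operation."""

    exit_code = 3


class DegenerateColumnError(DegeneracyError):
    """A criterion column has no dispersion (or is all zero) where the
    operation requires contrast."""


class DegenerateWeightsError(DegeneracyError):
    """Every criterion carries zero information content / removal effect,
    so objective weights are undefined."""


class IdenticalAlternativesError(DegeneracyError):
    """All alternatives coincide; distances or ideals are undefined."""
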