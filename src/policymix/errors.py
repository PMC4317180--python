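"""Exception hierarchy shared across the package."""


class PolicymixError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PolicymixError):
    """An input table is missing a required column or has the wrong dtype."""


class ReferentialError(PolicymixError):
    """A cell references a district that does not exist."""


class ValidationError(PolicymixError):
    """A table violates a domain invariant (offending rows are listed)."""


class GenerationError(PolicymixError):
    """A synthetic-landscape request is infeasible as parameterized."""


class ConfigurationError(PolicymixError):
    """An operation received inconsistent or degenerate inputs."""


class FittingError(PolicymixError):
    """A statistical fit cannot proceed (e.g. degenerate outcomes)."""
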