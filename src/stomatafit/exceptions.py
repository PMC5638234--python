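"""Exception hierarchy shared across the package."""


class StomatafitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(StomatafitError, ValueError):
    """A value violates a model precondition (e.g. Cs <= gamma_star)."""


class SchemaError(StomatafitError):
    """An input table cannot be mapped onto the canonical gas-exchange schema."""


class ConfigError(StomatafitError):
    """A pipeline configuration is malformed or inconsistent."""


class SpeciesExcluded(StomatafitError):
    """A species fails an inclusion criterion (e.g. <3 distinct psi values).

    Raised at species level; panel-level drivers catch it and log the
    exclusion instead of aborting.
    """


class UndefinedSignal(StomatafitError):
    """A requested quantity is undefined for this input (e.g. psi_gs50 of an
    erratic curve, constant covariate in a bias regression)."""
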