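"""Exception hierarchy shared across the package."""


class GlosensError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(GlosensError):
    """The input file could not be parsed as a kinetic model."""


class UnsupportedFeatureError(GlosensError):
    """The model uses a construct this package does not support.

    The message names the offending construct (e.g. algebraic rules,
    delay expressions).
    """


class ModelInvariantError(GlosensError):
    """A structural invariant of a kinetic model is violated."""


class CompletenessError(GlosensError):
    """A parameter set does not cover every model parameter."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"parameter set is missing ids: {', '.join(self.missing)}")


class SymbolResolutionError(GlosensError):
    """A rate expression references a symbol that is not a species,
    parameter or compartment of the model."""


class UnscalableParameterError(GlosensError):
    """A scaled sensitivity was requested for a parameter whose reference
    value is zero (the scaling divides by it)."""


class FixtureError(GlosensError):
    """Invalid arguments to a synthetic-model constructor."""


class ConfigError(GlosensError):
    """Invalid run configuration."""
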