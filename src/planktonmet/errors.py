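"""Exception hierarchy shared across the pipeline."""


class PlanktonMetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PlanktonMetError):
    """A required column is missing or a table does not match its schema."""


class StructuralError(PlanktonMetError):
    """The file parses but its content is structurally incomplete
    (e.g. a station/depth lacking one of the three bottle treatments)."""


class InsufficientReplicationError(PlanktonMetError):
    """Fewer than two replicates in a treatment; no rate/s.e. can be formed."""


class InsufficientDataError(PlanktonMetError):
    """Too few observations for the requested statistic."""


class ExtrapolationError(PlanktonMetError):
    """Deepest sample is too shallow to integrate to the euphotic depth."""


class DegenerateProfileError(PlanktonMetError):
    """A CTD series carries no usable vertical structure (e.g. flat chlorophyll)."""


class NoThermoclineError(DegenerateProfileError):
    """Temperature profile is effectively isothermal; no gradient maximum."""


class SingularFitError(PlanktonMetError):
    """Regression cannot be estimated (zero predictor variance or n too small)."""


class DegenerateTestError(PlanktonMetError):
    """A hypothesis test is undefined (zero standard error)."""


class ConfigError(PlanktonMetError):
    """A simulation/configuration field violates its invariant."""
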