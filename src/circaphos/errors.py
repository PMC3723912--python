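"""Exception hierarchy for the pipeline.

All pipeline errors derive from :class:`CircaphosError` so callers can
catch one base class; subclasses name the failure mode.
"""


class CircaphosError(Exception):
    """Base class for all package errors."""


class ParameterError(CircaphosError, ValueError):
    """A simulation or analysis parameter violates an invariant."""


class SchemaError(CircaphosError, ValueError):
    """An input table is missing a required column or has a bad dtype."""


class DegenerateFitError(CircaphosError):
    """The harmonic design matrix is rank deficient (e.g. period >> span)."""


class ArrhythmicError(CircaphosError):
    """A phase was requested from a fit flagged as arrhythmic."""


class InsufficientReplicatesError(CircaphosError):
    """A statistical comparison has fewer than two usable replicates."""


class PairingError(CircaphosError):
    """Treated wells could not be matched to control wells."""


class DataInconsistencyError(CircaphosError):
    """Conflicting annotations for the same phospho-site."""


class CoordinateError(CircaphosError, ValueError):
    """A site position falls outside its protein sequence."""


class PartitionError(CircaphosError, ValueError):
    """A permutation test was asked for with an empty group."""


class SizeError(CircaphosError):
    """An exhaustive enumeration exceeds its combinatorial bound."""


class ConfigError(CircaphosError, ValueError):
    """A pipeline configuration file is invalid or has unknown keys."""
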