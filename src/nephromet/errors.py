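"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI lives in :mod:`nephromet.cli`:
schema errors exit 2, configuration errors 3, statistical degeneracy 4.
"""


class NephrometError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NephrometError, ValueError):
    """Invalid threshold, bootstrap or cohort configuration."""


class SchemaError(NephrometError, ValueError):
    """Input table violates the expected schema or an invariant."""


class InputError(NephrometError, ValueError):
    """A single measurement or argument is out of its valid domain."""


class DegenerateStatisticError(NephrometError, ValueError):
    """A statistic is undefined on the given data (zero variance,
    one-category marginals, too-small samples)."""
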