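"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so keep the taxonomy coarse:
schema/parsing problems, geometric degeneracy, and statistical infeasibility.
"""


class CranioangleError(Exception):
    """Base class for all package errors."""


class SchemaError(CranioangleError):
    """Input violates the landmark/cohort schema (missing names, bad labels...)."""


class ParseError(SchemaError):
    """Input could not be parsed at all (non-numeric coordinate, bad JSON...)."""


class DegenerateGeometryError(CranioangleError):
    """Landmark configuration too degenerate to define a direction or alignment."""


class StatsError(CranioangleError):
    """A statistical computation is infeasible for the given inputs."""
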