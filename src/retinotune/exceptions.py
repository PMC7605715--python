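"""Exception hierarchy.

All errors raised by this package derive from :class:`RetinotuneError`, so
callers can catch one type at a pipeline boundary while tests can assert on
the specific failure mode.
"""


class RetinotuneError(Exception):
    """Base class for all package errors."""


class TrajectoryParseError(RetinotuneError):
    """A trajectory file violated the expected dialect (frame/atom bookkeeping)."""


class DegenerateGeometryError(RetinotuneError):
    """Zero-length bond vector or collinear torsion axis; no angle is defined."""


class MissingAtomError(RetinotuneError):
    """A frame or trajectory lacks an atom required by an angle definition."""


class TableValidationError(RetinotuneError):
    """A pigment or median table failed a structural validation check."""


class ModelFitError(RetinotuneError):
    """A regression could not be fit (rank deficiency, too few observations)."""
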