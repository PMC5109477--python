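"""Exception hierarchy for fluctcorr.

All package errors derive from :class:`FluctcorrError` so callers can catch
one base class; the CLI maps them to exit code 1 (usage problems exit 2).
"""


class FluctcorrError(Exception):
    """Base class for all fluctcorr errors."""


class FormatError(FluctcorrError):
    """A file could not be parsed in the expected format."""


class SelectionError(FluctcorrError):
    """A site selection resolved to nothing or is otherwise invalid."""


class IntegrityError(FluctcorrError):
    """Trajectory frames are mutually inconsistent (e.g. atom-count drift)."""


class DegenerateSuperpositionError(FluctcorrError):
    """Too few / collinear sites: the optimal rotation is not unique."""


class InsufficientDataError(FluctcorrError):
    """Not enough frames (or samples) for the requested estimator."""


class AlignmentError(FluctcorrError):
    """Two labelled objects do not share the same sites."""


class SpecError(FluctcorrError):
    """A synthetic-generator specification violates its invariants."""


class BinningError(FluctcorrError):
    """Too few samples per bin for the conditional (binned) estimator."""
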