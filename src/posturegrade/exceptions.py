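"""Exception hierarchy.

Degenerate geometry raises instead of silently returning zero angles:
a coincident-landmark artefact fed into the severity classifier would
corrupt gradings without any visible failure.
"""


class PostureGradeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PostureGradeError, ValueError):
    """Malformed, empty, or out-of-contract input."""


class DegenerateGeometryError(PostureGradeError, ValueError):
    """Coincident landmarks or other geometry with no defined angle/distance."""


class InvalidPostureError(PostureGradeError, ValueError):
    """Landmark set violating the upright-subject conventions (e.g. head below ankle)."""


class InfeasibleTargetError(PostureGradeError, ValueError):
    """Feature target outside the geometrically realizable region."""


class UndefinedStatisticError(PostureGradeError, ValueError):
    """Statistic undefined for the input (e.g. constant sample, zero variance)."""
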