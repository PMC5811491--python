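"""Exception hierarchy shared across the package."""


class ComorbnetError(Exception):
    """Base class for all package-specific errors."""


class MalformedRecordError(ComorbnetError):
    """A line or record in an input file could not be parsed.

    Carries file/line context in the message so a user can locate the
    offending record.
    """


class EmptyInputError(ComorbnetError):
    """An input that must be non-empty (gene list, edge list) was empty."""


class InvalidCountError(ComorbnetError):
    """Overlap/margin counts violate 0 <= k <= min(n, K), n, K <= N."""


class UnknownTermError(ComorbnetError):
    """A term id was requested that is not in the annotation collection."""


class UnknownNodeError(ComorbnetError):
    """A node was requested that is not in the (sub)network."""


class EmptyIntersectionError(ComorbnetError):
    """No gene of the tested set maps into the annotation universe, or no
    seed maps into the interaction network."""


class InfeasibleConstraintError(ComorbnetError):
    """Synthetic-data generation parameters cannot be satisfied."""


class PipelineStageError(ComorbnetError):
    """A pipeline stage failed; message is prefixed with the stage name."""
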