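"""Exception hierarchy."""


class MitotopoError(Exception):
    """Base class for package errors."""


class InvalidParameterError(MitotopoError, ValueError):
    """A parameter violates its contract (range, sign, ordering)."""


class ExtractionError(MitotopoError):
    """Skeleton-to-graph tracing failed (e.g. ambiguous voxel)."""


class EmbeddingError(MitotopoError):
    """A component could not be embedded as a clean voxel skeleton."""


class FitError(MitotopoError):
    """Distribution fit impossible (e.g. too few support points)."""
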