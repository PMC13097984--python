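"""Exception hierarchy shared across the pipeline stages."""


class NestNerError(Exception):
    """Base class for all package-specific errors."""


class MalformedAnnotationError(NestNerError):
    """A standoff annotation line cannot be parsed or validated."""


class SurfaceMismatchError(MalformedAnnotationError):
    """The annotated surface string disagrees with the text slice."""


class DiscontinuousSpanError(MalformedAnnotationError):
    """Discontinuous brat fragments (``start end;start end``) are unsupported."""


class LayerCapacityError(NestNerError):
    """A span set requires more BIO layers than the configured maximum."""

    def __init__(self, message, unplaced=()):
        super().__init__(message)
        self.unplaced = list(unplaced)


class AlignmentError(NestNerError):
    """A span boundary cannot be reconciled with token boundaries."""


class MissingArtifactError(NestNerError):
    """An upstream pipeline artifact is absent."""
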