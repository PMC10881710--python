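"""Exception hierarchy for mvphantom."""


class MVPhantomError(Exception):
    """Base class for all package errors."""


class InvalidFrameError(MVPhantomError):
    """An axis frame is not a proper orthonormal rotation."""


class ParameterError(MVPhantomError):
    """A numeric parameter violates its contract."""


class ConfigError(MVPhantomError):
    """A configuration document is malformed or names unknown entities."""


class InsufficientLandmarksError(MVPhantomError):
    """Fewer than 3 non-collinear matched landmarks for rigid alignment."""


class OutOfBoundsError(MVPhantomError):
    """Geometry falls outside the world bounds of a label volume."""

    def __init__(self, message, vertex_ids=None):
        super().__init__(message)
        self.vertex_ids = list(vertex_ids) if vertex_ids is not None else []


class GeometryError(MVPhantomError):
    """Degenerate geometry (collinear points, rank-deficient covariance...)."""


class DivergenceError(MVPhantomError):
    """The dynamics solver produced non-finite positions."""

    def __init__(self, message, frame=None):
        super().__init__(message)
        self.frame = frame


class InsufficientAnnotationError(MVPhantomError):
    """Too few annotated points for the requested quantification."""
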