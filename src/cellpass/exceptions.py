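"""Exception types shared across the package."""


class CellPassError(Exception):
    """Base class for all package-specific errors."""


class SingularEvaluationError(CellPassError, ZeroDivisionError):
    """A field (or its gradient) was evaluated exactly at a source position."""


class GeometryError(CellPassError, ValueError):
    """Invalid geometric input, e.g. a degenerate polygon or mesh."""


class ParameterError(CellPassError, ValueError):
    """Physically inconsistent parameter combination."""


class IntegrationUnstableError(CellPassError, RuntimeError):
    """A node moved further than one cell radius in a single step.

    The usual remedy is a smaller time step, especially when many nodes
    are in simultaneous contact with an obstacle.
    """


class UndefinedCorrelationError(CellPassError, ValueError):
    """Pearson correlation requested for a zero-variance input."""
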