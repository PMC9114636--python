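"""Exception hierarchy.

All library errors derive from :class:`MapcaError` so callers can catch one
type; the subclasses additionally inherit from the matching builtin so that
generic handlers (``except ValueError``) keep working.
"""


class MapcaError(Exception):
    """Base class for all mapca errors."""


class ParameterError(MapcaError, ValueError):
    """A parameter value is outside its admissible range."""


class InputError(MapcaError, ValueError):
    """Input data is malformed (wrong shape, non-finite entries, ...)."""


class DegenerateGraphError(MapcaError, RuntimeError):
    """A graph row has no positive neighbor weight (numerical underflow)."""


class SingularSystemError(MapcaError, RuntimeError):
    """The normal-equation matrix is singular even after jitter."""


class DescentDiagnosticError(MapcaError, RuntimeError):
    """The objective increased for several consecutive cycles.

    Alternating exact coordinate minimization cannot increase the objective,
    so this signals an implementation or severe conditioning problem.
    """
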