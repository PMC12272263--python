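"""Exception hierarchy shared across the package.

All errors derive from :class:`TmsNetError` so callers can catch pipeline
failures with a single ``except`` clause; each subclass also derives from
the closest built-in so idiomatic ``except ValueError`` still works.
"""


class TmsNetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TmsNetError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class InputError(TmsNetError, ValueError):
    """An input array/file is malformed (wrong shape, bad index, empty)."""


class GeometryError(TmsNetError, ValueError):
    """A geometric construction is impossible (grid off the patch, a field
    evaluation point on a coil winding, ...)."""


class DegenerateInputError(TmsNetError, ValueError):
    """Input is syntactically valid but carries no usable signal
    (all-zero field map, empty suprathreshold set, ...)."""
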