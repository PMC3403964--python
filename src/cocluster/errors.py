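"""Exception hierarchy shared across the package."""


class CoclusterError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CoclusterError, ValueError):
    """An input value violates a documented precondition."""


class ShapeMismatchError(CoclusterError, ValueError):
    """Arrays that must share a shape do not."""


class ChannelIndexError(CoclusterError, IndexError):
    """A channel map requests a page/channel that the file does not have."""


class CapacityError(CoclusterError, ValueError):
    """A layout cannot hold the number of cells requested."""


class DegenerateGLCMError(CoclusterError, ValueError):
    """No valid pixel pairs exist for co-occurrence counting."""


class DegenerateChannelError(CoclusterError, ValueError):
    """A channel is constant, so an automatic threshold is undefined."""
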