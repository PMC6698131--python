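"""Exception hierarchy shared across the toolkit."""


class NsltpError(Exception):
    """Base class for all toolkit errors."""


class InputError(NsltpError, ValueError):
    """Invalid value supplied by the caller (bad residue, inconsistent counts...)."""


class FormatError(NsltpError, ValueError):
    """A file did not conform to its expected format."""


class LookupIdError(NsltpError, KeyError):
    """An id was not found where it was required."""


class ConsistencyError(NsltpError, ValueError):
    """Two inputs that must agree (e.g. tree leaves vs alignment ids) do not."""


class GeometryError(NsltpError, ValueError):
    """Degenerate geometry: too few points or collinear configurations."""
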