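"""Exception hierarchy shared by all pipeline stages."""


class CiliacoatError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CiliacoatError):
    """A file could not be parsed, or its contents violate a format invariant."""


class ValidationError(CiliacoatError):
    """An in-memory object violates one of its declared invariants."""


class ParameterError(CiliacoatError):
    """A caller-supplied parameter is out of its allowed range."""


class FitError(CiliacoatError):
    """A geometric fit (spline, superposition) could not be performed."""
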