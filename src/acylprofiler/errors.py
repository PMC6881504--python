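"""Exception hierarchy shared by all pipeline stages."""


class AcylProfilerError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(AcylProfilerError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(AcylProfilerError):
    """Input data violates a documented invariant (coordinates, scores, ...)."""


class ConfigError(AcylProfilerError):
    """A simulation or run configuration is inconsistent or infeasible."""
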