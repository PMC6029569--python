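"""Exception hierarchy."""


class TermistdError(Exception):
    """Base class for package errors."""


class ParameterError(TermistdError, ValueError):
    """An operation was called with an invalid parameter."""


class FormatError(TermistdError, ValueError):
    """A file or identifier does not conform to its expected format."""


class PipelineError(TermistdError, RuntimeError):
    """A pipeline stage failed; message carries stage name and genome id."""
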