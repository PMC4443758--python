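"""Exception hierarchy shared across the package."""


class ParameterError(ValueError):
    """A parameter or window violates an operation's precondition."""


class TraceFormatError(ValueError):
    """A trace file or its JSON sidecar is missing or malformed."""


class TraceDataError(ValueError):
    """Trace data are internally inconsistent (non-monotonic time, NaNs...)."""


class FitError(RuntimeError):
    """A curve fit failed to converge; carries diagnostic context."""


class PipelineError(RuntimeError):
    """One or more pipeline stages failed."""
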