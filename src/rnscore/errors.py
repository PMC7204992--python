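"""Exception hierarchy shared by all pipeline stages."""


class RnscoreError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RnscoreError):
    """An input file violates its declared format."""


class ValidationError(RnscoreError):
    """Parsed data violate a domain invariant."""


class ParameterError(RnscoreError):
    """A user-supplied parameter is outside its admissible range."""


class PipelineError(RnscoreError):
    """A stage cannot proceed given the outputs of earlier stages."""
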