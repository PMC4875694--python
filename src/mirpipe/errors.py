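"""Exception types shared across the toolkit."""


class MirpipeError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MirpipeError):
    """A file does not conform to its declared format/dialect."""


class ValidationError(MirpipeError):
    """Input violates a documented invariant (duplicate ids, bad coordinates, ...)."""
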