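"""Exception hierarchy shared across the pipeline stages."""


class LesionFuseError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(LesionFuseError, ValueError):
    """A precondition on an operation's arguments was violated."""


class ConfigurationError(LesionFuseError, ValueError):
    """An unknown backbone, layer, classifier or config value was requested."""


class AlignmentError(LesionFuseError, ValueError):
    """Two feature matrices do not describe the same samples in the same order."""
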