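"""Exception hierarchy shared across the pipeline stages."""


class CoretreeError(Exception):
    """Base class for all pipeline errors."""


class ParseError(CoretreeError):
    """Input file could not be parsed."""


class EmptyGenomeError(CoretreeError):
    """A genome file yielded no usable coding sequences."""


class ConfigurationError(CoretreeError):
    """Inconsistent run configuration (missing databases, bad stage names...)."""


class NoLociError(CoretreeError):
    """The screen selected zero loci."""


class IntegrityError(CoretreeError):
    """Cross-stage bookkeeping violated (e.g. selected locus missing from genome)."""


class ExternalToolError(CoretreeError):
    """An external binary failed; carries the tool's stderr."""

    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message + ("\n" + stderr if stderr else ""))
        self.stderr = stderr
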