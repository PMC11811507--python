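"""Exception hierarchy for the metaboreg pipeline."""


class MetaboregError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetaboregError):
    """Invalid simulation or run configuration."""


class FormatError(MetaboregError):
    """Malformed input file; the message locates the offending row/column."""


class GraphError(MetaboregError):
    """Knowledge-graph invariant violation or unreadable graph file."""


class TemplateError(MetaboregError):
    """Invalid pathway template or template query."""


class PipelineError(MetaboregError):
    """A pipeline stage failed; the message names the stage."""
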