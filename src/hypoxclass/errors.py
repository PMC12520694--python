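"""Exception hierarchy shared across the pipeline."""


class HypoxclassError(Exception):
    """Base class for all package errors."""


class ValidationError(HypoxclassError, ValueError):
    """Malformed input or contract violation (CLI exit code 2)."""


class PipelineError(HypoxclassError, RuntimeError):
    """Runtime failure inside a pipeline stage (CLI exit code 1)."""
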