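"""Exception hierarchy shared across the pipeline stages."""


class ImmunohubError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ImmunohubError, ValueError):
    """Invalid configuration or argument combination supplied by the caller."""


class SchemaError(ImmunohubError, ValueError):
    """An input table does not match the declared schema (missing columns etc.)."""


class ParseError(ImmunohubError, ValueError):
    """An input file contains a value that cannot be interpreted."""


class TransformError(ImmunohubError, ValueError):
    """Illegal intensity-transform state (e.g. double arcsinh)."""


class PipelineError(ImmunohubError, RuntimeError):
    """A pipeline stage failed; the message names the stage and its input."""
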