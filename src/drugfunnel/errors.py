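"""Exception hierarchy shared across the pipeline.

Exit codes: 0 success, 2 configuration error, 3 data-format error,
4 stage failure (mapped by the CLI entry point).
"""


class DrugFunnelError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(DrugFunnelError):
    """Invalid configuration value or inconsistent inputs."""

    exit_code = 2


class DataFormatError(DrugFunnelError):
    """Malformed input file; message names file, line and offending content."""

    exit_code = 3


class StageError(DrugFunnelError):
    """A pipeline stage failed; message names the stage and context."""

    exit_code = 4
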