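"""Exception hierarchy; the CLI maps these to documented exit codes."""


class ValidationError(ValueError):
    """Invalid configuration or arguments (CLI exit code 2)."""


class DataError(RuntimeError):
    """Malformed or degenerate input data (CLI exit code 3)."""
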