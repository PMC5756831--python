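"""Exception hierarchy; the CLI maps these to exit codes."""


class ChannelWebError(Exception):
    """Base class for all package errors."""


class InputError(ChannelWebError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


class NumericalError(ChannelWebError):
    """A numerical procedure failed to converge or is infeasible (exit code 3)."""
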