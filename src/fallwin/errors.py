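"""Exception hierarchy: data errors (exit 1) vs usage errors (exit 2)."""


class FallwinError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DataError(FallwinError):
    """Malformed or inconsistent input data (parse failures, bad grids)."""

    exit_code = 1


class UsageError(FallwinError):
    """A precondition on arguments or configuration was violated."""

    exit_code = 2
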