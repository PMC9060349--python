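"""Exception hierarchy."""


class MRANetError(Exception):
    """Base class for all package errors."""


class InputError(MRANetError, ValueError):
    """Malformed or inconsistent user input."""


class ParseError(InputError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IllConditionedError(MRANetError):
    """The global response matrix is too ill-conditioned to invert reliably."""

    def __init__(self, condition: float, cap: float):
        self.condition = condition
        self.cap = cap
        super().__init__(
            f"condition estimate {condition:.3e} exceeds the cap {cap:.3e}; "
            "refusing to solve (consider checking the data rather than regularizing)"
        )


class SingularSubsystemError(MRANetError):
    """One of the per-row (n-1)-dimensional systems is singular."""

    def __init__(self, row_index: int, module_id: str | None = None):
        self.row_index = row_index
        self.module_id = module_id
        label = f"{row_index}" if module_id is None else f"{row_index} ({module_id})"
        super().__init__(f"singular subsystem for row {label}")


class SimulationError(MRANetError):
    """The simulated system is unstable or did not reach a steady state."""
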