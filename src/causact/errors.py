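"""Exception hierarchy shared across the package."""


class CausactError(Exception):
    """Base class for all package errors."""


class ParseError(CausactError):
    """Syntax or semantic error in a domain/problem file.

    Carries 1-based ``line`` and ``column`` of the offending token when
    available.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(message + loc)


class ApplicabilityError(CausactError):
    """An action was applied in a state where its precondition fails."""


class StateCapExceededError(CausactError):
    """Reachability analysis hit the state cap.

    ``graph`` holds the partial state graph explored so far and ``frontier``
    the unexpanded states.
    """

    def __init__(self, message: str, graph=None, frontier=None):
        super().__init__(message)
        self.graph = graph
        self.frontier = frontier


class DeadEndError(CausactError):
    """No applicable action in a state (cannot occur if the always-applicable
    idle action is part of the model)."""


class DegeneracyError(CausactError):
    """All filtering weights vanished at some step; ``step`` names it."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class SchemaError(CausactError):
    """Input table/feature-vector does not match the declared schema."""
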