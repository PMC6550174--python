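"""Exception hierarchy shared across the package."""


class FoodwatchError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FoodwatchError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class DegenerateDataError(FoodwatchError, ValueError):
    """Input data cannot support the requested computation
    (single-class training set, empty outcome level, no co-judged items...)."""


class SeparationError(DegenerateDataError):
    """A regression cannot be fit because the exposure perfectly predicts
    (or is never observed with) the outcome in some stratum."""

    def __init__(self, message: str, stratum: str | None = None):
        super().__init__(message)
        self.stratum = stratum


class ShortfallError(FoodwatchError, ValueError):
    """A sampling pool is too small to supply the requested number of
    unique items; raised instead of silently returning fewer."""

    def __init__(self, message: str, requested: int = 0, available: int = 0):
        super().__init__(message)
        self.requested = requested
        self.available = available


class SchemaError(FoodwatchError, ValueError):
    """An on-disk event log violates its documented schema."""

    def __init__(self, path: str, line: int, field: str, message: str):
        super().__init__(f"{path}:{line}: field '{field}': {message}")
        self.path = path
        self.line = line
        self.field = field
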