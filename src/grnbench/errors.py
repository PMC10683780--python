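"""Exception hierarchy. All grnbench errors derive from GrnBenchError."""


class GrnBenchError(Exception):
    """Base class for all grnbench errors."""


class ConfigurationError(GrnBenchError, ValueError):
    """Invalid configuration: unknown dialect, method, mode or option combination."""


class FormatError(GrnBenchError, ValueError):
    """An input file does not match the expected layout (missing/ambiguous columns)."""


class DataError(GrnBenchError, ValueError):
    """Input values violate a documented invariant (e.g. negative likelihood)."""


class InsufficientDataError(GrnBenchError, ValueError):
    """Too few samples/genes to carry out the requested computation."""


class AlignmentError(GrnBenchError, ValueError):
    """Dataset intersection is empty on some axis."""


class CollinearityError(GrnBenchError, ValueError):
    """Design matrix is rank deficient; carries the most-correlated regulator pair."""

    def __init__(self, message: str, pairs=None):
        super().__init__(message)
        self.pairs = pairs or []
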