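"""Exception hierarchy."""


class KirmotifError(Exception):
    """Base class for package errors."""


class DomainError(KirmotifError, ValueError):
    """Input violates an operation precondition."""


class UnknownPairError(KirmotifError, KeyError):
    """An ordered probe pair has no symbol and extension is disabled."""

    def __init__(self, pair, interval):
        self.pair = tuple(pair)
        self.interval = tuple(interval)
        super().__init__(
            f"probe pair {self.pair} at {self.interval[0]}-{self.interval[1]} "
            "is not in the alphabet and extension is disabled"
        )


class CapacityError(KirmotifError, RuntimeError):
    """The alphabet's reserve symbol pool is exhausted."""


class AnchorError(KirmotifError, ValueError):
    """Anchor constraints are infeasible or were violated."""


class RegistryError(KirmotifError, ValueError):
    """A registry (alphabet, pattern, or structure table) is inconsistent."""


class IntegrityError(KirmotifError, RuntimeError):
    """An internal consistency check failed (coordinates, round trips)."""
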