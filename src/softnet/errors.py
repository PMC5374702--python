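"""Exception hierarchy for softnet."""


class SoftnetError(Exception):
    """Base class for all softnet errors."""


class NetworkFormatError(SoftnetError, ValueError):
    """Raised for malformed eNewick input (dangling #H references, bad syntax)."""


class NetworkCycleError(NetworkFormatError):
    """Raised when #H tag structure induces a directed cycle."""


class NetworkValidationError(SoftnetError, ValueError):
    """Raised when a graph violates the rooted-network invariants."""


class TaxonMismatchError(SoftnetError, ValueError):
    """Raised when two networks are compared over different taxon sets."""

    def __init__(self, only_left, only_right):
        self.only_left = frozenset(only_left)
        self.only_right = frozenset(only_right)
        super().__init__(
            "taxon sets differ: only in first network %s; only in second %s"
            % (sorted(self.only_left), sorted(self.only_right))
        )


class GuardError(SoftnetError, RuntimeError):
    """Raised when a combinatorial enumeration exceeds its guard without force=True."""


class ContractError(SoftnetError, RuntimeError):
    """Raised when an operation is called outside its stated precondition."""


class GenerationError(SoftnetError, RuntimeError):
    """Raised when random-network generation cannot satisfy its constraints."""
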