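"""Exception types shared across the package."""


class StringsanError(Exception):
    """Base class for all package-specific errors."""


class EmptyPattern(StringsanError, ValueError):
    """A forbidden pattern was empty."""


class AlphabetViolation(StringsanError, ValueError):
    """A string contains a symbol outside the declared alphabet."""


class UnknownLetter(StringsanError, KeyError):
    """A letter was queried that the automaton's alphabet does not contain."""


class InfeasibleContext(StringsanError, ValueError):
    """A forbidden pattern occurs inside a context string, so no feasible
    completion exists and sink computation is undefined."""


class BadK(StringsanError, ValueError):
    """The window length k is invalid for the given input (k <= 1, a pattern
    of the wrong length, or a string shorter than k)."""


class LengthMismatch(StringsanError, ValueError):
    """Two label vectors to be compared have different lengths."""


class OracleBudgetExceeded(StringsanError, RuntimeError):
    """The exhaustive-search oracle exceeded its configured enumeration cap."""


class EmptyString(StringsanError, ValueError):
    """Random deletions exhausted the string being edited."""


class NotEnoughPatterns(StringsanError, ValueError):
    """More forbidden patterns were requested than the sampling pool holds."""


class ParseError(StringsanError, ValueError):
    """An input file could not be parsed."""


class DuplicateId(StringsanError, ValueError):
    """Two records in an input collection share an identifier."""


class ShapeMismatch(StringsanError, ValueError):
    """A matrix file does not describe a symmetric square matrix."""
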