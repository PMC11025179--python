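"""Exception types shared across the package."""


class WildtrieError(Exception):
    """Base class for all package errors."""


class InvalidSymbolError(WildtrieError, ValueError):
    """A sequence contains a character outside the alphabet.

    Carries the offending character and its 0-based position so callers
    (and the CLI) can point at the exact base.
    """

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        self.context = context
        where = f" in {context}" if context else ""
        super().__init__(
            f"invalid symbol {char!r} at position {position}{where} "
            f"(not in alphabet; pass coerce_unknown to convert to the wildcard)"
        )


class FormatError(WildtrieError, ValueError):
    """Structurally invalid record data (e.g. quality/sequence length mismatch)."""


class ParseError(WildtrieError, ValueError):
    """A malformed FASTA/FASTQ file."""


class InfeasibleConfigError(WildtrieError, ValueError):
    """A simulation configuration that cannot be satisfied."""
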