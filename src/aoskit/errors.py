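"""Exception hierarchy.

All package-raised errors derive from :class:`AoskitError` so callers (and
the CLI) can distinguish validation problems (exit code 2) from genuine
bugs (exit code 1).
"""


class AoskitError(Exception):
    """Base class for all errors raised by aoskit."""


class HgvsParseError(AoskitError):
    """Malformed HGVS c. syntax; message names the offending token."""


class UnsupportedSyntaxError(HgvsParseError):
    """Syntactically valid HGVS outside the supported coding-DNA subset
    (e.g. intronic offsets such as c.100+2T>C)."""


class ValidationError(AoskitError):
    """Input violates a documented invariant (bounds, reference allele,
    alphabet, group sizes, ...)."""


class AlphabetError(ValidationError):
    """Sequence contains a character outside A/C/G/T."""


class PdbFormatError(AoskitError):
    """Structure file unreadable or missing required records."""
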