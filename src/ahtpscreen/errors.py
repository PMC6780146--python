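"""Exception hierarchy for the screening pipeline."""


class AhtpScreenError(Exception):
    """Base class for all package errors."""


class FormatError(AhtpScreenError):
    """Malformed input file (missing columns, non-FASTA content, ...)."""


class EmptyDatabaseError(AhtpScreenError):
    """An AHTP database file yielded zero valid entries."""


class IntegrityError(AhtpScreenError):
    """Cross-reference violation: duplicate identifiers, orphan hits, ..."""


class GenerationError(AhtpScreenError):
    """Synthetic proteome generation could not satisfy its constraints."""
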