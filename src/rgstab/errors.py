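"""Exception hierarchy for rgstab.

All data problems raise a subclass of :class:`RgstabError`; the CLI maps
usage/config problems to exit code 1 and data-integrity problems to exit
code 2.
"""


class RgstabError(Exception):
    """Base class for all rgstab errors."""


class FormatError(RgstabError):
    """A file is structurally malformed (missing columns, unparseable cells)."""


class IntegrityError(RgstabError):
    """Data violates an invariant (duplicates, inconsistent group labels)."""


class CompletenessError(RgstabError):
    """Required (gene, sample) cells are absent."""


class DomainError(RgstabError):
    """A numeric value lies outside its admissible domain."""
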