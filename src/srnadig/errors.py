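"""Exception hierarchy shared by all modules."""


class SrnaDigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SrnaDigError, ValueError):
    """An input file violates its declared format (bad FASTA record, bad count)."""


class InputError(SrnaDigError, ValueError):
    """A value passed to an operation violates its preconditions."""


class NormalizationError(SrnaDigError, ValueError):
    """RPM normalization is impossible (zero total read count)."""


class UndefinedSiteError(SrnaDigError, KeyError):
    """A cleavage-site quantity was requested at a position with no mapped reads."""
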