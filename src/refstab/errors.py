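"""Exception hierarchy.

All analysis-level failures derive from :class:`RefstabError` so the CLI can
map them to exit code 2 (validation) while plain I/O failures map to 3.
"""


class RefstabError(Exception):
    """Base class for all refstab validation/analysis errors."""


class MatrixFormatError(RefstabError):
    """Structural problem in a matrix file (duplicate ids, missing cells, ...)."""


class MatrixParseError(RefstabError):
    """A cell could not be parsed as a number; message carries coordinates."""


class InsufficientDataError(RefstabError):
    """Too few assays or samples for the requested statistic."""


class ValidationError(RefstabError):
    """Inconsistent inputs (assay-set mismatch, bad parameters, ...)."""


class FixtureIntegrityError(RefstabError):
    """The packaged fixture does not match its recorded checksum."""


class InstanceSizeError(RefstabError):
    """Instance too large for an exhaustive method."""
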