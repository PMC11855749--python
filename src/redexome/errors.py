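"""Exception hierarchy shared across the package."""


class RedexomeError(Exception):
    """Base class for all package errors."""


class CatalogueFormatError(RedexomeError):
    """A catalogue file is structurally malformed (e.g. missing column)."""


class CatalogueValidationError(RedexomeError):
    """A catalogue row violates an invariant (duplicate gene, bad cutoff)."""


class NoThresholdError(RedexomeError):
    """Raised when a pathogenic cutoff is requested for a locus that has none.

    A few catalogued loci carry no expanded/normal boundary (printed "NA");
    they are loaded and reported but excluded from expansion calling.
    """


class ConfigError(RedexomeError):
    """Invalid simulation or pipeline configuration."""


class EvidenceError(RedexomeError):
    """Read evidence inconsistent with the operation requested on it."""
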