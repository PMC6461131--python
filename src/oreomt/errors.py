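"""Exception hierarchy shared across the package."""


class OreoError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(OreoError, ValueError):
    """A coordinate fell outside [1, genome_length]."""


class DesignError(OreoError, ValueError):
    """An amplicon chain or probe design is invalid or infeasible."""


class AdvisoryError(DesignError):
    """The requested operation is unnecessary (e.g. OREO at a non-overlap site)."""


class ConfigError(OreoError, ValueError):
    """An inconsistent simulation or threshold configuration."""


class ParseError(OreoError, ValueError):
    """A malformed input file (FASTQ/TSV/config)."""


class PileupError(OreoError, ValueError):
    """An alignment file could not be used for pileup counting."""


class UndefinedFractionError(OreoError, ZeroDivisionError):
    """No informative reads: the allele fraction is undefined."""
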