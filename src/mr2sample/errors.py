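"""Exception hierarchy shared across the package."""


class MRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRError):
    """A user-supplied configuration value is invalid or missing."""


class DataError(MRError):
    """Input data violates a structural invariant (duplicates, bad SEs, ...)."""


class SelectionError(MRError):
    """Instrument selection failed (empty result, SNP missing from LD reference)."""


class HarmonizationError(MRError):
    """Exposure and outcome datasets cannot be aligned."""


class EstimationError(MRError):
    """An estimator's preconditions are not met (too few SNPs, zero exposure beta)."""
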