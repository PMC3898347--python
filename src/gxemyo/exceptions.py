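"""Exception hierarchy for the gxemyo package."""


class GxeError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(GxeError, ValueError):
    """A refraction measurement is non-finite or outside sanity bounds."""


class ConfigError(GxeError, ValueError):
    """Invalid configuration value (unknown flag, bad scheme name, ...)."""


class SpecError(GxeError, ValueError):
    """Invalid synthetic-data specification."""


class AlignmentError(GxeError, ValueError):
    """Dosage vector/matrix not aligned with the SNP panel."""


class FormatError(GxeError, ValueError):
    """Malformed input file (missing column, duplicate variant, bad code)."""


class MissingVariantError(FormatError):
    """Panel variants absent from the genotype source."""

    def __init__(self, variant_ids):
        self.variant_ids = list(variant_ids)
        super().__init__(f"panel variants absent from genotypes: {', '.join(self.variant_ids)}")


class AlleleMismatchError(FormatError):
    """Neither VCF allele matches the panel's alleles for a variant."""


class DosageRangeError(FormatError):
    """Dosage outside the closed interval [0, 2]."""


class SingularDesignError(GxeError, ValueError):
    """Exactly rank-deficient design matrix."""


class StratificationError(GxeError, ValueError):
    """A required stratum is empty or degenerate."""


class TrendUndefinedError(GxeError, ValueError):
    """Trend test requested with fewer than two populated exposure levels."""


class CollapseError(GxeError, ValueError):
    """A corner cell needed for the synergy index is inestimable."""


class CalibrationError(GxeError, ValueError):
    """Infeasible odds requested from the OR-grid calibrator."""


class PipelineError(GxeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
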