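"""Exception types shared across the pipeline."""


class PainTransferError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(PainTransferError):
    """Invalid cohort or pipeline configuration (bad counts, empty mask, ...)."""


class DegenerateBaselineError(PainTransferError):
    """Baseline value at stimulus onset is zero, so percent signal change is undefined."""


class DegenerateResponseError(PainTransferError):
    """Response vector is constant; a regression on it is meaningless."""


class RankError(PainTransferError):
    """More latent components requested than the centered data can support."""


class AlignmentError(PainTransferError):
    """Objects that must be joined by individual or pair identity do not match."""


class ConstantInputError(PainTransferError):
    """A correlation was requested on a constant vector; names the offender."""
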