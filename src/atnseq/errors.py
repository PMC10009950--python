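"""Exception hierarchy for the atnseq pipeline."""


class AtnseqError(Exception):
    """Base class for all package errors."""


class SchemaError(AtnseqError):
    """A required column or field is missing from tabular input."""


class ValidationError(AtnseqError):
    """Input violates a structural invariant (duplicates, empty mask, ...)."""


class GridError(AtnseqError):
    """Image grids disagree in shape, voxel size or affine."""


class ConfigError(AtnseqError):
    """Analysis configuration is malformed or unsupported."""


class ClassificationError(AtnseqError):
    """A subject cannot be classified (missing marker value)."""


class FitError(AtnseqError):
    """A model fit failed (rank deficiency, non-finite input, ...)."""


class InsufficientGroupError(FitError):
    """A sequence position has fewer subjects than the configured minimum."""


class DegenerateMixtureError(AtnseqError):
    """Two-component mixture components too close to define a cutoff."""


class NoCandidateError(AtnseqError):
    """No candidate thresholds exist (e.g. a single distinct value)."""
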