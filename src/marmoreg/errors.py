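"""Exception hierarchy shared across marmoreg modules."""


class MarmoregError(Exception):
    """Base class for all marmoreg errors."""


class InputError(MarmoregError, ValueError):
    """Invalid user input (mismatched labels, bad thresholds, empty lists...)."""


class DegenerateGeometryError(MarmoregError, ValueError):
    """Point configuration too degenerate for the requested fit."""


class MatchingError(MarmoregError):
    """No acceptable marker correspondence could be found."""


class AmbiguousMatchError(MatchingError):
    """Several correspondences fit equally well (symmetric constellation)."""

    def __init__(self, message, tied_pairings=None):
        super().__init__(message)
        self.tied_pairings = tied_pairings or []


class SegmentationError(MarmoregError):
    """A required segmentation (e.g. bone mask) came out empty."""


class CoverageError(MarmoregError):
    """Too many samples fall outside the target field of view."""


class FormatError(MarmoregError, ValueError):
    """Malformed file on disk (missing affine, bad matrix shape...)."""


class PhantomSpecError(MarmoregError, ValueError):
    """Inconsistent synthetic-phantom specification."""


class RegistrationStageError(MarmoregError):
    """Failure inside a multi-stage registration pipeline, tagged with the stage."""

    def __init__(self, stage, cause):
        super().__init__(f"registration failed at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause
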