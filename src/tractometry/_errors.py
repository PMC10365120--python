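"""Named exception types raised at module boundaries.

Every fatal condition the pipeline can hit has a dedicated class so callers
(and the CLI exit-code mapping) can distinguish configuration problems from
data problems without string matching.
"""


class TractometryError(Exception):
    """Base class for all package errors."""


class ConfigError(TractometryError):
    """Invalid configuration or missing input path, detected before compute."""


class DataError(TractometryError):
    """Input data violates a contract (shape, frame count, singular affine...)."""


class FrameCountMismatchError(DataError):
    """DWI frame count disagrees with the gradient table length."""


class SingularAffineError(DataError):
    """A voxel->world affine is not invertible."""


class TrkParseError(DataError):
    """A TrackVis .trk file has a corrupt or unreadable header."""


class ProfileSchemaError(DataError):
    """A profile CSV is missing required columns."""


class EmptySeedError(DataError):
    """No voxel satisfies the seeding criterion; tracking cannot start."""


class RankDeficientDesignError(DataError):
    """The gradient scheme does not span the 7 tensor design-matrix columns."""


class EmptyBundleError(DataError):
    """An operation requiring streamlines received an empty bundle."""
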