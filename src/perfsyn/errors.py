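"""Exception types shared across the pipeline stages."""


class InvalidParameterError(ValueError):
    """A physical or model parameter is outside its valid domain."""


class ShapeError(ValueError):
    """Array arguments do not have compatible shapes."""


class SingularInputError(ValueError):
    """An input (e.g. an all-zero AIF) makes the operation ill-posed."""


class BoundsError(ValueError):
    """A requested region falls outside the simulation grid."""


class DegenerateNormalizationError(ValueError):
    """Normalization statistics are degenerate (constant data)."""


class IncompatibleCheckpointError(ValueError):
    """Checkpoint architecture configuration does not match the model."""


class EmptyResultError(ValueError):
    """An operation produced no valid voxels/samples."""
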