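"""Exception hierarchy for renalseg."""


class RenalsegError(Exception):
    """Base class for all renalseg errors."""


class FormatError(RenalsegError):
    """A file could not be read as the expected image format."""


class LabelDomainError(RenalsegError):
    """A stored label value falls outside the {0, 1} = {OT, KT} domain."""


class GridCompatibilityError(RenalsegError):
    """Two voxel grids with mismatched dims/spacing were mixed."""


class ConstantVolumeError(RenalsegError):
    """An operation requiring intensity variance received a constant volume."""


class CohortSizeError(RenalsegError):
    """Too few scans/subjects for the requested selection or fold layout."""


class EstimationError(RenalsegError):
    """A statistical model could not be estimated from the provided data."""


class PhantomSpecError(RenalsegError):
    """A phantom specification is geometrically or numerically invalid."""
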