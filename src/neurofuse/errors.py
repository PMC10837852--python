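"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateDesignError(InvalidArgumentError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = tuple(columns) if columns is not None else ()


class InvalidReferenceError(InvalidArgumentError):
    """A PET reference region has a non-positive mean signal."""


class MissingRoiError(InvalidArgumentError):
    """One or more atlas ROIs contain no usable voxels."""

    def __init__(self, roi_ids):
        self.roi_ids = tuple(roi_ids)
        super().__init__(f"ROIs with no usable voxels: {sorted(self.roi_ids)}")


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")
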