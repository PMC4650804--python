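"""Tomogram container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Tomogram:
    """A 3D attenuation volume with isotropic voxel size.

    Axis convention: ``values[slice, row, col]`` with the vessel axis along
    ``axial_axis`` (default 0, i.e. one trans-axial slice per leading index).
    Grey values are arbitrary attenuation units; integer inputs are promoted
    to float without rescaling.
    """

    values: np.ndarray
    voxel_size_um: float = 1.0
    axial_axis: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={arr.ndim}")
        if arr.shape[self.axial_axis] < 1:
            raise ValueError("volume must contain at least one slice")
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")
        self.values = arr

    @property
    def n_slices(self) -> int:
        return self.values.shape[self.axial_axis]

    def slices(self) -> np.ndarray:
        """Return the volume with the axial axis first."""
        return np.moveaxis(self.values, self.axial_axis, 0)

    def with_values(self, values: np.ndarray) -> "Tomogram":
        return Tomogram(values, self.voxel_size_um, self.axial_axis)
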