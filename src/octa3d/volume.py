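"""Lightweight volume container with axis and voxel-size metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical axis order: axial (depth), fast scan, slow scan
AXES = "ZXY"


@dataclass
class Volume3D:
    """A real-valued 3D intensity volume.

    Parameters
    ----------
    data:
        Array of shape (Z, X, Y): axial depth first, then fast and slow
        lateral axes.
    voxel_size_um:
        Physical voxel edge lengths in micrometres, ordered like the axes.
    axes:
        Axis label string; only "ZXY" is produced by this package, the
        field exists so files written elsewhere can be validated on read.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (5.0, 10.0, 10.0)
    axes: str = AXES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if len(self.axes) != 3:
            raise ValueError(f"invalid axes string {self.axes!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.data
        return self.data.astype(dtype)


def as_array(volume) -> np.ndarray:
    """Accept a Volume3D or a plain array and return the ndarray view."""
    if isinstance(volume, Volume3D):
        return volume.data
    return np.asarray(volume)
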