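"""Labeled 3D volumes: the segmentation input every other module consumes.

A labeled volume is an integer voxel grid in which each cell carries a
unique positive label and 0 marks background.  Axes are ordered (z, y, x)
to match multi-page TIFF stacks (page index = z).  Physical coordinates
are always reported as (x, y, z) in micrometres, with the centre of voxel
(iz, iy, ix) at (ix * vx, iy * vy, iz * vz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["LabeledVolume"]


@dataclass
class LabeledVolume:
    """A 3D cell segmentation with physical voxel size.

    Parameters
    ----------
    labels
        Integer array of shape (nz, ny, nx); 0 (or ``background_label``)
        is background, every other value identifies one cell.
    voxel_size
        Physical edge lengths of one voxel in micrometres, ordered
        (z, y, x) to match the array axes.  All components must be > 0.
    background_label
        The label value treated as background.  Default 0.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_label: int = 0
    _cell_labels: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InputError(
                f"labeled volume must be 3-dimensional, got {self.labels.ndim} axes"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InputError(
                f"labels must be an integer array, got dtype {self.labels.dtype}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InputError(
                f"voxel_size must be 3 positive lengths (z, y, x), got {self.voxel_size}"
            )
        if self.labels.size and self.labels.min() < 0:
            raise InputError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    @property
    def voxel_size_xyz(self) -> tuple[float, float, float]:
        """Voxel size reordered to (x, y, z), matching reported coordinates."""
        vz, vy, vx = self.voxel_size
        return (vx, vy, vz)

    def cell_labels(self) -> np.ndarray:
        """Sorted array of the non-background labels present in the volume."""
        if self._cell_labels is None:
            present = np.unique(self.labels)
            self._cell_labels = present[present != self.background_label]
        return self._cell_labels

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels().size)

    def foreground_mask(self) -> np.ndarray:
        return self.labels != self.background_label
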