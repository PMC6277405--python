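"""Voxelized 3D volumes with world-coordinate metadata.

Axis convention: data is indexed ``[ix, iy, iz]`` with x the first axis
(x fastest in the on-disk raw layout); the world position of voxel center
``(i, j, k)`` is ``origin + (i, j, k) * voxel_size`` in millimetres.
The axial (cranio-caudal) direction is the z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEMANTICS = ("activity_Bq", "density", "label", "fraction")


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic voxel size and world origin."""

    data: np.ndarray
    voxel_size: float  # mm, isotropic
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    semantics: str = "activity_Bq"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VoxelVolume requires a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.semantics not in SEMANTICS:
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.semantics == "activity_Bq" and np.any(self.data < 0):
            raise ValueError("activity must be non-negative")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (cm^3)."""
        return (self.voxel_size / 10.0) ** 3

    def world_coords(self, indices):
        """World position (mm) of fractional voxel indices, shape (..., 3)."""
        return self.origin + np.asarray(indices, dtype=float) * self.voxel_size

    def index_coords(self, world_mm):
        """Fractional voxel indices of world positions (mm)."""
        return (np.asarray(world_mm, dtype=float) - self.origin) / self.voxel_size

    def center_world(self):
        return self.world_coords((np.array(self.shape) - 1) / 2.0)

    def like(self, data, semantics=None) -> "VoxelVolume":
        """New volume on the same grid with different data."""
        return VoxelVolume(data, self.voxel_size, self.origin.copy(),
                           semantics or self.semantics)

    def total_activity(self) -> float:
        if self.semantics != "activity_Bq":
            raise ValueError("total_activity only defined for activity volumes")
        return float(self.data.sum())


def centered_grid(shape, voxel_size) -> VoxelVolume:
    """Empty float32 volume whose world origin centers the grid at 0."""
    shape = tuple(int(s) for s in shape)
    origin = -(np.array(shape) - 1) / 2.0 * voxel_size
    return VoxelVolume(np.zeros(shape, dtype=np.float32), voxel_size, origin)


def check_same_grid(a: VoxelVolume, b: VoxelVolume, what="volumes"):
    if a.shape != b.shape or a.voxel_size != b.voxel_size \
            or not np.allclose(a.origin, b.origin):
        raise ValueError(f"{what} are not on the same grid: "
                         f"{a.shape}@{a.voxel_size} vs {b.shape}@{b.voxel_size}")
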