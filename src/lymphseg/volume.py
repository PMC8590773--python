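"""3D volume containers used throughout the pipeline.

All grids are indexed ``(z, y, x)`` — slice axis first, matching the
convention in which an anisotropic pelvic DWI stack is a pile of thick
axial slices (slice thickness 6-8 mm, in-plane ~1.5 mm).  Geometry is
carried by per-axis voxel spacing in millimetres; the scanner origin is
retained for provenance only and never enters any measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = ["Volume3D", "BinaryMask3D", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid differ in shape or spacing."""


def _as_triple(v) -> Tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t


@dataclass
class Volume3D:
    """A 3D scalar image.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar grid, finite values.
    spacing : (sz, sy, sx)
        Voxel size in mm along each axis; all positive.
    origin : (oz, oy, ox)
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all shape components must be >= 1")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume3D") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=1e-6
        )

    def require_same_grid(self, other: "Volume3D") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Copy of this volume carrying new data on the same grid."""
        return replace(self, data=data)


@dataclass
class BinaryMask3D(Volume3D):
    """A {0, 1} label mask on the same kind of grid as :class:`Volume3D`."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != np.uint8:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"mask values must be a subset of {{0, 1}}, got {vals[:10]}"
                )
            self.data = self.data.astype(np.uint8)
        super().__post_init__()

    @classmethod
    def from_volume(cls, vol: Volume3D) -> "BinaryMask3D":
        """Cast a volume holding {0,1} values to a mask (validates values)."""
        return cls(data=vol.data, spacing=vol.spacing, origin=vol.origin)

    def foreground_count(self) -> int:
        return int(self.data.sum())

    def foreground_points_mm(self) -> np.ndarray:
        """Physical (z, y, x) mm coordinates of foreground voxel centers."""
        idx = np.argwhere(self.data > 0)
        return idx * np.asarray(self.spacing)
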