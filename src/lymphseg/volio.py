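"""NIfTI reading/writing, grid resampling and intensity normalization.

NIfTI files store (x, y, z) arrays; on read we reorient to canonical
(RAS) voxel order and transpose to this package's (z, y, x) convention,
taking voxel spacing from the header zooms.  Only spacing enters any
downstream geometry; the affine translation is kept as ``origin`` for
provenance.
"""

from __future__ import annotations

import os
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from skimage.transform import resize

from .volume import BinaryMask3D, Volume3D

__all__ = ["read_volume", "read_mask", "write_volume", "resample_to_shape",
           "zscore_normalize"]


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI file into a (z, y, x)-ordered :class:`Volume3D`.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file is not a readable NIfTI image.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
    except (nib.filebasedimages.ImageFileError, OSError) as exc:
        raise ValueError(f"not a readable NIfTI file: {path}") from exc
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    origin_xyz = img.affine[:3, 3]
    return Volume3D(
        data=np.ascontiguousarray(data.T.astype(np.float32)),  # -> (z, y, x)
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=(float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0])),
    )


def read_mask(path: str | os.PathLike) -> BinaryMask3D:
    """Read a NIfTI {0,1} mask; values are validated."""
    vol = read_volume(path)
    return BinaryMask3D(data=np.rint(vol.data), spacing=vol.spacing,
                        origin=vol.origin)


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume (or mask) to NIfTI; round-trips with :func:`read_volume`.

    Masks are written as uint8, images as float32.  The affine encodes the
    voxel spacing (RAS-aligned axes) and origin.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        raise IsADirectoryError(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    data_xyz = np.ascontiguousarray(vol.data.T)  # (z,y,x) -> (x,y,z)
    if isinstance(vol, BinaryMask3D):
        data_xyz = data_xyz.astype(np.uint8)
    else:
        data_xyz = data_xyz.astype(np.float32)
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag((sx, sy, sz, 1.0))
    affine[:3, 3] = (ox, oy, oz)
    nib.save(nib.Nifti1Image(data_xyz, affine), path)


def resample_to_shape(
    vol: Volume3D,
    target_shape: Sequence[int],
    mode: Literal["continuous", "nearest"] = "continuous",
) -> Volume3D:
    """Resample onto a new grid shape, preserving the physical extent.

    The network expects a fixed grid (64 x 256 x 256 at full scale); spacing
    is rescaled by old/new shape ratio per axis so that
    ``shape[i] * spacing[i]`` is unchanged.  ``continuous`` uses trilinear
    interpolation (images); ``nearest`` preserves the input value set (masks).
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ValueError(f"target shape must be 3 positive ints, got {target_shape}")
    if mode not in ("continuous", "nearest"):
        raise ValueError(f"unknown mode: {mode!r}")
    if target_shape == vol.shape:
        return vol.with_data(vol.data.copy())
    order = 1 if mode == "continuous" else 0
    out = resize(
        vol.data.astype(np.float32),
        target_shape,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    new_spacing = tuple(
        s * old / new for s, old, new in zip(vol.spacing, vol.shape, target_shape)
    )
    if isinstance(vol, BinaryMask3D):
        return BinaryMask3D(data=np.rint(out), spacing=new_spacing,
                            origin=vol.origin)
    return Volume3D(data=out.astype(np.float32), spacing=new_spacing,
                    origin=vol.origin)


def zscore_normalize(vol: Volume3D) -> Volume3D:
    """Per-volume z-score: zero mean, unit standard deviation.

    A constant volume maps to all zeros.  Applied to every image before it
    enters the network, making training invariant to scanner gain/offset.
    """
    if vol.data.size < 2:
        raise ValueError("z-score normalization needs at least 2 voxels")
    data = vol.data.astype(np.float64)
    mu = data.mean()
    sd = data.std()
    if sd == 0:
        return Volume3D(np.zeros_like(data, dtype=np.float32), vol.spacing,
                        vol.origin)
    return Volume3D(((data - mu) / sd).astype(np.float32), vol.spacing,
                    vol.origin)
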