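"""Synthetic DWI-like phantoms with ground-truth lymph-node masks.

On high-b-value DWI, lymph nodes appear as compact bright blobs on a dark
background, while vessels, ureters and bowel segments form bright tubular
structures that mimic nodes in any single 2D slice.  The phantom emulates
exactly that: random-orientation ellipsoidal "nodes" (the ground truth),
capsule-swept polyline "tubes" at similar intensity (hard distractors that
are *not* in the truth mask), mild partial-volume smoothing and additive
Gaussian noise.

The default grid is 32 x 96 x 96 voxels at (3, 1.5, 1.5) mm — the same
anisotropy as an axial pelvic DWI stack, scaled to desk size; the full
64 x 256 x 256 network grid is supported.  A voxel belongs to a shape iff
its center is inside, which bounds diameter-recovery error at one voxel
spacing.

:func:`degrade_mask` produces imperfect segmentations from a perfect one
(boundary flips emulate contour error, whole-component drops emulate missed
small nodes) so the evaluation stack can be exercised without a trained
network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volume import BinaryMask3D, Volume3D

__all__ = ["PhantomSpec", "LesionTruth", "generate_phantom", "degrade_mask",
           "PlacementError"]


class PlacementError(RuntimeError):
    """Shape placement failed after the retry budget (phantom too crowded)."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    ``diameters_cm`` optionally fixes each node's short diameter explicitly
    (overriding ``n_nodes``/``diameter_range_cm``), which is how staging
    scenarios with a known count of suspicious nodes are constructed.
    """

    shape: Tuple[int, int, int] = (32, 96, 96)
    spacing: Tuple[float, float, float] = (3.0, 1.5, 1.5)
    n_nodes: int = 4
    diameter_range_cm: Tuple[float, float] = (0.4, 1.6)
    n_tubes: int = 2
    noise_sd: float = 0.1
    seed: int = 0
    diameters_cm: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.n_nodes < 0 or self.n_tubes < 0:
            raise ValueError("n_nodes and n_tubes must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.diameters_cm is None:
            lo, hi = self.diameter_range_cm
            extent_cm = min(
                s * n for s, n in zip(self.spacing, self.shape)
            ) / 10.0
            if not (0 < lo <= hi < extent_cm):
                raise ValueError(
                    f"diameter range {self.diameter_range_cm} cm must lie "
                    f"within (0, {extent_cm:.1f}) cm"
                )

    def node_diameters_cm(self, rng: np.random.Generator) -> np.ndarray:
        if self.diameters_cm is not None:
            return np.asarray(self.diameters_cm, dtype=float)
        lo, hi = self.diameter_range_cm
        return rng.uniform(lo, hi, size=self.n_nodes)


@dataclass
class LesionTruth:
    """Ground truth for one generated node."""

    center: Tuple[float, float, float]       # physical mm (z, y, x)
    axes_lengths: Tuple[float, float, float]  # ellipsoid semi-axes, mm
    short_diameter_cm: float                  # 2 * smallest semi-axis / 10
    label_id: int

    def to_dict(self) -> dict:
        return {
            "center_mm": list(self.center),
            "semi_axes_mm": list(self.axes_lengths),
            "short_diameter_cm": self.short_diameter_cm,
            "label_id": self.label_id,
        }


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _grid_mm(shape, spacing) -> List[np.ndarray]:
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _rasterize_ellipsoid(shape, spacing, center, semi_axes, rot) -> np.ndarray:
    """Boolean grid of voxels whose centers fall inside the ellipsoid."""
    zz, yy, xx = _grid_mm(shape, spacing)
    # bounding window to avoid full-grid work
    r = float(np.max(semi_axes))
    sl = tuple(
        slice(
            int(np.searchsorted(ax, c - r - 1e-9)),
            int(np.searchsorted(ax, c + r + 1e-9)),
        )
        for ax, c in zip((zz, yy, xx), center)
    )
    Z, Y, X = np.meshgrid(zz[sl[0]], yy[sl[1]], xx[sl[2]], indexing="ij")
    d = np.stack([Z - center[0], Y - center[1], X - center[2]], axis=-1)
    local = d @ rot  # coordinates in ellipsoid frame
    inside = np.sum((local / np.asarray(semi_axes)) ** 2, axis=-1) <= 1.0
    out = np.zeros(shape, dtype=bool)
    out[sl] = inside
    return out


def _rasterize_capsule_path(shape, spacing, points, radius) -> np.ndarray:
    """Voxels within *radius* mm of a polyline (a swept capsule)."""
    zz, yy, xx = _grid_mm(shape, spacing)
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    P = np.stack([Z, Y, X], axis=-1)
    inside = np.zeros(shape, dtype=bool)
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        t = np.clip(((P - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        inside |= np.sum((P - closest) ** 2, axis=-1) <= radius**2
    return inside


def generate_phantom(
    spec: PhantomSpec,
) -> Tuple[Volume3D, BinaryMask3D, List[LesionTruth]]:
    """Generate one (image, truth mask, truth list) triple.

    Nodes are placed by rejection sampling with mutual clearance (no two
    shapes touch, so the mask has exactly ``n_nodes`` 26-connected
    components) and a margin from the volume border.  Identical spec+seed
    gives bitwise-identical outputs.

    Raises
    ------
    PlacementError
        If a node or tube cannot be placed after the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    extent = np.array([s * (n - 1) for n, s in zip(shape, spacing)])
    clearance = 2.0 * max(spacing)  # keeps components separate after raster

    mask = np.zeros(shape, dtype=bool)
    image = np.zeros(shape, dtype=np.float32)
    truths: List[LesionTruth] = []
    placed: List[Tuple[np.ndarray, float]] = []  # (center, outer radius)

    diameters = spec.node_diameters_cm(rng)
    for i, d_cm in enumerate(diameters):
        short_semi = d_cm * 10.0 / 2.0  # mm
        # other two semi-axes moderately longer: nodes are oval, not needles
        semi = np.sort(short_semi * np.r_[1.0, rng.uniform(1.0, 1.6, size=2)])
        rot = _random_rotation(rng)
        r_out = float(semi.max())
        for _ in range(200):
            margin = r_out + clearance
            if np.any(extent - 2 * margin <= 0):
                raise PlacementError(
                    f"node of diameter {d_cm} cm does not fit the volume"
                )
            center = rng.uniform(margin, extent - margin)
            if all(
                np.linalg.norm(center - c) > r + r_out + clearance
                for c, r in placed
            ):
                break
        else:
            raise PlacementError(f"could not place node {i} after 200 tries")
        vox = _rasterize_ellipsoid(shape, spacing, center, semi, rot)
        mask |= vox
        image[vox] = rng.uniform(0.9, 1.1)
        placed.append((center, r_out))
        truths.append(
            LesionTruth(
                center=tuple(center),
                axes_lengths=tuple(semi),
                short_diameter_cm=float(2 * semi[0] / 10.0),
                label_id=i + 1,
            )
        )

    for _ in range(spec.n_tubes):
        radius = rng.uniform(1.5, 3.0)  # mm — below the suspicious cutoff
        for _ in range(200):
            start = rng.uniform(0.1 * extent, 0.9 * extent)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            n_seg = 4
            pts = [start]
            for _ in range(n_seg):
                step = direction * rng.uniform(8.0, 15.0)
                direction = direction + rng.normal(scale=0.3, size=3)
                direction /= np.linalg.norm(direction)
                pts.append(np.clip(pts[-1] + step, 0, extent))
            pts = np.array(pts)
            # keep tubes clear of nodes so truth components stay intact
            ok = all(
                np.min(np.linalg.norm(pts - c, axis=1)) > r + radius + clearance
                for c, r in placed
            )
            if ok:
                break
        else:
            raise PlacementError("could not place tube after 200 tries")
        vox = _rasterize_capsule_path(shape, spacing, pts, radius)
        vox &= ~ndimage.binary_dilation(mask, iterations=1)
        image[vox] = rng.uniform(0.75, 0.95)

    # mild partial-volume blur, then noise relative to node intensity (~1)
    image = ndimage.gaussian_filter(image, sigma=0.6)
    if spec.noise_sd > 0:
        image = image + rng.normal(scale=spec.noise_sd, size=shape)

    vol = Volume3D(image.astype(np.float32), spacing)
    truth_mask = BinaryMask3D(mask.astype(np.uint8), spacing)
    return vol, truth_mask, truths


def degrade_mask(
    mask: BinaryMask3D,
    boundary_flip_rate: float,
    drop_rate: float,
    seed: int,
) -> BinaryMask3D:
    """Emulate an imperfect segmentation of *mask*.

    Boundary voxels (foreground surface and the background shell adjacent to
    it) are flipped independently with ``boundary_flip_rate`` — contour
    error; whole 26-connected components are removed with probability
    ``drop_rate`` — missed nodes (false negatives typically occur with small
    lesions).  Rates (0, 0) return an identical mask; ``drop_rate=1``
    empties it.
    """
    for name, r in (("boundary_flip_rate", boundary_flip_rate),
                    ("drop_rate", drop_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    data = mask.data.astype(bool)

    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(data, structure=structure)
    if drop_rate > 0 and n > 0:
        drop = rng.random(n) < drop_rate
        for k in np.nonzero(drop)[0]:
            data[labels == k + 1] = False

    if boundary_flip_rate > 0:
        inner = data & ~ndimage.binary_erosion(data, structure=structure)
        outer = ~data & ndimage.binary_dilation(data, structure=structure)
        boundary = inner | outer
        flips = boundary & (rng.random(mask.shape) < boundary_flip_rate)
        data = data ^ flips

    return BinaryMask3D(data.astype(np.uint8), mask.spacing, mask.origin)


def truths_to_json(truths: List[LesionTruth]) -> str:
    return json.dumps([t.to_dict() for t in truths], indent=2)
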