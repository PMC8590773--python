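"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation's code paths: distances by
double loops, the oriented-box minimum by an exhaustive rotation grid.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def directed_hausdorff_bruteforce(A: np.ndarray, B: np.ndarray) -> float:
    worst = 0.0
    for a in A:
        best = min(float(np.linalg.norm(a - b)) for b in B)
        worst = max(worst, best)
    return worst


def hausdorff_bruteforce(A, B) -> float:
    return max(directed_hausdorff_bruteforce(A, B),
               directed_hausdorff_bruteforce(B, A))


def directed_average_bruteforce(A: np.ndarray, B: np.ndarray) -> float:
    return float(
        np.mean([min(float(np.linalg.norm(a - b)) for b in B) for a in A])
    )


def average_bruteforce(A, B) -> float:
    return max(directed_average_bruteforce(A, B),
               directed_average_bruteforce(B, A))


def obb_min_volume_grid(points: np.ndarray, spacing,
                        step_deg: float = 1.0) -> float:
    """Exhaustive rotation-grid minimum of the padded OBB volume.

    Scans box z-axis directions over the hemisphere (polar 0-90, azimuth
    0-360) and in-plane angles over 0-90 degrees, all at *step_deg*; box
    symmetry makes this a cover of distinct orientations.  Uses the convex
    hull vertices (same bounding box as the full set).
    """
    pts = np.asarray(points, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    try:
        pts = pts[ConvexHull(pts).vertices]
    except (QhullError, ValueError):
        pass

    thetas = np.deg2rad(np.arange(0.0, 90.0 + 1e-9, step_deg))
    phis = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    psis = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    cos_psi, sin_psi = np.cos(psis), np.sin(psis)

    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    w = np.stack(
        [np.cos(tt), np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp)],
        axis=-1,
    ).reshape(-1, 3)                       # (M, 3) box z-axis directions
    # in-plane frame (u, v) per direction
    ref = np.where(np.abs(w[:, [0]]) > 0.9, [0.0, 1.0, 0.0], [1.0, 0.0, 0.0])
    u = np.cross(w, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(w, u)

    best = np.inf
    chunk = 4000
    for lo in range(0, len(w), chunk):
        wu, uu, vv = w[lo:lo + chunk], u[lo:lo + chunk], v[lo:lo + chunk]
        a = pts @ uu.T                    # (n, m)
        b = pts @ vv.T
        cw = pts @ wu.T
        ext3 = cw.max(axis=0) - cw.min(axis=0)
        pad3 = np.abs(wu) @ spacing
        for cp, sp in zip(cos_psi, sin_psi):
            c1 = a * cp + b * sp
            c2 = -a * sp + b * cp
            e1 = c1.max(axis=0) - c1.min(axis=0)
            e2 = c2.max(axis=0) - c2.min(axis=0)
            ax1 = uu * cp + vv * sp
            ax2 = -uu * sp + vv * cp
            p1 = np.abs(ax1) @ spacing
            p2 = np.abs(ax2) @ spacing
            vol = (e1 + p1) * (e2 + p2) * (ext3 + pad3)
            m = float(vol.min())
            if m < best:
                best = m
    return best


def rasterize_random_blob(rng: np.random.Generator, spacing,
                          max_voxels: int = 200) -> np.ndarray:
    """Physical-mm voxel centers of a random small ellipsoid component."""
    spacing = np.asarray(spacing, dtype=float)
    for _ in range(100):
        semi = rng.uniform(1.5, 5.0, size=3)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        grid = np.array([17, 17, 17])
        center = (grid - 1) / 2.0 * spacing
        idx = np.indices(grid).reshape(3, -1).T * spacing
        local = (idx - center) @ q
        inside = np.sum((local / semi) ** 2, axis=1) <= 1.0
        pts = idx[inside]
        if 1 <= len(pts) <= max_voxels:
            return pts
    raise RuntimeError("could not draw a small blob")
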