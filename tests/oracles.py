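"""Independent brute-force oracles used to verify the analytic kernels.

Everything here is deliberately naive: dense discretization for the
geometry primitives and a direct normal-equations solve for OLS. These
implementations share no code with the package's analytic paths.
"""

from __future__ import annotations

import numpy as np


def dense_point_distance(p, line: np.ndarray, n: int = 10_000) -> float:
    """Min distance to ~n evenly spaced points along the polyline.

    Samples include every vertex, so corner-nearest cases are exact and
    the interior error is second order in the spacing.
    """
    verts = np.asarray(line, float)
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    best = np.inf
    for a, d, L in zip(verts[:-1], seg, seg_len):
        k = max(2, int(np.ceil(n * L / total)) + 1)
        t = np.linspace(0.0, 1.0, k)
        pts = a + t[:, None] * d
        best = min(best, float(np.min(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]))))
    return best


def dense_length_in_disc(line: np.ndarray, center, radius: float,
                         step: float = 0.05) -> float:
    """Sum of sub-segment lengths whose midpoints fall inside the disc."""
    verts = np.asarray(line, float)
    total = 0.0
    c = np.asarray(center, float)
    for a, b in zip(verts[:-1], verts[1:]):
        seg_len = float(np.hypot(*(b - a)))
        n = max(1, int(np.ceil(seg_len / step)))
        t = (np.arange(n) + 0.5) / n
        mid = a + t[:, None] * (b - a)
        inside = np.hypot(mid[:, 0] - c[0], mid[:, 1] - c[1]) <= radius
        total += inside.sum() * seg_len / n
    return total


def dense_sector_lengths(lines, center, radius: float, sector_count: int,
                         step: float = 0.05) -> np.ndarray:
    """Discretized per-sector clipped lengths (midpoint azimuth binning)."""
    if isinstance(lines, np.ndarray) and lines.ndim == 2:
        lines = [lines]
    c = np.asarray(center, float)
    width = 360.0 / sector_count
    out = np.zeros(sector_count)
    for line in lines:
        verts = np.asarray(line, float)
        for a, b in zip(verts[:-1], verts[1:]):
            seg_len = float(np.hypot(*(b - a)))
            n = max(1, int(np.ceil(seg_len / step)))
            t = (np.arange(n) + 0.5) / n
            mid = a + t[:, None] * (b - a)
            rel = mid - c
            inside = np.hypot(rel[:, 0], rel[:, 1]) <= radius
            az = np.degrees(np.arctan2(rel[inside, 0], rel[inside, 1])) % 360.0
            sec = (np.floor((az + width / 2.0) / width).astype(int)) % sector_count
            np.add.at(out, sec, seg_len / n)
    return out


def dense_kernel_density(center, radius: float, segments, kernel: str = "quartic",
                         step: float = 0.02) -> float:
    """Brute-force kernel line density; segments = (vertices, adt) pairs."""
    c = np.asarray(center, float)
    total = 0.0
    for verts, adt in segments:
        verts = np.asarray(verts, float)
        for a, b in zip(verts[:-1], verts[1:]):
            seg_len = float(np.hypot(*(b - a)))
            n = max(1, int(np.ceil(seg_len / step)))
            t = (np.arange(n) + 0.5) / n
            mid = a + t[:, None] * (b - a)
            d = np.hypot(mid[:, 0] - c[0], mid[:, 1] - c[1])
            if kernel == "quartic":
                k = np.where(d < radius,
                             3.0 / (np.pi * radius**2) * (1 - (d / radius) ** 2) ** 2,
                             0.0)
            else:
                k = np.where(d < radius, 1.0 / (np.pi * radius**2), 0.0)
            total += float(np.sum(adt * (seg_len / n) * k))
    return total


def normal_equations_ols(X: np.ndarray, y: np.ndarray):
    """Direct solve of X'X beta = X'y with classical inference."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / tss
    return beta, se, r2


def random_polyline(rng: np.random.Generator, n_max: int = 5,
                    scale: float = 500.0) -> np.ndarray:
    n = int(rng.integers(2, n_max + 1))
    while True:
        pts = rng.uniform(-scale, scale, size=(n, 2))
        if not np.any(np.all(pts[1:] == pts[:-1], axis=1)):
            return pts
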