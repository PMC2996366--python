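"""Exact planar geometry kernels for GIS covariate construction.

Everything works in planar meter coordinates (x = easting, y = northing).
Azimuths follow the compass convention: degrees clockwise from north, so
north = 0, east = 90. Disc clipping of polylines is analytic
(circle-segment intersection); discretized brute force is used only as an
independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class RoadSegment:
    """One classed polyline of the road network.

    vertices: (n, 2) array of planar coordinates, n >= 2, consecutive
    vertices distinct. road_class 1 = limited-access highway, 2 = other
    highway/connector, 3 = arterial/collector, 4 = minor road. adt is
    average daily traffic (vehicles/day) and may be None for minor roads.
    """

    vertices: np.ndarray
    road_class: int
    adt: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n>=2, 2) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        if np.any(np.all(v[1:] == v[:-1], axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", v)
        if self.road_class not in (1, 2, 3, 4):
            raise ValueError("road_class must be in {1,2,3,4}")
        if self.adt is not None and self.adt < 0:
            raise ValueError("adt must be non-negative")

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))


@dataclass
class RoadNetwork:
    segments: list[RoadSegment]

    def by_class(self, road_class: int) -> "RoadNetwork":
        return RoadNetwork([s for s in self.segments if s.road_class == road_class])

    @property
    def classes_present(self) -> set[int]:
        return {s.road_class for s in self.segments}

    def total_length(self) -> float:
        return sum(s.length for s in self.segments)


@dataclass
class AirportLayout:
    """Marker geometries used as airport proxies.

    terminal and centroid are (2,) points; runways maps a name such as
    "5/23" to an (n, 2) polyline; fence is an (n, 2) polyline (the
    perimeter, closed by repeating the first vertex).
    """

    terminal: np.ndarray
    runways: dict[str, np.ndarray]
    centroid: np.ndarray
    fence: np.ndarray

    def __post_init__(self) -> None:
        self.terminal = np.asarray(self.terminal, dtype=float).reshape(2)
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(2)
        self.runways = {k: np.asarray(v, dtype=float) for k, v in self.runways.items()}
        self.fence = np.asarray(self.fence, dtype=float)
        if len(self.runways) != len(set(self.runways)):
            raise ValueError("runway names must be unique")


def _as_polyline(line) -> np.ndarray:
    v = np.asarray(line, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
        raise ValueError("polyline must be an (n>=2, 2) array")
    return v


def point_to_polyline_distance(p, line) -> float:
    """Euclidean distance from a point to the nearest point on a polyline."""
    return float(points_to_polyline_distance(np.asarray(p, float).reshape(1, 2), line)[0])


def points_to_polyline_distance(points: np.ndarray, line) -> np.ndarray:
    """Vectorized point-to-polyline distance for an (m, 2) array of points."""
    v = _as_polyline(line)
    a, b = v[:-1], v[1:]
    d = b - a                                # (n, 2)
    seg_len2 = np.einsum("ij,ij->i", d, d)   # (n,)
    if np.all(seg_len2 == 0):
        raise ValueError("degenerate polyline: all vertices identical")
    keep = seg_len2 > 0
    a, d, seg_len2 = a[keep], d[keep], seg_len2[keep]
    pts = np.asarray(points, dtype=float)
    ap = pts[:, None, :] - a[None, :, :]     # (m, n, 2)
    t = np.clip(np.einsum("mnj,nj->mn", ap, d) / seg_len2, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * d[None, :, :]
    dist = np.linalg.norm(pts[:, None, :] - foot, axis=2)
    return dist.min(axis=1)


def _chord_params(a: np.ndarray, b: np.ndarray, center: np.ndarray, radius: float):
    """Clamp the circle-segment intersection to parameter range [0, 1].

    Returns (t_lo, t_hi, seg_len) arrays; rows with t_hi <= t_lo have no
    chord inside the disc.
    """
    d = b - a
    f = a - center
    aa = np.einsum("ij,ij->i", d, d)
    bb = 2.0 * np.einsum("ij,ij->i", f, d)
    cc = np.einsum("ij,ij->i", f, f) - radius * radius
    disc = bb * bb - 4.0 * aa * cc
    seg_len = np.sqrt(aa)
    t_lo = np.zeros(len(aa))
    t_hi = np.zeros(len(aa))
    ok = (disc > 0) & (aa > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = (-bb - sq) / (2.0 * aa)
        r2 = (-bb + sq) / (2.0 * aa)
    t_lo[ok] = np.clip(r1[ok], 0.0, 1.0)
    t_hi[ok] = np.clip(r2[ok], 0.0, 1.0)
    return t_lo, t_hi, seg_len


def _polyline_edges(lines) -> tuple[np.ndarray, np.ndarray]:
    """Stack the constituent edges of one polyline or a list of polylines."""
    if isinstance(lines, np.ndarray) and lines.ndim == 2:
        lines = [lines]
    starts, ends = [], []
    for line in lines:
        v = _as_polyline(line)
        starts.append(v[:-1])
        ends.append(v[1:])
    return np.vstack(starts), np.vstack(ends)


def length_in_disc(line, center, radius: float) -> float:
    """Arc length of a polyline's intersection with the closed disc."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    a, b = _polyline_edges(line)
    c = np.asarray(center, dtype=float).reshape(2)
    t_lo, t_hi, seg_len = _chord_params(a, b, c, radius)
    return float(np.sum(np.maximum(t_hi - t_lo, 0.0) * seg_len))


def lengths_in_discs(centers: np.ndarray, lines, radius: float) -> np.ndarray:
    """length_in_disc for many centers at once; centers is (m, 2)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    a, b = _polyline_edges(lines)
    cs = np.asarray(centers, dtype=float)
    d = b - a
    aa = np.einsum("ij,ij->i", d, d)            # (n,)
    seg_len = np.sqrt(aa)
    f = a[None, :, :] - cs[:, None, :]          # (m, n, 2)
    bb = 2.0 * np.einsum("mnj,nj->mn", f, d)
    cc = np.einsum("mnj,mnj->mn", f, f) - radius * radius
    disc = bb * bb - 4.0 * aa[None, :] * cc
    ok = (disc > 0) & (aa[None, :] > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.clip((-bb - sq) / (2.0 * aa[None, :]), 0.0, 1.0)
        r2 = np.clip((-bb + sq) / (2.0 * aa[None, :]), 0.0, 1.0)
    chord = np.where(ok, np.maximum(r2 - r1, 0.0), 0.0) * seg_len[None, :]
    return chord.sum(axis=1)


def azimuth_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Compass azimuth (deg clockwise from north) of displacement (dx, dy)."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


def sector_of(az: np.ndarray, sector_count: int) -> np.ndarray:
    """Sector index of a compass azimuth.

    Sector 0 is centered on north; a point exactly on a boundary azimuth
    belongs to the clockwise sector.
    """
    width = 360.0 / sector_count
    return (np.floor((np.asarray(az) + width / 2.0) / width).astype(int)) % sector_count


def sector_lengths(lines, center, radius: float, sector_count: int = 8) -> np.ndarray:
    """Per-sector clipped road length within the disc.

    Sectors are equal wedges centered on the standard compass directions
    (for sector_count=8: N, NE, E, SE, S, SW, W, NW). The wedges partition
    the disc, so the result sums to ``length_in_disc`` of the same lines.
    """
    if 360 % sector_count != 0:
        raise ValueError("sector_count must divide 360")
    c = np.asarray(center, dtype=float).reshape(2)
    a, b = _polyline_edges(lines)
    t_lo, t_hi, seg_len = _chord_params(a, b, c, radius)
    out = np.zeros(sector_count)
    width = 360.0 / sector_count
    boundary_az = (np.arange(sector_count) * width - width / 2.0) % 360.0
    # unit direction of each boundary ray from the center
    rad = np.radians(boundary_az)
    rays = np.stack([np.sin(rad), np.cos(rad)], axis=1)   # compass -> (dx, dy)
    d = b - a
    for i in np.nonzero(t_hi > t_lo)[0]:
        lo, hi = t_lo[i], t_hi[i]
        ai, di = a[i], d[i]
        # parameter values where the segment crosses a boundary ray
        cuts = [lo, hi]
        for u in rays:
            denom = u[0] * di[1] - u[1] * di[0]
            if denom == 0.0:
                continue
            rel = ai - c
            t = (u[1] * rel[0] - u[0] * rel[1]) / denom
            if lo < t < hi:
                p = ai + t * di - c
                # on the ray, not its opposite; dot == 0 is the center
                # itself, where a through-segment must also be split
                if p @ u >= 0.0:
                    cuts.append(t)
        cuts = np.unique(cuts)
        mids = (cuts[:-1] + cuts[1:]) / 2.0
        pts = ai + mids[:, None] * di - c
        sec = sector_of(azimuth_deg(pts[:, 0], pts[:, 1]), sector_count)
        np.add.at(out, sec, (cuts[1:] - cuts[:-1]) * seg_len[i])
    return out


def quartic_kernel(d: np.ndarray, radius: float) -> np.ndarray:
    """Quartic (biweight) density kernel, integrating to 1 over the disc."""
    u2 = np.clip(1.0 - (d / radius) ** 2, 0.0, None)
    return (3.0 / (np.pi * radius**2)) * u2**2


def uniform_kernel(d: np.ndarray, radius: float) -> np.ndarray:
    return np.where(d < radius, 1.0 / (np.pi * radius**2), 0.0)


_KERNELS = {"quartic": quartic_kernel, "uniform": uniform_kernel}


@dataclass
class NetworkDiscretization:
    """Road network discretized into weighted points for density sums.

    Each segment edge is sampled at mid-steps of ``step`` meters; every
    sample carries its arc-length share, its segment ADT and road class.
    A KD-tree makes radius queries cheap for many evaluation centers.
    """

    points: np.ndarray          # (k, 2)
    step_lengths: np.ndarray    # (k,) arc length represented by the point
    adt: np.ndarray             # (k,) nan where the segment has no ADT
    road_class: np.ndarray      # (k,)
    segment_index: np.ndarray   # (k,) which RoadSegment the point came from
    tree: cKDTree = field(repr=False, default=None)

    @classmethod
    def build(cls, network: RoadNetwork, step: float) -> "NetworkDiscretization":
        if step <= 0:
            raise ValueError("step must be positive")
        pts, lens, adts, classes, segidx = [], [], [], [], []
        for si, seg in enumerate(network.segments):
            v = seg.vertices
            for a, b in zip(v[:-1], v[1:]):
                d = b - a
                L = float(np.hypot(*d))
                n = max(1, int(np.ceil(L / step)))
                t = (np.arange(n) + 0.5) / n
                pts.append(a + t[:, None] * d)
                lens.append(np.full(n, L / n))
                adts.append(np.full(n, np.nan if seg.adt is None else seg.adt))
                classes.append(np.full(n, seg.road_class, dtype=int))
                segidx.append(np.full(n, si, dtype=int))
        points = np.vstack(pts)
        return cls(
            points=points,
            step_lengths=np.concatenate(lens),
            adt=np.concatenate(adts),
            road_class=np.concatenate(classes),
            segment_index=np.concatenate(segidx),
            tree=cKDTree(points),
        )


def kernel_line_density(
    center,
    radius: float,
    network: RoadNetwork | NetworkDiscretization,
    weight: str = "adt",
    kernel: str = "quartic",
    step: float = 1.0,
) -> float:
    """Kernel-weighted line density around a point.

    Sums ``weight x step_length x K(d)`` over discretized road points
    within the search radius, where K is the quartic or uniform kernel.
    With ADT weights the units are vehicle.m/day per m^2; with unit
    weights, m per m^2.
    """
    return float(
        kernel_line_densities(np.asarray(center, float).reshape(1, 2),
                              radius, network, weight, kernel, step)[0]
    )


def kernel_line_densities(
    centers: np.ndarray,
    radius: float,
    network: RoadNetwork | NetworkDiscretization,
    weight: str = "adt",
    kernel: str = "quartic",
    step: float = 1.0,
) -> np.ndarray:
    """Vectorized kernel line density for an (m, 2) array of centers."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if weight not in ("adt", "unit"):
        raise ValueError("weight must be 'adt' or 'unit'")
    kfun = _KERNELS[kernel]
    disc = network if isinstance(network, NetworkDiscretization) else NetworkDiscretization.build(network, step)
    cs = np.asarray(centers, dtype=float)
    out = np.zeros(len(cs))
    hits = disc.tree.query_ball_point(cs, radius)
    for i, idx in enumerate(hits):
        if not idx:
            continue
        idx = np.asarray(idx)
        if weight == "adt":
            w = disc.adt[idx]
            if np.any(np.isnan(w)):
                bad = disc.segment_index[idx[np.isnan(w)]][0]
                raise ValueError(f"segment {bad} has no ADT but ADT weighting was requested")
        else:
            w = 1.0
        d = np.linalg.norm(disc.points[idx] - cs[i], axis=1)
        out[i] = np.sum(w * disc.step_lengths[idx] * kfun(d, radius))
    return out
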