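"""Per-record GIS covariate assembly.

For every sampling record the full covariate vector is built from the
geometry kernels: distances to the nearest road of each class, distances
to the five airport markers, per-class and total road length within each
buffer radius, ADT-weighted road length at 100 and 200 m, kernel traffic
density at every radius, and wind-rose-weighted per-class road length at
the wind buffer radius.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import (
    NetworkDiscretization,
    kernel_line_densities,
    lengths_in_discs,
    points_to_polyline_distance,
    sector_lengths,
)
from .io import COMPASS, CampaignBundle, WindRose

ROAD_CLASSES = (1, 2, 3, 4)
ADT_LEN_RADII = (100.0, 200.0)


def covariate_columns(config: RunConfig) -> list[str]:
    """Names of all covariate columns, in canonical order."""
    cols = [f"dist_class{c}" for c in ROAD_CLASSES]
    cols += [f"traffic_density_{int(r)}" for r in config.buffer_radii_m]
    cols += ["dist_terminal", "dist_runway_16_34", "dist_runway_5_23",
             "dist_centroid", "dist_fence"]
    for c in ROAD_CLASSES:
        cols += [f"len_class{c}_{int(r)}" for r in config.buffer_radii_m]
    cols += [f"len_all_{int(r)}" for r in config.buffer_radii_m]
    cols += [f"adt_len_{int(r)}" for r in ADT_LEN_RADII]
    cols += [f"windlen_class{c}" for c in ROAD_CLASSES]
    return cols


def wind_weighted_length(sector_lens: np.ndarray, rose: WindRose) -> float:
    """Road length weighted by the fraction of time wind blows from each sector.

    The weight on a sector is the upwind fraction: road mass sitting in
    the direction the wind comes from is what gets transported across the
    sampler.
    """
    lens = np.asarray(sector_lens, dtype=float)
    if lens.shape != rose.fractions.shape:
        raise ValueError(
            f"sector count mismatch: {lens.shape[0]} lengths vs {rose.fractions.shape[0]} fractions"
        )
    return float(np.dot(rose.fractions, lens))


def _runway_key(name: str) -> str:
    return "dist_runway_" + name.replace("/", "_")


def build_covariates(bundle: CampaignBundle, config: RunConfig) -> pd.DataFrame:
    """Assemble the covariate table for every analysis record.

    Returns a DataFrame with one row per non-blank record. A road class
    absent from the network yields an undefined (NaN) distance column;
    those columns are listed in ``df.attrs["undefined_columns"]`` and are
    skipped by the screening stage.
    """
    records = bundle.analysis_records()
    if not records:
        raise ValueError("bundle has no analysis records")
    pts = np.array([[r.x, r.y] for r in records])
    df = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "session": [r.session for r in records],
        "fence_flag": [r.fence_flag for r in records],
    })
    gc = grid_covariates(pts, bundle, config,
                         sessions=[r.session for r in records])
    df = df.join(gc)
    df["no2_ppb"] = [r.no2_ppb for r in records]
    df.attrs["undefined_columns"] = gc.attrs["undefined_columns"]
    return df


def grid_covariates(
    pts: np.ndarray,
    bundle: CampaignBundle,
    config: RunConfig,
    sessions: list[str] | None = None,
) -> pd.DataFrame:
    """Covariate vectors at arbitrary points.

    ``sessions`` gives the session label per point (needed for the
    wind-weighted lengths); a single label may be broadcast by passing a
    list of length 1.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    if sessions is None:
        sessions = [bundle.sessions[0]]
    if len(sessions) == 1 and n > 1:
        sessions = sessions * n
    if len(sessions) != n:
        raise ValueError("sessions must match points")

    net = bundle.network
    airport = bundle.airport
    out: dict[str, np.ndarray] = {}
    undefined: list[str] = []

    class_lines: dict[int, list[np.ndarray]] = {
        c: [s.vertices for s in net.by_class(c).segments] for c in ROAD_CLASSES
    }

    # distances to nearest road of each class
    for c in ROAD_CLASSES:
        col = f"dist_class{c}"
        lines = class_lines[c]
        if not lines:
            out[col] = np.full(n, np.nan)
            undefined.append(col)
            continue
        d = np.full(n, np.inf)
        for line in lines:
            d = np.minimum(d, points_to_polyline_distance(pts, line))
        out[col] = d

    # distances to airport markers
    out["dist_terminal"] = np.linalg.norm(pts - airport.terminal, axis=1)
    out["dist_centroid"] = np.linalg.norm(pts - airport.centroid, axis=1)
    out["dist_fence"] = points_to_polyline_distance(pts, airport.fence)
    for name, line in airport.runways.items():
        out[_runway_key(name)] = points_to_polyline_distance(pts, line)

    # buffer road lengths per class and total
    for r in config.buffer_radii_m:
        total = np.zeros(n)
        for c in ROAD_CLASSES:
            col = f"len_class{c}_{int(r)}"
            lines = class_lines[c]
            vals = lengths_in_discs(pts, lines, r) if lines else np.zeros(n)
            out[col] = vals
            total = total + vals
        out[f"len_all_{int(r)}"] = total

    # kernel traffic density (scaled) and ADT-weighted length
    disc = NetworkDiscretization.build(net, config.discretization_step_m)
    for r in config.buffer_radii_m:
        raw = kernel_line_densities(pts, r, disc, weight="adt",
                                    kernel=config.density_kernel)
        out[f"traffic_density_{int(r)}"] = raw * config.density_scale
    for r in ADT_LEN_RADII:
        out[f"adt_len_{int(r)}"] = _adt_weighted_lengths(pts, net, r)

    # wind-weighted per-class road length at the wind buffer
    roses = {rose.session: rose for rose in bundle.roses}
    for c in ROAD_CLASSES:
        col = f"windlen_class{c}"
        lines = class_lines[c]
        vals = np.zeros(n)
        if lines:
            for i in range(n):
                sl = sector_lengths(lines, pts[i], config.wind_buffer_m,
                                    config.sector_count)
                vals[i] = wind_weighted_length(sl, roses[sessions[i]])
        out[col] = vals

    df = pd.DataFrame(out)
    df.attrs["undefined_columns"] = undefined
    return df


def _adt_weighted_lengths(pts: np.ndarray, net, radius: float) -> np.ndarray:
    """Sum over segments of ADT x clipped length within the buffer."""
    vals = np.zeros(len(pts))
    for seg in net.segments:
        if seg.adt is None:
            continue
        vals += seg.adt * lengths_in_discs(pts, seg.vertices, radius)
    return vals


def check_table(df: pd.DataFrame, config: RunConfig, atol: float = 1e-6) -> None:
    """Assert the internal consistency invariants of a covariate table."""
    for r in config.buffer_radii_m:
        total = sum(df[f"len_class{c}_{int(r)}"] for c in ROAD_CLASSES)
        if not np.allclose(total, df[f"len_all_{int(r)}"], atol=atol):
            raise AssertionError(f"len_all_{int(r)} != sum of class lengths")
    length_cols = [c for c in df.columns if c.startswith(("len_", "adt_len", "windlen", "traffic_density"))]
    if (df[length_cols] < -atol).any().any():
        raise AssertionError("negative length or density")
    dist_cols = [c for c in df.columns if c.startswith("dist_")]
    if (df[dist_cols].fillna(0) < 0).any().any():
        raise AssertionError("negative distance")
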