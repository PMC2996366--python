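"""Synthetic sampling campaigns with known ground truth.

The generator emulates a saturation NO2 study around a small commercial
airport: a ~5 x 5 km planar domain with one limited-access highway, a
couple of high-volume connectors, several arterials, a dense minor-road
grid, and an airport block (terminal, two crossing runways, centroid,
rectangular fence). Sampler locations saturate the fence line and spread
over the surrounding neighborhoods across three seasonal sessions, with
random field losses, duplicate pairs, and laboratory/field blanks.

Concentrations follow a linear model in the GIS covariates (the same
term vocabulary the regression modules use) plus homoscedastic Gaussian
noise, so every fitted quantity can be checked against the generating
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .covariates import build_covariates
from .geometry import AirportLayout, RoadNetwork, RoadSegment
from .io import CampaignBundle, SamplingRecord, WindRose

SESSIONS = ("S1", "S2", "S3")
#: share of deployed samplers per session (fall deployment was thinner)
SESSION_WEIGHTS = {"S1": 0.26, "S2": 0.385, "S3": 0.355}
#: field loss rate (lost or damaged samplers)
DEFAULT_LOSS_RATE = 51.0 / 695.0

DEFAULT_ROSES = {
    # W-dominant flow; SW tilt in fall, NW tilt in spring/summer
    "S1": [0.05, 0.03, 0.04, 0.06, 0.08, 0.22, 0.34, 0.18],
    "S2": [0.07, 0.04, 0.03, 0.04, 0.06, 0.14, 0.34, 0.28],
    "S3": [0.06, 0.05, 0.04, 0.05, 0.07, 0.15, 0.33, 0.25],
}


@dataclass
class TrueModel:
    """Generative linear model for NO2 (ppb).

    Coefficients are keyed by covariate column name; the session effect
    of the reference session (last label) is fixed at zero. ``noise_sd``
    may be None, meaning "calibrate against a covariate table" via
    :func:`calibrate_noise_sd`.
    """

    intercept: float = 12.64
    session_effects: dict[str, float] = field(
        default_factory=lambda: {"S1": 2.18, "S2": 1.89, "S3": 0.0}
    )
    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "dist_terminal": -0.00140,
            "traffic_density_100": 0.00830,
            "len_class1_100": 0.0230,
            "len_class2_200": 0.00381,
            "dist_class3": -0.00286,
        }
    )
    noise_sd: float | None = 3.2

    def linear_predictor(self, cov: pd.DataFrame) -> np.ndarray:
        missing = [t for t in self.coefficients if t not in cov.columns]
        if missing:
            raise KeyError(f"covariate table lacks truth terms: {missing}")
        mu = np.full(len(cov), self.intercept)
        mu += cov["session"].map(self.session_effects).to_numpy(float)
        for term, beta in self.coefficients.items():
            mu += beta * cov[term].to_numpy(float)
        return mu


def default_true_model(**overrides) -> TrueModel:
    return TrueModel(**overrides)


def default_wind_roses() -> list[WindRose]:
    return [WindRose(s, np.array(DEFAULT_ROSES[s])) for s in SESSIONS]


# ------------------------------------------------------------- study area

def _grid_lines(lo, hi, step, axis, rng, exclude_box=None):
    """Axis-parallel polylines every ``step`` m, split around a box."""
    segs = []
    for v in np.arange(lo + step, hi, step):
        v = float(v + rng.normal(0.0, 4.0))
        if axis == "x":     # vertical street at x = v
            line = [(v, lo), (v, hi)]
        else:
            line = [(lo, v), (hi, v)]
        segs.extend(_split_around_box(np.array(line, float), exclude_box))
    return segs


def _split_around_box(line: np.ndarray, box) -> list[np.ndarray]:
    if box is None:
        return [line]
    (x0, y0), (x1, y1) = box
    (ax, ay), (bx, by) = line
    out = []
    if ax == bx:  # vertical
        if x0 <= ax <= x1:
            if ay < y0:
                out.append(np.array([[ax, ay], [ax, y0]]))
            if by > y1:
                out.append(np.array([[ax, y1], [ax, by]]))
            return out
        return [line]
    if ay == by:  # horizontal
        if y0 <= ay <= y1:
            if ax < x0:
                out.append(np.array([[ax, ay], [x0, ay]]))
            if bx > x1:
                out.append(np.array([[x1, ay], [bx, ay]]))
            return out
        return [line]
    return [line]


def generate_study_area(config: RunConfig, seed: int) -> tuple[RoadNetwork, AirportLayout]:
    """Build the road network and airport layout of the synthetic domain.

    Deterministic for a fixed seed. The domain is 0..5000 m on both axes.
    Road mix: one class-1 highway (ADT ~150,000) near the east edge, two
    class-2 connectors (ADT ~100,000), several class-3 arterials
    (ADT 20,000-35,000) and a dense class-4 street grid.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 0.0, 5000.0
    fence_box = ((1800.0, 1600.0), (3400.0, 3000.0))

    segments: list[RoadSegment] = []

    # class 1: limited-access highway, roughly N-S near the east edge
    x_hw = 4700.0 + rng.uniform(-60, 60)
    hw = np.array([[x_hw, lo], [x_hw + rng.uniform(-40, 40), 2500.0],
                   [x_hw + rng.uniform(-40, 40), hi]])
    segments.append(RoadSegment(hw, 1, 150_000.0))

    # class 2: airport connector, a north connector, and the terminal
    # access road running just outside the east fence
    segments.append(RoadSegment(
        np.array([[3400.0, 2400.0], [x_hw, 2400.0 + rng.uniform(-80, 80)]]), 2, 100_000.0))
    segments.append(RoadSegment(
        np.array([[2600.0, 3000.0], [2600.0 + rng.uniform(-60, 60), hi]]), 2, 80_000.0))
    segments.append(RoadSegment(
        np.array([[3450.0, 1650.0], [3450.0, 2950.0]]), 2, 60_000.0))

    # class 3: arterials/collectors framing the airport and following the
    # commercial corridors (so arterial proximity co-varies with traffic)
    arterials = [
        [(1600.0, lo), (1600.0, hi)],
        [(lo, 1350.0), (hi, 1350.0)],
        [(lo, 3250.0), (hi, 3250.0)],
        [(4250.0, lo), (4250.0, hi)],
    ]
    for line in arterials:
        v = np.array(line, float) + rng.normal(0.0, 15.0, size=(2, 2))
        segments.append(RoadSegment(v, 3, float(rng.uniform(20_000, 35_000))))

    # class 4: minor-road grid, clipped out of the airport block
    for seg in _grid_lines(lo, hi, 250.0, "x", rng, fence_box):
        segments.append(RoadSegment(seg, 4, float(rng.uniform(300, 1500))))
    for seg in _grid_lines(lo, hi, 250.0, "y", rng, fence_box):
        segments.append(RoadSegment(seg, 4, float(rng.uniform(300, 1500))))

    (fx0, fy0), (fx1, fy1) = fence_box
    fence = np.array([[fx0, fy0], [fx1, fy0], [fx1, fy1], [fx0, fy1], [fx0, fy0]])
    airport = AirportLayout(
        terminal=np.array([3250.0, 2400.0]),
        runways={
            "5/23": np.array([[1950.0, 1700.0], [3250.0, 2850.0]]),
            "16/34": np.array([[2600.0, 2900.0], [2850.0, 1700.0]]),
        },
        centroid=np.array([2600.0, 2300.0]),
        fence=fence,
    )
    return RoadNetwork(segments), airport


# -------------------------------------------------------- sampling design

def _fence_positions(fence: np.ndarray, n: int) -> np.ndarray:
    """n points evenly spaced by arc length along the fence polyline."""
    d = np.diff(fence, axis=0)
    seg_len = np.hypot(d[:, 0], d[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = (np.arange(n) + 0.5) / n * total
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seg_len) - 1)
    t = (s - cum[idx]) / seg_len[idx]
    return fence[idx] + t[:, None] * d[idx]


def _inside_box(p, box) -> bool:
    (x0, y0), (x1, y1) = box
    return x0 <= p[0] <= x1 and y0 <= p[1] <= y1


def _community_pool(area, n: int, rng: np.random.Generator) -> np.ndarray:
    """Community sampler locations: around the airport, some domain-wide,
    and a deliberate share near major (class 1-3) roads."""
    network, airport = area
    fence_box = ((airport.fence[:, 0].min(), airport.fence[:, 1].min()),
                 (airport.fence[:, 0].max(), airport.fence[:, 1].max()))
    by_class = {c: [s for s in network.segments if s.road_class == c]
                for c in (1, 2, 3)}
    pts = []
    while len(pts) < n:
        u = rng.random()
        if u < 0.68:   # ring around the airport
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(500.0, 2600.0)
            p = airport.centroid + r * np.array([np.cos(ang), np.sin(ang)])
        elif u < 0.85:  # anywhere in the domain
            p = rng.uniform(100.0, 4900.0, size=2)
        else:           # near a major roadway (highway oversampled so its
                        # sparse footprint is still estimable)
            cls = (1, 2, 3)[rng.choice(3, p=[0.5, 0.25, 0.25])]
            segs = by_class[cls]
            seg = segs[rng.integers(len(segs))]
            v = seg.vertices
            i = rng.integers(len(v) - 1)
            t = rng.random()
            p = v[i] + t * (v[i + 1] - v[i]) + rng.normal(0.0, 70.0, size=2)
        if not (0.0 <= p[0] <= 5000.0 and 0.0 <= p[1] <= 5000.0):
            continue
        if _inside_box(p, fence_box):
            continue
        pts.append(p)
    return np.array(pts)


def generate_sampling_design(
    area: tuple[RoadNetwork, AirportLayout],
    n_fence: int,
    n_community: int,
    seed: int,
    loss_rate: float = DEFAULT_LOSS_RATE,
    sessions: tuple[str, ...] = SESSIONS,
) -> list[SamplingRecord]:
    """Sampler deployment skeletons (no concentrations yet).

    ``n_fence`` and ``n_community`` are retention targets: the generator
    deploys ``n / (1 - loss_rate)`` samplers and then drops each with
    probability ``loss_rate``, so the expected retained total equals the
    request. Fence samplers are evenly spaced along the fence; community
    samplers are re-jittered per session (similar but not identical
    location sets).
    """
    network, airport = area
    rng = np.random.default_rng(seed)
    n_fence_dep = int(round(n_fence / (1.0 - loss_rate)))
    n_comm_dep = int(round(n_community / (1.0 - loss_rate)))

    weights = np.array([SESSION_WEIGHTS.get(s, 1.0 / len(sessions)) for s in sessions])
    weights = weights / weights.sum()

    comm_counts = np.round(weights * n_comm_dep).astype(int)
    base_pool = _community_pool((network, airport), comm_counts.max(), rng)

    records: list[SamplingRecord] = []
    for si, session in enumerate(sessions):
        nf = int(round(weights[si] * n_fence_dep))
        for j, p in enumerate(_fence_positions(airport.fence, nf)):
            records.append(SamplingRecord(
                record_id=f"{session}-F{j:03d}", x=float(p[0]), y=float(p[1]),
                session=session, fence_flag=1, no2_ppb=float("nan")))
        pts = base_pool[: comm_counts[si]] + rng.normal(0.0, 25.0, size=(comm_counts[si], 2))
        for j, p in enumerate(pts):
            records.append(SamplingRecord(
                record_id=f"{session}-C{j:03d}", x=float(p[0]), y=float(p[1]),
                session=session, fence_flag=0, no2_ppb=float("nan")))

    if loss_rate > 0:
        keep = rng.random(len(records)) >= loss_rate
        records = [r for r, k in zip(records, keep) if k]
    return records


# ------------------------------------------------------------- simulation

def calibrate_noise_sd(cov: pd.DataFrame, truth: TrueModel, target_r2: float = 0.32) -> float:
    """Noise level that makes the population R-squared equal target_r2.

    With homoscedastic noise, R^2 = var(signal) / (var(signal) + sd^2),
    so sd = sqrt(var(signal) * (1 - R2) / R2) in closed form.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must lie in (0, 1)")
    signal = truth.linear_predictor(cov)
    return float(np.sqrt(np.var(signal) * (1.0 - target_r2) / target_r2))


def simulate_no2(cov: pd.DataFrame, truth: TrueModel, seed: int) -> np.ndarray:
    """Draw NO2 concentrations for each covariate row.

    Independent Gaussian noise per record; negative draws are possible
    in the far noise tail and are left in place (QA clamps them later).
    """
    if truth.noise_sd is None or truth.noise_sd <= 0:
        raise ValueError("truth.noise_sd must be positive; calibrate first")
    rng = np.random.default_rng(seed)
    return truth.linear_predictor(cov) + rng.normal(0.0, truth.noise_sd, size=len(cov))


def _qa_extras(
    records: list[SamplingRecord],
    rng: np.random.Generator,
    duplicate_frac: float,
    duplicate_sd: float,
    centroid: np.ndarray,
    sessions: tuple[str, ...],
) -> list[SamplingRecord]:
    """Duplicate pairs (10-12% of samples) and per-session blanks."""
    extras: list[SamplingRecord] = []
    for session in sessions:
        sess = [r for r in records if r.session == session]
        n_dup = int(round(duplicate_frac * len(sess)))
        for r in rng.choice(len(sess), size=min(n_dup, len(sess)), replace=False):
            parent = sess[r]
            extras.append(SamplingRecord(
                record_id=parent.record_id + "-D", x=parent.x, y=parent.y,
                session=session, fence_flag=parent.fence_flag,
                no2_ppb=parent.no2_ppb + float(rng.normal(0.0, duplicate_sd)),
                role=f"duplicate_of:{parent.record_id}"))
        for j in range(10):
            extras.append(SamplingRecord(
                record_id=f"{session}-LB{j:02d}", x=float(centroid[0]), y=float(centroid[1]),
                session=session, fence_flag=0,
                no2_ppb=max(0.0, float(rng.normal(0.01, 0.002))), role="lab_blank"))
        for j in range(22):
            extras.append(SamplingRecord(
                record_id=f"{session}-FB{j:02d}", x=float(centroid[0]), y=float(centroid[1]),
                session=session, fence_flag=0,
                no2_ppb=max(0.0, float(rng.normal(0.09, 0.02))), role="field_blank"))
    return extras


def generate_campaign(
    config: RunConfig,
    seed: int,
    n_fence: int = 253,
    n_community: int = 391,
    truth: TrueModel | None = None,
    target_r2: float = 0.32,
    qa_features: bool = True,
    duplicate_frac: float = 0.11,
    duplicate_sd: float = 3.0,
    loss_rate: float = DEFAULT_LOSS_RATE,
) -> tuple[CampaignBundle, TrueModel, pd.DataFrame]:
    """End-to-end campaign: area, design, covariates, concentrations, QA.

    If ``truth`` is None (or its ``noise_sd`` is None) the default truth
    is used with the noise level calibrated so the generative R-squared
    equals ``target_r2``. Sub-seeds are derived from ``seed`` so losses,
    duplicates and blanks can be regenerated independently.

    Returns the bundle, the truth actually used, and the covariate table
    of the analysis records (concentration column filled in).
    """
    area = generate_study_area(config, seed)
    records = generate_sampling_design(area, n_fence, n_community, seed + 1,
                                       loss_rate=loss_rate)
    roses = default_wind_roses()
    bundle = CampaignBundle(network=area[0], airport=area[1], roses=roses,
                            records=records)
    bundle.validate()

    cov = build_covariates(bundle, config)
    if truth is None:
        truth = default_true_model(noise_sd=None)
    if truth.noise_sd is None:
        truth = TrueModel(
            intercept=truth.intercept,
            session_effects=dict(truth.session_effects),
            coefficients=dict(truth.coefficients),
            noise_sd=calibrate_noise_sd(cov, truth, target_r2),
        )
    y = simulate_no2(cov, truth, seed + 2)
    cov = cov.copy()
    cov["no2_ppb"] = y
    for r, v in zip(records, y):
        r.no2_ppb = float(v)

    if qa_features:
        rng = np.random.default_rng(seed + 3)
        extras = _qa_extras(records, rng, duplicate_frac, duplicate_sd,
                            bundle.airport.centroid, SESSIONS)
        bundle.records = records + extras
    return bundle, truth, cov
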