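"""File formats of the pipeline: GeoJSON layers, wind-rose and record CSVs.

All readers validate on entry so downstream modules only ever see a
consistent :class:`CampaignBundle`; nothing elsewhere re-parses files.
Coordinates must be planar meters — inputs that look like geographic
longitude/latitude are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import AirportLayout, RoadNetwork, RoadSegment

COMPASS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
ROSE_COLUMNS = ["session"] + [f"f_{d}" for d in COMPASS]
RECORD_COLUMNS = ["record_id", "x_m", "y_m", "session", "fence_flag", "no2_ppb", "role"]


class FormatError(ValueError):
    """A file does not conform to the declared schema."""


class ValidationError(ValueError):
    """Schema-conformant input that violates a bundle invariant."""


@dataclass(frozen=True)
class WindRose:
    """Fraction of time wind blows FROM each of 8 compass directions."""

    session: str
    fractions: np.ndarray  # ordered N, NE, E, SE, S, SW, W, NW

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (8,):
            raise ValidationError("wind rose needs exactly 8 fractions")
        if np.any(f < 0):
            raise ValidationError(f"wind rose {self.session}: negative fraction")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"wind rose {self.session}: fractions sum to {f.sum():.6f}, not 1"
            )
        object.__setattr__(self, "fractions", f)


@dataclass
class SamplingRecord:
    """One passive-sampler observation."""

    record_id: str
    x: float
    y: float
    session: str
    fence_flag: int
    no2_ppb: float
    role: str = "sample"  # sample | duplicate_of:<id> | field_blank | lab_blank

    @property
    def is_blank(self) -> bool:
        return self.role in ("field_blank", "lab_blank")

    @property
    def duplicate_parent(self) -> str | None:
        if self.role.startswith("duplicate_of:"):
            return self.role.split(":", 1)[1]
        return None


@dataclass
class CampaignBundle:
    """All layers of one sampling campaign in a shared meter frame."""

    network: RoadNetwork
    airport: AirportLayout
    roses: list[WindRose]
    records: list[SamplingRecord]

    @property
    def sessions(self) -> list[str]:
        """Session labels in rose-file order; the last is the reference."""
        return [r.session for r in self.roses]

    def rose_for(self, session: str) -> WindRose:
        for r in self.roses:
            if r.session == session:
                return r
        raise KeyError(session)

    def analysis_records(self, include_duplicates: bool = False) -> list[SamplingRecord]:
        """Records that enter the regression.

        Blanks are always excluded; duplicate tubes (co-located QA
        measurements, not independent observations) are excluded unless
        requested.
        """
        return [r for r in self.records if not r.is_blank
                and (include_duplicates or r.duplicate_parent is None)]

    def validate(self) -> None:
        sessions = set(self.sessions)
        if len(sessions) != len(self.roses):
            raise ValidationError("duplicate session labels in wind roses")
        for rec in self.records:
            if rec.session not in sessions:
                raise ValidationError(
                    f"record {rec.record_id}: unknown session {rec.session!r}"
                )
        xs = np.array([r.x for r in self.records]) if self.records else np.array([])
        ys = np.array([r.y for r in self.records]) if self.records else np.array([])
        if len(xs) and np.all(np.abs(xs) <= 360.0) and np.all(np.abs(ys) <= 90.0):
            raise ValidationError(
                "record coordinates look like geographic lon/lat; "
                "planar meter coordinates are required"
            )


# ---------------------------------------------------------------- GeoJSON

def read_roads(path: str | Path) -> RoadNetwork:
    data = json.loads(Path(path).read_text())
    segments = []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise FormatError(f"roads feature {i}: geometry must be LineString")
        if "road_class" not in props:
            raise FormatError(f"roads feature {i}: missing property 'road_class'")
        if "adt" not in props:
            raise FormatError(f"roads feature {i}: missing property 'adt'")
        rc = int(props["road_class"])
        adt = props["adt"]
        if adt is None and rc != 4:
            raise FormatError(f"roads feature {i}: adt may be null only for class 4")
        segments.append(
            RoadSegment(np.asarray(geom["coordinates"], float), rc,
                        None if adt is None else float(adt))
        )
    if not segments:
        raise FormatError("road network is empty")
    return RoadNetwork(segments)


def read_airport(path: str | Path) -> AirportLayout:
    data = json.loads(Path(path).read_text())
    terminal = centroid = fence = None
    runways: dict[str, np.ndarray] = {}
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        geom = feat.get("geometry") or {}
        role = props.get("role")
        if role is None:
            raise FormatError(f"airport feature {i}: missing property 'role'")
        coords = np.asarray(geom.get("coordinates"), float)
        if role == "terminal":
            terminal = coords
        elif role == "centroid":
            centroid = coords
        elif role == "fence":
            fence = coords
        elif role == "runway":
            name = props.get("name")
            if not name:
                raise FormatError(f"airport feature {i}: runway missing 'name'")
            runways[name] = coords
        else:
            raise FormatError(f"airport feature {i}: unknown role {role!r}")
    missing = [n for n, v in
               [("terminal", terminal), ("centroid", centroid), ("fence", fence)]
               if v is None]
    if missing or not runways:
        raise FormatError(f"airport layer incomplete: missing {missing or 'runways'}")
    return AirportLayout(terminal=terminal, runways=runways, centroid=centroid, fence=fence)


def _feature(geom_type: str, coords, **props) -> dict:
    return {"type": "Feature", "properties": props,
            "geometry": {"type": geom_type, "coordinates": coords}}


def _round_coords(arr: np.ndarray, ndigits: int = 3):
    return np.round(np.asarray(arr, float), ndigits).tolist()


def write_roads(network: RoadNetwork, path: str | Path) -> None:
    feats = [
        _feature("LineString", _round_coords(s.vertices),
                 road_class=s.road_class, adt=s.adt)
        for s in network.segments
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats},
                   sort_keys=True, separators=(",", ":"))
    )


def write_airport(airport: AirportLayout, path: str | Path) -> None:
    feats = [
        _feature("Point", _round_coords(airport.terminal), role="terminal"),
        _feature("Point", _round_coords(airport.centroid), role="centroid"),
        _feature("LineString", _round_coords(airport.fence), role="fence"),
    ]
    for name in sorted(airport.runways):
        feats.append(_feature("LineString", _round_coords(airport.runways[name]),
                              role="runway", name=name))
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats},
                   sort_keys=True, separators=(",", ":"))
    )


# -------------------------------------------------------------------- CSV

def read_windroses(path: str | Path) -> list[WindRose]:
    df = pd.read_csv(path)
    missing = set(ROSE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"windrose file missing columns {sorted(missing)}")
    roses = []
    for _, row in df.iterrows():
        roses.append(WindRose(str(row["session"]),
                              row[[f"f_{d}" for d in COMPASS]].to_numpy(float)))
    if not roses:
        raise FormatError("windrose file has no rows")
    return roses


def write_windroses(roses: list[WindRose], path: str | Path) -> None:
    rows = [{"session": r.session, **{f"f_{d}": r.fractions[i] for i, d in enumerate(COMPASS)}}
            for r in roses]
    pd.DataFrame(rows, columns=ROSE_COLUMNS).to_csv(path, index=False)


def read_records(path: str | Path) -> list[SamplingRecord]:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"records file missing columns {sorted(missing)}")
    return [
        SamplingRecord(
            record_id=str(row.record_id), x=float(row.x_m), y=float(row.y_m),
            session=str(row.session), fence_flag=int(row.fence_flag),
            no2_ppb=float(row.no2_ppb), role=str(row.role),
        )
        for row in df.itertuples()
    ]


def write_records(records: list[SamplingRecord], path: str | Path) -> None:
    rows = [
        {"record_id": r.record_id, "x_m": r.x, "y_m": r.y, "session": r.session,
         "fence_flag": r.fence_flag, "no2_ppb": r.no2_ppb, "role": r.role}
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV at full float precision (round-trips)."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------------ bundle

def read_bundle(paths: dict[str, str | Path], config: RunConfig | None = None) -> CampaignBundle:
    """Load and validate a full campaign.

    ``paths`` maps "roads", "airport", "windrose", "records" to files.
    """
    bundle = CampaignBundle(
        network=read_roads(paths["roads"]),
        airport=read_airport(paths["airport"]),
        roses=read_windroses(paths["windrose"]),
        records=read_records(paths["records"]),
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: CampaignBundle, directory: str | Path) -> dict[str, Path]:
    """Emit a campaign in the standard file layout; returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "roads": d / "roads.geojson",
        "airport": d / "airport.geojson",
        "windrose": d / "windrose.csv",
        "records": d / "records.csv",
    }
    write_roads(bundle.network, paths["roads"])
    write_airport(bundle.airport, paths["airport"])
    write_windroses(bundle.roses, paths["windrose"])
    write_records(bundle.records, paths["records"])
    return paths
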