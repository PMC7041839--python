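"""Telemetry data model: bearings to positions, nights, site visits.

Coordinates are planar metres in a projected frame; the study area spans a few
kilometres, so no geodesy.  Azimuths are degrees clockwise from north.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import Landscape

__all__ = [
    "Bearing",
    "TriangulationError",
    "triangulate",
    "assign_night",
    "assign_visits",
    "tracking_effort",
    "mean_nights_per_bat",
    "read_fixes",
    "write_visits",
]

logger = logging.getLogger(__name__)

FIX_SOURCES = frozenset({"exact_sighting", "manual_bearing", "triangulated"})


@dataclass(frozen=True)
class Bearing:
    station_id: str
    x: float
    y: float
    azimuth: float  # degrees clockwise from north, [0, 360)
    strength: float = 1.0
    timestamp: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.azimuth < 360.0):
            raise ValueError("azimuth must lie in [0, 360)")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("station coordinates must be finite")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")


class TriangulationError(ValueError):
    pass


def triangulate(
    bearings: list[Bearing],
    window_s: float = 60.0,
    min_angle_deg: float = 5.0,
    rays: bool = False,
) -> tuple[float, float]:
    """Least-squares intersection of simultaneous bearing lines.

    Each bearing defines the line through its station along its azimuth; the
    returned point minimizes the sum of squared perpendicular distances to
    those lines.  Bearings are treated as full lines by default (the 180-degree
    signal ambiguity of a dipole); ``rays=True`` additionally requires the
    solution to lie forward of every station and fails otherwise.

    Raises :class:`TriangulationError` with "insufficient bearings" when fewer
    than two distinct stations contribute, and "degenerate geometry" when all
    bearing lines are within ``min_angle_deg`` of parallel.
    """
    stations = {b.station_id for b in bearings}
    if len(stations) < 2:
        raise TriangulationError("insufficient bearings")
    times = [b.timestamp for b in bearings if b.timestamp is not None]
    if times and (max(times) - min(times)).total_seconds() > window_s:
        raise TriangulationError("bearings not simultaneous")
    # pairwise angle between lines, modulo 180
    az = np.array([b.azimuth for b in bearings])
    diffs = np.abs(az[:, None] - az[None, :]) % 180.0
    diffs = np.minimum(diffs, 180.0 - diffs)
    if diffs.max() < min_angle_deg:
        raise TriangulationError("degenerate geometry")
    # normal n to the bearing direction d = (sin az, cos az); the line is
    # {p : n . (p - s) = 0}; normal equations of the stacked constraints
    A = np.zeros((2, 2))
    b_vec = np.zeros(2)
    for b in bearings:
        a = math.radians(b.azimuth)
        n = np.array([math.cos(a), -math.sin(a)])
        s = np.array([b.x, b.y])
        A += np.outer(n, n)
        b_vec += n * (n @ s)
    p = np.linalg.solve(A, b_vec)
    if rays:
        for b in bearings:
            a = math.radians(b.azimuth)
            d = np.array([math.sin(a), math.cos(a)])
            if d @ (p - np.array([b.x, b.y])) < 0:
                raise TriangulationError("solution behind a station (rays mode)")
    return float(p[0]), float(p[1])


def assign_night(timestamp) -> pd.Timestamp:
    """Night label of a fix: local noon of day d to noon of day d+1 is night d.

    Bats forage from sunset to sunrise, so every fix of one foraging night
    shares a label even across midnight.  Returns the night's calendar date.
    """
    ts = pd.Timestamp(timestamp)
    if ts is pd.NaT:
        raise ValueError("unparseable timestamp")
    return (ts - pd.Timedelta(hours=12)).normalize()


def assign_visits(
    fixes: pd.DataFrame,
    landscape: Landscape,
    min_fixes_per_visit: int = 2,
) -> pd.DataFrame:
    """Turn located fixes into per-night site visits.

    A bat visits a site on a night iff at least ``min_fixes_per_visit`` of its
    fixes that night fall inside the site's circle (default 2, suppressing
    single spurious triangulations).  Night indices are consecutive integers
    from 1 at the first night present in the data.

    Returns a frame with columns ``bat_id, night, site_id``.
    """
    if not landscape.sites:
        raise ValueError("empty landscape")
    if fixes.empty:
        return pd.DataFrame(columns=["bat_id", "night", "site_id"])
    ts = pd.to_datetime(fixes["timestamp"])
    if ts.isna().any():
        raise ValueError("unparseable timestamp in fixes")
    night_date = (ts - pd.Timedelta(hours=12)).dt.normalize()
    night = (night_date - night_date.min()).dt.days + 1
    xy = fixes[["x_m", "y_m"]].to_numpy(dtype=float)
    rows = []
    for site in landscape.sites:
        d2 = (xy[:, 0] - site.x) ** 2 + (xy[:, 1] - site.y) ** 2
        inside = d2 <= site.radius**2
        if not inside.any():
            continue
        sub = pd.DataFrame(
            {"bat_id": fixes["bat_id"].to_numpy()[inside], "night": night.to_numpy()[inside]}
        )
        counts = sub.groupby(["bat_id", "night"]).size()
        hits = counts[counts >= min_fixes_per_visit]
        for (bat, nt), _ in hits.items():
            rows.append((bat, int(nt), site.id))
    visits = pd.DataFrame(rows, columns=["bat_id", "night", "site_id"])
    return visits.sort_values(["bat_id", "night", "site_id"]).reset_index(drop=True)


def tracking_effort(visits: pd.DataFrame, mode: str = "literal") -> pd.DataFrame:
    """Per-night tracking effort: new-site discovery rate.

    For night t, a bat's new sites are those it had not visited on any earlier
    night; ``mean_new_sites`` averages this over the bats with visit records on
    night t.  The probability of visiting a new site is that mean divided by
    the consecutive night number t (``mode="literal"``).  The alternative
    ``mode="cumulative"`` divides the cumulative mean of new sites over nights
    1..t by t instead; the literal form is the default.
    """
    if visits.empty:
        raise ValueError("visits must be non-empty")
    if mode not in {"literal", "cumulative"}:
        raise ValueError("mode must be 'literal' or 'cumulative'")
    seen: dict[str, set[str]] = {}
    new_counts: dict[int, list[int]] = {}
    for night in sorted(visits["night"].unique()):
        sub = visits[visits["night"] == night]
        for bat, grp in sub.groupby("bat_id"):
            prior = seen.setdefault(bat, set())
            fresh = set(grp["site_id"]) - prior
            new_counts.setdefault(int(night), []).append(len(fresh))
            prior.update(fresh)
    nights = sorted(new_counts)
    mean_new = np.array([np.mean(new_counts[t]) for t in nights])
    if mode == "literal":
        prob = mean_new / np.array(nights, dtype=float)
    else:
        prob = np.cumsum(mean_new) / (np.arange(len(nights)) + 1) / np.array(nights, dtype=float)
    return pd.DataFrame(
        {
            "night": nights,
            "n_bats": [len(new_counts[t]) for t in nights],
            "mean_new_sites": mean_new,
            "prob_new_site": prob,
        }
    )


def mean_nights_per_bat(visits: pd.DataFrame) -> float:
    """Mean number of tracked nights per bat (bat-nights / bats)."""
    bat_nights = visits.drop_duplicates(["bat_id", "night"])
    n_bats = bat_nights["bat_id"].nunique()
    if n_bats == 0:
        raise ValueError("no bats in visit table")
    return len(bat_nights) / n_bats


def read_fixes(path: str | Path) -> pd.DataFrame:
    fixes = pd.read_csv(path)
    missing = {"bat_id", "timestamp", "x_m", "y_m"} - set(fixes.columns)
    if missing:
        raise ValueError(f"fixes file missing columns: {sorted(missing)}")
    bad = set(fixes.get("source", pd.Series(dtype=str)).dropna()) - FIX_SOURCES
    if bad:
        raise ValueError(f"unknown fix sources: {sorted(bad)}")
    return fixes


def write_visits(visits: pd.DataFrame, path: str | Path) -> None:
    visits.to_csv(path, index=False)
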