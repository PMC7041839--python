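"""Minimum convex polygon home ranges (MCP 95%) and core areas (CA 50%).

The level-L MCP keeps the floor(L% * n) fixes nearest the arithmetic mean
centre (one peeling pass, ties broken toward earlier records) and takes their
convex hull; areas are reported in hectares.  The 50% polygon under the same
rule is the core area.  Kernel estimators are deliberately out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

__all__ = ["HomeRange", "mcp", "homeranges_table", "seasonal_area_summary"]

logger = logging.getLogger(__name__)

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class HomeRange:
    bat_id: str
    level: float
    #: hull vertices (metres), counter-clockwise; degenerate hulls keep the
    #: raw shapely boundary coordinates
    polygon: tuple[tuple[float, float], ...]
    area_ha: float
    n_fixes: int
    collinear: bool = False


def _peel(points: np.ndarray, level: float) -> np.ndarray:
    """Keep the floor(level% * n) points nearest the mean centre.

    Stable argsort on distance means ties keep the earlier fix, so results are
    reproducible bit-for-bit.
    """
    n = len(points)
    keep = int(math.floor(level / 100.0 * n))
    centre = points.mean(axis=0)
    d = np.linalg.norm(points - centre, axis=1)
    order = np.argsort(d, kind="stable")
    return points[np.sort(order[:keep])]


def mcp(points, level: float = 95.0, bat_id: str = "") -> HomeRange:
    """Minimum convex polygon of one bat's fixes at a percentage level.

    Requires at least 5 distinct retained fixes.  Collinear fixes yield a
    zero-area polygon flagged ``collinear=True`` rather than an error.
    """
    if not (0.0 < level <= 100.0):
        raise ValueError("level must be in (0, 100]")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    kept = _peel(pts, level)
    if len(kept) < 5:
        raise ValueError("too few fixes")
    distinct = np.unique(kept, axis=0)
    hull = MultiPoint([tuple(p) for p in distinct]).convex_hull
    collinear = hull.geom_type != "Polygon"
    if collinear:
        logger.warning("bat %s: collinear fixes, zero-area home range", bat_id or "?")
        coords = tuple(map(tuple, hull.coords))
        area = 0.0
    else:
        coords = tuple(map(tuple, hull.exterior.coords[:-1]))
        area = hull.area
    return HomeRange(
        bat_id=bat_id,
        level=level,
        polygon=coords,
        area_ha=area / M2_PER_HA,
        n_fixes=len(kept),
        collinear=collinear,
    )


def homeranges_table(
    fixes: pd.DataFrame,
    levels: tuple[float, ...] = (95.0, 50.0),
    season: str | None = None,
) -> pd.DataFrame:
    """MCP/CA areas for every bat in a fix table (bats with too few fixes skipped)."""
    rows = []
    for bat, grp in fixes.groupby("bat_id"):
        pts = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        for level in levels:
            try:
                hr = mcp(pts, level=level, bat_id=str(bat))
            except ValueError:
                logger.warning("bat %s: too few fixes for level %s", bat, level)
                continue
            rows.append((bat, season, level, hr.area_ha, hr.n_fixes))
    return pd.DataFrame(rows, columns=["bat_id", "season", "level", "area_ha", "n_fixes"])


def seasonal_area_summary(areas: pd.DataFrame, level: float = 95.0) -> pd.DataFrame:
    """Median and quartiles of home-range area per season at one level.

    Seasons with fewer than 2 bats are excluded with a warning; statistical
    comparison of the per-season vectors is delegated to the inference module
    (Kruskal-Wallis with node permutations).
    """
    sub = areas[areas["level"] == level]
    rows = []
    for season, grp in sub.groupby("season"):
        if grp["bat_id"].nunique() < 2:
            logger.warning("season %s: fewer than 2 bats, excluded from summary", season)
            continue
        v = grp["area_ha"].to_numpy()
        rows.append(
            (season, len(v), float(np.median(v)), float(np.percentile(v, 25)), float(np.percentile(v, 75)))
        )
    return pd.DataFrame(rows, columns=["season", "n_bats", "median_ha", "q25_ha", "q75_ha"])
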