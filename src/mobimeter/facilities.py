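"""Voronoi service areas, park/mall tower tagging, and phone-hour labels.

A tower's service area is its Voronoi cell, clipped to the city's bounding
region. A tower is a "park tower" when at least 5% of its cell area overlaps
the union of park polygons (malls analogously, computed independently). A
phone-hour is labelled home when the raw (unbinned) distance from home is
under 500 m; otherwise park (then mall) when dwell on tagged towers exceeds
40 minutes of the hour, computed from the raw records before aggregation;
otherwise "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import GeometryCollection, MultiPoint, Point, Polygon, box
from shapely.ops import unary_union, voronoi_diagram

LABELS = ["h", "m", "p", "o"]


@dataclass
class LabelRules:
    """Thresholds of the labelling stage (defaults are the study's)."""

    home_radius: float = 500.0        # meters; strict <
    facility_min_seconds: float = 40 * 60.0   # strict >
    overlap_threshold: float = 0.05
    precedence: tuple[str, str] = ("p", "m")  # order checked after home

    def __post_init__(self):
        if self.home_radius <= 0 or self.facility_min_seconds <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in [0, 1]")
        if sorted(self.precedence) != ["m", "p"]:
            raise ValueError("precedence must order 'p' and 'm'")


def voronoi_service_areas(towers: pd.DataFrame, region: Polygon) -> pd.DataFrame:
    """Voronoi cell (clipped to ``region``) and area for each tower.

    Cells tile the region exactly: pairwise interior-disjoint with areas
    summing to the region's. Duplicate tower coordinates are rejected.
    """
    pts = towers[["x", "y"]].to_numpy(dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 towers for a service-area tessellation")
    _, inv, counts = np.unique(pts.round(9), axis=0, return_inverse=True,
                               return_counts=True)
    if np.any(counts > 1):
        dup = towers["tower_id"].to_numpy()[np.isin(inv, np.where(counts > 1)[0])]
        raise ValueError(f"duplicate tower coordinates: {sorted(dup)}")

    cells = voronoi_diagram(MultiPoint(pts), envelope=region.buffer(1.0))
    assert isinstance(cells, GeometryCollection)
    # map cells back to their towers: each raw cell contains its seed point
    tree = shapely.STRtree(list(cells.geoms))
    rows = []
    for tid, (x, y) in zip(towers["tower_id"], pts):
        hits = tree.query(Point(x, y), predicate="intersects")
        cell = None
        for h in hits:
            if cells.geoms[h].covers(Point(x, y)):
                cell = cells.geoms[h]
                break
        if cell is None:   # pragma: no cover - voronoi_diagram guarantees coverage
            raise RuntimeError(f"no Voronoi cell found for tower {tid}")
        clipped = cell.intersection(region)
        rows.append((tid, clipped, clipped.area))
    out = pd.DataFrame(rows, columns=["tower_id", "polygon", "area"])
    if np.any(out["area"].to_numpy() <= 0):
        bad = out.loc[out["area"] <= 0, "tower_id"].tolist()
        raise ValueError(f"towers with zero service area inside region: {bad}")
    total = out["area"].sum()
    if abs(total - region.area) > 1e-6 * region.area:
        raise AssertionError("Voronoi cells do not tile the bounding region")
    return out


def default_region(towers: pd.DataFrame) -> Polygon:
    """Tower bounding box padded by one median nearest-neighbour spacing."""
    from scipy.spatial import cKDTree

    pts = towers[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    pad = float(np.median(dist[:, 1]))
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    return box(x0, y0, x1, y1)


def tag_towers(service_areas: pd.DataFrame, facilities: pd.DataFrame,
               threshold: float = 0.05) -> pd.DataFrame:
    """Overlap fractions and park/mall tags per tower.

    The fraction is area(cell ∩ union of that kind's polygons)/area(cell);
    a tower is tagged when the fraction is at least the threshold. Park and
    mall tags are independent of each other.
    """
    unions = {}
    for kind in ("park", "mall"):
        geoms = facilities.loc[facilities["kind"] == kind, "geometry"].tolist()
        unions[kind] = unary_union(geoms) if geoms else None
    rows = []
    for t in service_areas.itertuples(index=False):
        if t.area <= 0:
            raise ValueError(f"zero-area service cell for tower {t.tower_id}")
        fr = {}
        for kind, u in unions.items():
            fr[kind] = 0.0 if u is None else t.polygon.intersection(u).area / t.area
        rows.append((t.tower_id, fr["park"] >= threshold, fr["mall"] >= threshold,
                     fr["park"], fr["mall"]))
    return pd.DataFrame(rows, columns=[
        "tower_id", "is_park_tower", "is_mall_tower",
        "park_overlap_frac", "mall_overlap_frac"])


def label_placements(placements: pd.DataFrame, dwell: pd.DataFrame,
                     tags: pd.DataFrame,
                     rules: LabelRules | None = None) -> pd.DataFrame:
    """Attach one exhaustive, mutually exclusive label per phone-hour.

    Precedence: home first (raw distance < home_radius), then park, then mall
    (configurable order), else other. The facility criterion sums dwell over
    the union of that kind's tagged towers and requires strictly more than
    the 40-minute threshold. Phone-hours where both facility criteria fire
    are counted in the returned frame's ``attrs["label_conflicts"]``.
    """
    rules = LabelRules() if rules is None else rules
    tg = tags.set_index("tower_id")

    d = dwell.copy()
    d["day"] = d["hour_abs"] // 24
    d["hour"] = d["hour_abs"] % 24 + 1   # hour t covers (t-1, t]
    d["park_s"] = d["seconds"] * tg["is_park_tower"].reindex(
        d["tower_id"]).fillna(False).to_numpy(dtype=float)
    d["mall_s"] = d["seconds"] * tg["is_mall_tower"].reindex(
        d["tower_id"]).fillna(False).to_numpy(dtype=float)
    fac = d.groupby(["phone_id", "day", "hour"])[["park_s", "mall_s"]].sum()

    out = placements.merge(fac, left_on=["phone_id", "day", "hour"],
                           right_index=True, how="left")
    if out[["park_s", "mall_s"]].isna().any().any():
        raise ValueError("missing dwell data for some placements")

    at_home = out["distance"].to_numpy() < rules.home_radius
    crit = {"p": out["park_s"].to_numpy() > rules.facility_min_seconds,
            "m": out["mall_s"].to_numpy() > rules.facility_min_seconds}
    first, second = rules.precedence
    label = np.full(len(out), "o", dtype=object)
    label[crit[second]] = second
    label[crit[first]] = first
    label[at_home] = "h"
    out = out.drop(columns=["park_s", "mall_s"])
    out["label"] = label
    out.attrs["label_conflicts"] = int(np.sum(crit["p"] & crit["m"] & ~at_home))
    return out


def classify(towers: pd.DataFrame, facilities: pd.DataFrame,
             placements: pd.DataFrame, dwell: pd.DataFrame, *,
             rules: LabelRules | None = None,
             regions: dict | None = None) -> dict:
    """Per-city service areas + tags, then labels for every placement."""
    rules = LabelRules() if rules is None else rules
    areas, tags = [], []
    for city, tw in towers.groupby("city"):
        region = (regions or {}).get(city) or default_region(tw)
        sa = voronoi_service_areas(tw, region)
        fac = facilities[facilities["city"] == city]
        tags.append(tag_towers(sa, fac, rules.overlap_threshold))
        sa.insert(1, "city", city)
        areas.append(sa)
    tag_df = pd.concat(tags, ignore_index=True)
    labeled = label_placements(placements, dwell, tag_df, rules)
    return {"service_areas": pd.concat(areas, ignore_index=True),
            "tags": tag_df, "labeled": labeled}
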