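"""File interchange: CSV tables, facility GeoJSON, truth JSON, projections.

The synthetic generator's output schemas double as the interchange standard
for real data: towers.csv (tower_id,city,x,y), records.csv
(phone_id,tower_id,timestamp,event), aqi.csv (city,day,hour,aqi,level),
facilities.geojson (FeatureCollection with property "kind" in {park, mall}).
Coordinates are planar meters; adapters below project lon/lat degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

EARTH_RADIUS_M = 6_371_000.0


def write_facilities(path, facilities: pd.DataFrame) -> None:
    features = []
    for row in facilities.itertuples(index=False):
        features.append({
            "type": "Feature",
            "geometry": mapping(row.geometry),
            "properties": {"facility_id": row.facility_id, "city": row.city,
                           "kind": row.kind},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def read_facilities(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        if props.get("kind") not in ("park", "mall"):
            raise ValueError(f"facility feature with kind={props.get('kind')!r}")
        rows.append((props.get("facility_id"), props.get("city"),
                     props["kind"], shape(feat["geometry"])))
    return pd.DataFrame(rows, columns=["facility_id", "city", "kind", "geometry"])


def equirectangular(lon, lat, *, lon0: float, lat0: float):
    """Project lon/lat degrees to planar meters around a reference point.

    Adequate at city scale where the projection error is far below the
    tower-spacing measurement error.
    """
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    x = np.radians(lon - lon0) * np.cos(np.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def haversine(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters between lon/lat degree points."""
    lon1, lat1, lon2, lat2 = map(lambda a: np.radians(np.asarray(a, float)),
                                 (lon1, lat1, lon2, lat2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))
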