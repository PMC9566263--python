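"""Minimal GeoJSON feature-collection I/O on top of shapely.

Features are held as a pandas DataFrame with a ``geometry`` column of shapely
objects; all other columns are feature properties. Coordinates are planar
projected metres throughout the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape


def frame_to_geojson(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with a ``geometry`` column as a GeoJSON FeatureCollection."""
    if "geometry" not in df.columns:
        raise ValueError("DataFrame must have a 'geometry' column")
    features = []
    prop_cols = [c for c in df.columns if c != "geometry"]
    for _, row in df.iterrows():
        props = {}
        for c in prop_cols:
            v = row[c]
            if hasattr(v, "item"):  # numpy scalar -> native
                v = v.item()
            props[c] = v
        features.append(
            {"type": "Feature", "geometry": mapping(row["geometry"]), "properties": props}
        )
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc))


def geojson_to_frame(path: str | Path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a DataFrame with a ``geometry`` column."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a FeatureCollection")
    rows = []
    for feat in fc["features"]:
        row = dict(feat.get("properties") or {})
        row["geometry"] = shape(feat["geometry"])
        rows.append(row)
    return pd.DataFrame(rows)
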