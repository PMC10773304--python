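"""Reading and writing the pipeline's tabular artifacts.

Fix tables are plain CSV with ISO-8601 UTC timestamps (columns
individual_id, sex, timestamp, lon, lat, optionally pair_id); nests carry
identities, coordinates and clutch metadata.  Simulation configs round-trip
through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import SimConfig


def read_fixes_csv(path) -> pd.DataFrame:
    fixes = pd.read_csv(path)
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True).dt.tz_localize(None)
    required = {"individual_id", "sex", "timestamp", "lon", "lat"}
    missing = required - set(fixes.columns)
    if missing:
        raise ValueError(f"fix table missing columns: {sorted(missing)}")
    return fixes.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_nests_csv(path) -> pd.DataFrame:
    nests = pd.read_csv(path)
    if "clutch_init_date" in nests.columns:
        nests["clutch_init_date"] = pd.to_datetime(nests["clutch_init_date"]).dt.date
    return nests


def write_nests_csv(nests: pd.DataFrame, path) -> None:
    nests.to_csv(path, index=False)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    # YAML maps keyed by day arrive with string keys
    for key in ("together_prob_by_day", "separation_rate_by_day",
                "female_mover_prob_by_day"):
        if key in raw:
            raw[key] = {int(k): float(v) for k, v in raw[key].items()}
    if "nest_attendance_by_day_sex" in raw:
        raw["nest_attendance_by_day_sex"] = {
            sex: {int(k): float(v) for k, v in m.items()}
            for sex, m in raw["nest_attendance_by_day_sex"].items()}
    return SimConfig(**raw)


def dump_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def tracks_to_geojson(fixes: pd.DataFrame, path) -> None:
    """One LineString feature per individual, ordered by time."""
    features = []
    for ind, grp in fixes.sort_values("timestamp").groupby("individual_id"):
        features.append({
            "type": "Feature",
            "properties": {"individual_id": str(ind),
                           "sex": str(grp["sex"].iloc[0])},
            "geometry": {"type": "LineString",
                         "coordinates": [[round(x, 6), round(y, 6)]
                                         for x, y in zip(grp["lon"], grp["lat"])]},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
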