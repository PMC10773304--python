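"""Plausibility filtering of raw GPS fix streams.

Three rules, applied in a fixed order to each individual's time-sorted track:

1. *far*: drop fixes further than ``max_dist_from_capture`` (default 500 km,
   great-circle) from the capture site;
2. *speed*: forward sequential scan dropping any fix whose arrival leg from
   the previously retained fix implies a ground speed above ``max_speed``
   (default 105 km/h);
3. *single outlier*: drop interior fixes further than ``outlier_jump``
   (default 2.5 km) from both temporal neighbours when those neighbours are
   within ``outlier_neighbor_window`` (default 100 m) of each other.

All thresholds are strict inequalities.  Duplicate timestamps within one
individual are a data error, not something to average away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import LocalProjection, haversine_m

FIX_COLUMNS = ["individual_id", "sex", "timestamp", "lon", "lat"]


class DataError(ValueError):
    """Raised for malformed input fix tables (e.g. duplicate timestamps)."""


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the three plausibility rules (strict '>' comparisons)."""

    max_dist_from_capture: float = 500_000.0   # m
    max_speed: float = 105.0                   # km/h
    outlier_jump: float = 2_500.0              # m
    outlier_neighbor_window: float = 100.0     # m

    def __post_init__(self):
        for name in ("max_dist_from_capture", "max_speed",
                     "outlier_jump", "outlier_neighbor_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class FilterReport:
    """Per-rule removal audit for one filtering run."""

    n_input: int = 0
    removed_far: int = 0
    removed_speed: int = 0
    removed_single_outlier: int = 0

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.removed_far - self.removed_speed
                - self.removed_single_outlier)

    def __add__(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.n_input + other.n_input,
            self.removed_far + other.removed_far,
            self.removed_speed + other.removed_speed,
            self.removed_single_outlier + other.removed_single_outlier,
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_input", "removed_far", "removed_speed", "removed_single_outlier")}
        d["n_retained"] = self.n_retained
        return d


def _check_sorted_unique(fixes: pd.DataFrame) -> None:
    t = fixes["timestamp"]
    if t.duplicated().any():
        raise DataError("duplicate timestamps within one individual's track")
    if not t.is_monotonic_increasing:
        raise DataError("fixes must be time-sorted within an individual")


def clip_to_deployment(fixes: pd.DataFrame, release_time, end_time) -> pd.DataFrame:
    """Keep fixes with release_time <= t <= end_time (closed interval)."""
    release_time = pd.Timestamp(release_time)
    end_time = pd.Timestamp(end_time)
    if release_time > end_time:
        raise ValueError("release_time must not be after end_time")
    mask = (fixes["timestamp"] >= release_time) & (fixes["timestamp"] <= end_time)
    return fixes.loc[mask]


def filter_far(fixes: pd.DataFrame, capture_site: tuple[float, float],
               params: FilterParams = FilterParams()):
    """Remove fixes > max_dist_from_capture from the capture site (lon, lat)."""
    if len(fixes) == 0:
        return fixes, fixes.index[:0]
    lon0, lat0 = capture_site
    d = haversine_m(fixes["lon"].to_numpy(), fixes["lat"].to_numpy(), lon0, lat0)
    removed = fixes.index[d > params.max_dist_from_capture]
    return fixes.drop(index=removed), removed


def filter_speed(fixes: pd.DataFrame, params: FilterParams = FilterParams()):
    """Sequentially remove fixes arriving faster than max_speed from the
    previously retained fix; the later fix of a violating leg is dropped."""
    if len(fixes) == 0:
        return fixes, fixes.index[:0]
    _check_sorted_unique(fixes)
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    t = fixes["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    keep = [0]
    removed_pos = []
    vmax_ms = params.max_speed / 3.6
    for i in range(1, len(fixes)):
        j = keep[-1]
        dt = t[i] - t[j]
        d = haversine_m(lon[j], lat[j], lon[i], lat[i])
        if dt <= 0 or d / dt > vmax_ms:
            removed_pos.append(i)
        else:
            keep.append(i)
    removed = fixes.index[removed_pos]
    return fixes.drop(index=removed), removed


def filter_single_outlier(fixes: pd.DataFrame, params: FilterParams = FilterParams()):
    """Remove isolated jumps: interior fix B with dist(A,B) and dist(B,C)
    both > outlier_jump while A and C sit within outlier_neighbor_window."""
    if len(fixes) < 3:
        return fixes, fixes.index[:0]
    _check_sorted_unique(fixes)
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    d_prev = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])        # leg i -> i+1
    d_skip = haversine_m(lon[:-2], lat[:-2], lon[2:], lat[2:])        # i -> i+2
    bad = ((d_prev[:-1] > params.outlier_jump)
           & (d_prev[1:] > params.outlier_jump)
           & (d_skip <= params.outlier_neighbor_window))
    removed = fixes.index[1:-1][bad]
    return fixes.drop(index=removed), removed


def run_filters(fixes: pd.DataFrame, capture_site: tuple[float, float],
                params: FilterParams = FilterParams(),
                release_time=None, end_time=None):
    """Full per-individual pipeline: clip -> far -> speed -> single outlier.

    Returns the retained fixes and a :class:`FilterReport`.  Idempotent: a
    second pass over the output removes nothing.
    """
    if release_time is not None and end_time is not None:
        fixes = clip_to_deployment(fixes, release_time, end_time)
    report = FilterReport(n_input=len(fixes))
    fixes, rm_far = filter_far(fixes, capture_site, params)
    fixes, rm_speed = filter_speed(fixes, params)
    fixes, rm_out = filter_single_outlier(fixes, params)
    report.removed_far = len(rm_far)
    report.removed_speed = len(rm_speed)
    report.removed_single_outlier = len(rm_out)
    return fixes, report


def filter_dataset(fixes: pd.DataFrame, captures: pd.DataFrame,
                   params: FilterParams = FilterParams()):
    """Filter a multi-individual fix table.

    ``captures`` has one row per individual: individual_id, lon, lat and
    optionally release_time / end_time for deployment clipping.
    Returns (filtered fixes, pooled FilterReport, per-individual reports).
    """
    cap = captures.set_index("individual_id")
    out = []
    total = FilterReport()
    per_individual: dict = {}
    for ind, grp in fixes.groupby("individual_id", sort=False):
        row = cap.loc[ind]
        rt = row.get("release_time") if "release_time" in cap.columns else None
        et = row.get("end_time") if "end_time" in cap.columns else None
        grp = grp.sort_values("timestamp")
        kept, rep = run_filters(grp, (row["lon"], row["lat"]), params,
                                release_time=rt, end_time=et)
        out.append(kept)
        per_individual[ind] = rep
        total = total + rep
    kept_all = pd.concat(out) if out else fixes.iloc[:0]
    return kept_all, total, per_individual
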