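"""Nest attendance: at-nest classification and per-sex daily summaries.

An individual is *at the nest* in a paired slot when either

1. its own position is within 15 m of the nest coordinates (inclusive), or
2. it is "together" with its partner and the partner is within 15 m.

Proportions are over recorded paired slots, treating missing slots as
missing at random.  Rule 2 is applied in a single step (it is not chained
through the partner's own rule-2 status).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geo import LocalProjection, planar_distance
from .proximity import local_day

#: inclusive at-nest radius, metres
NEST_RADIUS_M = 15.0


@dataclass
class NestRecord:
    """One nest: identity, members, location and clutch metadata."""

    nest_id: str
    male_id: str
    female_id: str
    lon: float
    lat: float
    clutch_init_date: Optional[pd.Timestamp] = None
    clutch_number: int = 1
    epp: Optional[bool] = None
    n_eggs: int = 4

    def __post_init__(self):
        if self.lon is None or self.lat is None:
            raise ValueError(f"nest {self.nest_id} lacks coordinates")
        if self.clutch_init_date is not None:
            self.clutch_init_date = pd.Timestamp(self.clutch_init_date)


def classify_at_nest(labeled: pd.DataFrame, nest: NestRecord,
                     projection: LocalProjection | None = None,
                     radius_m: float = NEST_RADIUS_M) -> pd.DataFrame:
    """Flag each member of each paired slot as at-nest or not.

    ``labeled`` is classify_together output with member coordinates, member
    "a" = male, member "b" = female.  Adds columns at_nest_male and
    at_nest_female.
    """
    proj = projection or LocalProjection()
    nx, ny = proj.forward(nest.lon, nest.lat)
    out = labeled.copy()
    if len(out) == 0:
        out["at_nest_male"] = pd.Series(dtype=bool)
        out["at_nest_female"] = pd.Series(dtype=bool)
        return out
    d_m = planar_distance(out["x_a"].to_numpy(), out["y_a"].to_numpy(), nx, ny)
    d_f = planar_distance(out["x_b"].to_numpy(), out["y_b"].to_numpy(), nx, ny)
    near_m = d_m <= radius_m
    near_f = d_f <= radius_m
    tog = out["together"].to_numpy(dtype=bool)
    out["at_nest_male"] = near_m | (tog & near_f)
    out["at_nest_female"] = near_f | (tog & near_m)
    return out


def attendance_day_summary(flagged: pd.DataFrame,
                           clutch_init_date=None) -> pd.DataFrame:
    """Per-sex per-day attendance decomposition.

    For each sex and local day: ``at_nest`` (total), ``at_nest_with_mate``
    (at nest while together), ``at_nest_alone`` (at nest, not together) and
    ``alone_away`` (neither together nor at nest), all as proportions of
    recorded paired slots.  at_nest = with_mate + alone exactly.
    """
    cols = ["date", "day_rel", "sex", "n_slots", "at_nest",
            "at_nest_with_mate", "at_nest_alone", "alone_away"]
    if len(flagged) == 0:
        return pd.DataFrame(columns=cols)
    day = local_day(flagged["slot_time"]).values
    rows = []
    for sex, col in (("M", "at_nest_male"), ("F", "at_nest_female")):
        at = flagged[col].to_numpy(dtype=bool)
        tog = flagged["together"].to_numpy(dtype=bool)
        df = pd.DataFrame({
            "date": day,
            "at": at,
            "with_mate": at & tog,
            "alone_at": at & ~tog,
            "alone_away": ~tog & ~at,
        })
        grp = df.groupby("date")
        agg = grp.agg(n_slots=("at", "size"), at_nest=("at", "mean"),
                      at_nest_with_mate=("with_mate", "mean"),
                      at_nest_alone=("alone_at", "mean"),
                      alone_away=("alone_away", "mean")).reset_index()
        agg["sex"] = sex
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    if clutch_init_date is not None:
        out["day_rel"] = (pd.to_datetime(out["date"])
                          - pd.Timestamp(clutch_init_date)).dt.days
    else:
        out["day_rel"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out[cols]


def first_nest_visit_day(flagged: pd.DataFrame, clutch_init_date):
    """day_rel of the first at-nest slot of either member.

    Returns (day_rel, has_prior_data): ``has_prior_data`` is True when at
    least one earlier day of paired data exists before the first visit —
    the inclusion criterion for population summaries of visit onset.
    Returns (None, False) when no slot is at-nest.
    """
    at = (flagged["at_nest_male"].to_numpy(dtype=bool)
          | flagged["at_nest_female"].to_numpy(dtype=bool))
    if not at.any():
        return None, False
    day = pd.to_datetime(pd.Series(local_day(flagged["slot_time"])))
    cid = pd.Timestamp(clutch_init_date)
    day_rel = (day - cid).dt.days.to_numpy()
    first = int(day_rel[at].min())
    has_prior = bool((day_rel < first).any())
    return first, has_prior
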