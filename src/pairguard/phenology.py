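"""Clutch initiation dates and season covariates.

Clutch initiation (the day the first egg is laid, day 0 of the relative
axis) is back-calculated from whichever evidence channel a nest offers,
assuming one egg laid per day:

1. nests found during laying: ``discovery - (n_eggs_at_discovery - 1)``;
2. hatched clutches: ``hatch - (clutch_size - 1) - incubation`` with a mean
   incubation of 17 days for incubator-hatched and 19 days for naturally
   incubated clutches;
3. unhatched clutches aged by egg flotation:
   ``discovery - flotation_age - (n_eggs_at_discovery - 1)``;
4. a manual override date from more reliable field observations, which wins
   over everything; and
5. onset of nest visits by the tagged male (a date supplied directly).

Priority: manual override > laying back-count > hatch > flotation > male
visits.  The first-egg day carries offset 0, hence the ``- 1`` terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

INCUBATION_DAYS_INCUBATOR = 17
INCUBATION_DAYS_NATURAL = 19


@dataclass
class NestEvidence:
    """Raw evidence for one nest's clutch initiation date."""

    nest_id: str
    discovery_date: Optional[pd.Timestamp] = None
    n_eggs_at_discovery: Optional[int] = None
    found_during_laying: bool = False
    hatch_date: Optional[pd.Timestamp] = None
    hatch_context: Optional[str] = None       # 'incubator' | 'natural'
    flotation_age_days: Optional[float] = None
    clutch_size: Optional[int] = None
    manual_override_date: Optional[pd.Timestamp] = None
    male_visit_onset: Optional[pd.Timestamp] = None

    def __post_init__(self):
        for f in ("discovery_date", "hatch_date", "manual_override_date",
                  "male_visit_onset"):
            v = getattr(self, f)
            if v is not None:
                setattr(self, f, pd.Timestamp(v))
        for f, v in (("n_eggs_at_discovery", self.n_eggs_at_discovery),
                     ("clutch_size", self.clutch_size)):
            if v is not None and v < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.clutch_size is not None and self.clutch_size > 6:
            raise ValueError("clutch_size above the hard cap of 6")


@dataclass(frozen=True)
class PhenologyParams:
    incubation_days_incubator: int = INCUBATION_DAYS_INCUBATOR
    incubation_days_natural: int = INCUBATION_DAYS_NATURAL
    inconsistency_warn_days: int = 3


def _candidate_estimates(ev: NestEvidence, params: PhenologyParams) -> dict:
    est = {}
    if ev.manual_override_date is not None:
        est[4] = ev.manual_override_date
    if (ev.found_during_laying and ev.discovery_date is not None
            and ev.n_eggs_at_discovery is not None and ev.n_eggs_at_discovery >= 1):
        est[1] = ev.discovery_date - pd.Timedelta(days=ev.n_eggs_at_discovery - 1)
    if ev.hatch_date is not None and ev.clutch_size:
        inc = (params.incubation_days_natural if ev.hatch_context == "natural"
               else params.incubation_days_incubator)
        est[2] = ev.hatch_date - pd.Timedelta(days=(ev.clutch_size - 1) + inc)
    if (ev.flotation_age_days is not None and ev.discovery_date is not None
            and ev.n_eggs_at_discovery is not None and ev.n_eggs_at_discovery >= 1):
        est[3] = ev.discovery_date - pd.Timedelta(
            days=round(ev.flotation_age_days) + (ev.n_eggs_at_discovery - 1))
    if ev.male_visit_onset is not None:
        est[5] = ev.male_visit_onset
    return est


def estimate_clutch_initiation(evidence: NestEvidence,
                               params: PhenologyParams = PhenologyParams()):
    """Return (clutch_init_date, method) from the highest-priority channel.

    Raises when no channel is usable; warns when available channels disagree
    by more than ``inconsistency_warn_days`` (the chosen method still wins).
    """
    est = _candidate_estimates(evidence, params)
    if not est:
        raise ValueError(f"nest {evidence.nest_id}: no usable evidence channel")
    dates = list(est.values())
    spread = (max(dates) - min(dates)).days
    if len(dates) > 1 and spread > params.inconsistency_warn_days:
        warnings.warn(f"nest {evidence.nest_id}: evidence channels diverge by "
                      f"{spread} days", stacklevel=2)
    for method in (4, 1, 2, 3, 5):
        if method in est:
            return est[method], method
    raise AssertionError("unreachable")


def standardize_init_date(dates: pd.Series, years: pd.Series | None = None) -> pd.Series:
    """Clutch initiation date minus its within-year mean, in (real) days."""
    dates = pd.to_datetime(pd.Series(dates))
    if len(dates) == 0:
        return pd.Series(dtype=float)
    years = dates.dt.year if years is None else pd.Series(years, index=dates.index)
    ordinal = dates.map(pd.Timestamp.toordinal).astype(float)
    return ordinal - ordinal.groupby(years).transform("mean")


def assign_clutch_order(clutches: pd.DataFrame) -> pd.Series:
    """Rank each female's clutches (1, 2, 3) by initiation date.

    ``clutches`` needs female_id, nest_id and clutch_init_date.  Date ties
    within a female are broken by nest_id with a warning.
    """
    df = clutches.copy()
    df["_date"] = pd.to_datetime(df["clutch_init_date"])
    dup = df.duplicated(subset=["female_id", "_date"], keep=False)
    if dup.any():
        warnings.warn("tied clutch initiation dates within a female; "
                      "ordering by nest_id", stacklevel=2)
    order = (df.sort_values(["female_id", "_date", "nest_id"])
               .groupby("female_id").cumcount() + 1)
    return order.reindex(df.index).rename("clutch_number")


def split_renest_data(fixes: pd.DataFrame, failure_time) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one pair's fixes at the failure of its first clutch.

    Data up to and including the failure instant belong to the first clutch;
    everything after to the replacement clutch.
    """
    ft = pd.Timestamp(failure_time)
    before = fixes[fixes["timestamp"] <= ft]
    after = fixes[fixes["timestamp"] > ft]
    return before, after
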