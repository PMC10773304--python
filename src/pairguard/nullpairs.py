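"""Random non-breeding pair comparison set.

The baseline for "time together" is built from opposite-sex dyads that did
NOT breed together.  For each focal female and each day relative to her
clutch initiation, up to 50 eligible dyads are sampled without replacement.
A dyad is eligible on a date when (1) it has paired location data covering
at least 50% of that day and (2) it was together in at least one 10-min
slot anywhere in the data (dyads that never met are uninformative about
proximity maintenance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: nominal number of 10-min slots in a full day
SLOTS_PER_DAY = 144


@dataclass
class NullPairSample:
    """Sampled comparison dyads for one focal nest-day."""

    focal_nest_id: str
    day_rel: int
    date: object
    pairs: list = field(default_factory=list)   # (male_id, female_id)
    shortfall: bool = False


def eligible_random_pairs(dyad_daily: pd.DataFrame, date,
                          breeding_dyads: set[tuple] | None = None,
                          min_coverage: float = 0.5,
                          slots_per_day: int = SLOTS_PER_DAY) -> list[tuple]:
    """Dyads eligible on ``date``.

    ``dyad_daily`` holds one row per dyad per date: male_id, female_id,
    date, n_slots, n_together.  Coverage counts paired slots against the
    nominal daily schedule; the ever-together criterion is evaluated over
    the dyad's whole record.
    """
    eligible_by_date = eligibility_by_date(dyad_daily, breeding_dyads,
                                           min_coverage, slots_per_day)
    return eligible_by_date.get(date, [])


def eligibility_by_date(dyad_daily: pd.DataFrame,
                        breeding_dyads: set[tuple] | None = None,
                        min_coverage: float = 0.5,
                        slots_per_day: int = SLOTS_PER_DAY) -> dict:
    """{date: sorted eligible dyads}, computed once for the whole table."""
    breeding_dyads = breeding_dyads or set()
    ever = (dyad_daily.groupby(["male_id", "female_id"])["n_together"]
            .transform("sum") > 0)
    keep = (ever
            & (dyad_daily["n_slots"] >= min_coverage * slots_per_day)
            & ~pd.MultiIndex.from_frame(
                dyad_daily[["male_id", "female_id"]]).isin(breeding_dyads))
    rows = dyad_daily[keep]
    out: dict = {}
    for date, grp in rows.groupby("date"):
        out[date] = sorted(zip(grp["male_id"], grp["female_id"]))
    return out


def sample_null(candidates: list[tuple], n: int = 50,
                rng: np.random.Generator | int | None = None) -> tuple[list, bool]:
    """Uniform sample of ``n`` dyads without replacement.

    With fewer than ``n`` candidates all are taken and the shortfall is
    flagged (and logged); an empty candidate set yields an empty sample.
    Deterministic for a given rng seed.
    """
    rng = np.random.default_rng(rng)
    if len(candidates) == 0:
        log.warning("no eligible random dyads for this day")
        return [], True
    if len(candidates) <= n:
        if len(candidates) < n:
            log.warning("only %d eligible dyads (< %d); taking all",
                        len(candidates), n)
        return list(candidates), len(candidates) < n
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)], False


def build_null_samples(dyad_daily: pd.DataFrame, nests: pd.DataFrame,
                       day_rel_range: tuple[int, int] = (-5, 10),
                       n: int = 50, seed: int | None = None) -> list[NullPairSample]:
    """Sample comparison dyads for every focal nest-day in the range."""
    rng = np.random.default_rng(seed)
    breeding = set(zip(nests["male_id"], nests["female_id"]))
    eligible = eligibility_by_date(dyad_daily, breeding)
    samples = []
    for _, nest in nests.iterrows():
        cid = pd.Timestamp(nest["clutch_init_date"])
        for day_rel in range(day_rel_range[0], day_rel_range[1] + 1):
            date = (cid + pd.Timedelta(days=day_rel)).date()
            cands = eligible.get(date, [])
            pairs, short = sample_null(cands, n=n, rng=rng)
            samples.append(NullPairSample(nest["nest_id"], day_rel, date,
                                          pairs, short))
    return samples


def null_daily_summaries(samples: list[NullPairSample],
                         dyad_daily: pd.DataFrame) -> pd.DataFrame:
    """Daily together proportions of the sampled dyads, on the focal
    female's day_rel axis (one row per sampled dyad per focal nest-day)."""
    keyed = dyad_daily.set_index(["male_id", "female_id", "date"])
    rows = []
    for s in samples:
        for male_id, female_id in s.pairs:
            try:
                row = keyed.loc[(male_id, female_id, s.date)]
            except KeyError:
                continue
            rows.append({
                "focal_nest_id": s.focal_nest_id,
                "pair_id": f"{male_id}x{female_id}",
                "day_rel": s.day_rel,
                "date": s.date,
                "n_slots": int(row["n_slots"]),
                "n_together": int(row["n_together"]),
            })
    out = pd.DataFrame(rows, columns=["focal_nest_id", "pair_id", "day_rel",
                                      "date", "n_slots", "n_together"])
    if len(out):
        out["proportion_together"] = out["n_together"] / out["n_slots"]
    else:
        out["proportion_together"] = pd.Series(dtype=float)
    return out


def null_comparison(summaries_breeding: pd.DataFrame,
                    summaries_null: pd.DataFrame,
                    windows: dict[str, tuple[int, int]] | None = None) -> dict:
    """Stack breeding and null daily summaries per analysis window.

    Returns {window name: DataFrame} with a ``pair_type`` factor in
    {'breeding', 'random'}, ready for the proportion models.  Windows must
    not overlap.
    """
    windows = windows or {"prelaying": (-5, -1), "laying": (0, 3),
                          "post": (4, 10)}
    spans = sorted(windows.values())
    for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
        if b >= c:
            raise ValueError("analysis windows overlap")
    out = {}
    b = summaries_breeding.copy()
    b["pair_type"] = "breeding"
    r = summaries_null.copy()
    r["pair_type"] = "random"
    cols = ["pair_id", "day_rel", "n_slots", "n_together", "pair_type"]
    stacked = pd.concat([b[cols], r[cols]], ignore_index=True)
    for name, (lo, hi) in windows.items():
        out[name] = stacked[(stacked["day_rel"] >= lo)
                            & (stacked["day_rel"] <= hi)].reset_index(drop=True)
    return out
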