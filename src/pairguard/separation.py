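"""Separation events: together -> not-together transitions and who moved.

Each transition between two consecutive paired slots is one event.  Each
member's displacement is the straight-line planar distance between its own
fixes at the two bracketing slots; the *mover* is the member with the
strictly larger displacement (equal displacements are recorded as a tie and
excluded from mover-sex models).  The partner is "stationary" when the
non-mover displaced at most 30 m.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .proximity import local_day

#: a non-mover within this displacement (m) counts as stationary
STATIONARY_THRESHOLD_M = 30.0


def detect_separations(labeled: pd.DataFrame, pair_id=None,
                       sex_a: str = "M", sex_b: str = "F") -> pd.DataFrame:
    """Extract one event per together -> not-together transition.

    ``labeled`` is the output of :func:`pairguard.proximity.classify_together`
    (time-sorted, with member coordinates x_a/y_a and x_b/y_b); member "a"
    has sex ``sex_a``, member "b" sex ``sex_b``.

    Returns a DataFrame with event_time (the not-together slot), the two
    displacements keyed by sex, mover in {'M', 'F', 'tie'} and
    partner_stationary.
    """
    cols = ["pair_id", "event_time", "displacement_male",
            "displacement_female", "mover", "partner_stationary"]
    if len(labeled) < 2:
        return pd.DataFrame(columns=cols)
    lab = labeled.reset_index(drop=True)
    tog = lab["together"].to_numpy(dtype=bool)
    trans = np.flatnonzero(tog[:-1] & ~tog[1:])  # index of the together slot
    if len(trans) == 0:
        return pd.DataFrame(columns=cols)

    def disp(xcol, ycol):
        x = lab[xcol].to_numpy(dtype=float)
        y = lab[ycol].to_numpy(dtype=float)
        return np.hypot(x[trans + 1] - x[trans], y[trans + 1] - y[trans])

    d_a = disp("x_a", "y_a")
    d_b = disp("x_b", "y_b")
    d_by_sex = {sex_a: d_a, sex_b: d_b}
    mover = np.where(d_a > d_b, sex_a, np.where(d_b > d_a, sex_b, "tie"))
    nonmover_disp = np.where(d_a > d_b, d_b, np.where(d_b > d_a, d_a,
                                                      np.minimum(d_a, d_b)))
    out = pd.DataFrame({
        "pair_id": pair_id,
        "event_time": lab["slot_time"].to_numpy()[trans + 1],
        "displacement_male": d_by_sex.get("M", np.full(len(trans), np.nan)),
        "displacement_female": d_by_sex.get("F", np.full(len(trans), np.nan)),
        "mover": mover,
        "partner_stationary": nonmover_disp <= STATIONARY_THRESHOLD_M,
    })
    return out[cols]


def separation_day_stats(events: pd.DataFrame, clutch_init_date=None) -> pd.DataFrame:
    """Per-day event counts and per-sex mover counts for one dyad."""
    cols = ["date", "day_rel", "n_events", "n_female_mover", "n_male_mover",
            "n_tie", "female_share"]
    if len(events) == 0:
        return pd.DataFrame(columns=cols)
    day = local_day(events["event_time"])
    grp = events.groupby(day.values)
    out = pd.DataFrame({
        "n_events": grp.size(),
        "n_female_mover": grp["mover"].apply(lambda m: int((m == "F").sum())),
        "n_male_mover": grp["mover"].apply(lambda m: int((m == "M").sum())),
        "n_tie": grp["mover"].apply(lambda m: int((m == "tie").sum())),
    })
    out.index.name = "date"
    out = out.reset_index()
    attributed = out["n_female_mover"] + out["n_male_mover"]
    out["female_share"] = np.where(attributed > 0,
                                   out["n_female_mover"] / attributed.replace(0, 1),
                                   np.nan)
    if clutch_init_date is not None:
        out["day_rel"] = (pd.to_datetime(out["date"])
                          - pd.Timestamp(clutch_init_date)).dt.days
    else:
        out["day_rel"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out[cols]


def mover_displacement(events: pd.DataFrame) -> pd.Series:
    """Displacement of the attributed mover (NaN for ties)."""
    return pd.Series(
        np.where(events["mover"] == "M", events["displacement_male"],
                 np.where(events["mover"] == "F", events["displacement_female"],
                          np.nan)),
        index=events.index, name="mover_displacement")


def separation_distance_table(events: pd.DataFrame,
                              windows: dict[str, tuple[int, int]] | None = None
                              ) -> pd.DataFrame:
    """Mover displacement summaries by mover sex and day_rel window.

    ``events`` must carry a ``day_rel`` column (merge from day stats or the
    pipeline).  Ties are excluded.  Returns mean, median, SE and n per
    (window, sex) cell; empty input yields an empty table.
    """
    windows = windows or {"prelaying": (-5, -1), "laying": (0, 3)}
    ev = events[events["mover"].isin(["M", "F"])].copy()
    if len(ev) == 0:
        return pd.DataFrame(columns=["window", "mover", "n", "mean_m",
                                     "median_m", "se_m"])
    ev["mover_displacement"] = mover_displacement(ev)
    rows = []
    for name, (lo, hi) in windows.items():
        sub = ev[(ev["day_rel"] >= lo) & (ev["day_rel"] <= hi)]
        for sex, grp in sub.groupby("mover"):
            d = grp["mover_displacement"].to_numpy(dtype=float)
            rows.append({
                "window": name, "mover": sex, "n": len(d),
                "mean_m": float(np.mean(d)),
                "median_m": float(np.median(d)),
                "se_m": float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0,
            })
    return pd.DataFrame(rows, columns=["window", "mover", "n", "mean_m",
                                       "median_m", "se_m"])
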