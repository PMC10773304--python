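"""Dyadic proximity: pairing fix streams and the together/not-together rules.

Two individuals' fixes are first matched into near-simultaneous *paired
observations* (one-to-one, greedily by ascending time gap, gap capped at
10 min).  Each paired observation is then labelled by three rules:

1. candidate-together where the planar distance is below a *dynamic*
   threshold that grows with the time gap between the two fixes
   (30 m at zero gap, plus an allowance for movement during the gap);
2. a maximal run of candidate slots (a *bout*) counts as together only if
   at least one of its distances is below the fixed 30-m threshold;
3. if the final slot of a confirmed bout is > 30 m apart, that slot is
   relabelled not-together — the separating flight itself is not "together".

Daily proportions divide together slots by recorded paired slots per local
calendar day (the study site has 24-h daylight; days follow local civil
time, a fixed UTC offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import LocalProjection, planar_distance

#: fixed local civil time offset of the study site from UTC, hours
LOCAL_UTC_OFFSET_H = -8


@dataclass(frozen=True)
class TogetherParams:
    """Thresholds of the together classification."""

    fixed_threshold: float = 30.0        # m, rule 2 (strict '<')
    base_threshold: float = 30.0         # m, dynamic threshold at zero gap
    gap_allowance_rate: float = 12.0     # m per minute of pairing gap
    max_pairing_gap: float = 10.0        # minutes

    def __post_init__(self):
        for name in ("fixed_threshold", "base_threshold",
                     "gap_allowance_rate", "max_pairing_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def dynamic_threshold(gap_min, params: TogetherParams = TogetherParams()):
    """Distance threshold in metres for a pairing gap in minutes.

    Linear in the gap: ``base + rate * gap``; 30 m at zero gap, monotone
    non-decreasing.  The allowance absorbs genuine movement that can happen
    between the two asynchronous fixes.
    """
    gap = np.asarray(gap_min, dtype=float)
    if np.any(gap < 0):
        raise ValueError("pairing gap must be non-negative")
    return params.base_threshold + params.gap_allowance_rate * gap


def pair_fixes(fixes_a: pd.DataFrame, fixes_b: pd.DataFrame,
               params: TogetherParams = TogetherParams(),
               projection: LocalProjection | None = None) -> pd.DataFrame:
    """Match two time-sorted fix streams into paired observations.

    One-to-one greedy matching by ascending gap: every candidate (i, j) with
    |t_a_i - t_b_j| <= max_pairing_gap is considered in order of increasing
    gap (ties broken by index for determinism); a candidate is accepted when
    both fixes are still unmatched.  Unmatched fixes yield no observation.

    Returns a DataFrame with columns slot_time, t_a, t_b, gap_min, distance,
    x_a, y_a, x_b, y_b sorted by slot_time.
    """
    proj = projection or LocalProjection()
    cols = ["slot_time", "t_a", "t_b", "gap_min", "distance",
            "x_a", "y_a", "x_b", "y_b"]
    if len(fixes_a) == 0 or len(fixes_b) == 0:
        return pd.DataFrame(columns=cols)

    ta = fixes_a["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    tb = fixes_b["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    max_gap_ns = int(params.max_pairing_gap * 60 * 1e9)

    lo = np.searchsorted(tb, ta - max_gap_ns, side="left")
    hi = np.searchsorted(tb, ta + max_gap_ns, side="right")
    counts = hi - lo
    ii = np.repeat(np.arange(len(ta)), counts)
    jj = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi)]) \
        if counts.sum() else np.empty(0, dtype=int)
    if len(ii) == 0:
        return pd.DataFrame(columns=cols)
    gaps = np.abs(ta[ii] - tb[jj])

    order = np.lexsort((jj, ii, gaps))
    used_a = np.zeros(len(ta), dtype=bool)
    used_b = np.zeros(len(tb), dtype=bool)
    sel_i, sel_j = [], []
    for k in order:
        i, j = ii[k], jj[k]
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            sel_i.append(i)
            sel_j.append(j)
    sel_i = np.asarray(sel_i, dtype=int)
    sel_j = np.asarray(sel_j, dtype=int)

    xa, ya = proj.forward(fixes_a["lon"].to_numpy(), fixes_a["lat"].to_numpy())
    xb, yb = proj.forward(fixes_b["lon"].to_numpy(), fixes_b["lat"].to_numpy())
    t_a = fixes_a["timestamp"].to_numpy()[sel_i]
    t_b = fixes_b["timestamp"].to_numpy()[sel_j]
    slot = t_a + (t_b - t_a) / 2
    out = pd.DataFrame({
        "slot_time": slot,
        "t_a": t_a,
        "t_b": t_b,
        "gap_min": np.abs(ta[sel_i] - tb[sel_j]) / 60e9,
        "distance": planar_distance(xa[sel_i], ya[sel_i], xb[sel_j], yb[sel_j]),
        "x_a": xa[sel_i], "y_a": ya[sel_i],
        "x_b": xb[sel_j], "y_b": yb[sel_j],
    })
    return out.sort_values("slot_time", kind="stable").reset_index(drop=True)


def classify_together(observations: pd.DataFrame,
                      params: TogetherParams = TogetherParams()) -> pd.DataFrame:
    """Label time-sorted paired observations with the three together rules.

    Adds columns ``candidate`` (rule 1), ``bout_id`` (consecutive candidate
    runs, -1 outside bouts; ids count confirmed and rejected runs alike) and
    ``together`` (final label after rules 2 and 3).
    """
    obs = observations.reset_index(drop=True).copy()
    n = len(obs)
    if n == 0:
        obs["candidate"] = pd.Series(dtype=bool)
        obs["bout_id"] = pd.Series(dtype=int)
        obs["together"] = pd.Series(dtype=bool)
        return obs

    dist = obs["distance"].to_numpy(dtype=float)
    gap = obs["gap_min"].to_numpy(dtype=float)
    cand = dist < dynamic_threshold(gap, params)

    # maximal runs of candidate slots
    starts = cand & ~np.concatenate(([False], cand[:-1]))
    run_id = np.where(cand, np.cumsum(starts) - 1, -1)

    together = cand.copy()
    n_runs = int(starts.sum())
    for r in range(n_runs):
        idx = np.flatnonzero(run_id == r)
        # rule 2: a bout needs at least one distance under the fixed threshold
        if not np.any(dist[idx] < params.fixed_threshold):
            together[idx] = False
        # rule 3: a separating final slot (> 30 m) is not "together"
        elif dist[idx[-1]] > params.fixed_threshold:
            together[idx[-1]] = False

    obs["candidate"] = cand
    obs["bout_id"] = run_id
    obs["together"] = together
    return obs


def classify_together_reference(distances, gaps,
                                params: TogetherParams = TogetherParams()):
    """Literal, slot-by-slot reading of the three rules (test oracle).

    Enumerates maximal candidate runs with an explicit loop and applies
    rules 2 and 3 exactly as stated; independent of the vectorised
    implementation in :func:`classify_together`.
    """
    labels = []
    runs: list[list[int]] = []
    current: list[int] = []
    for i, (d, g) in enumerate(zip(distances, gaps)):
        is_cand = d < params.base_threshold + params.gap_allowance_rate * g
        labels.append(is_cand)
        if is_cand:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    for run in runs:
        if min(distances[i] for i in run) >= params.fixed_threshold:
            for i in run:
                labels[i] = False
        elif distances[run[-1]] > params.fixed_threshold:
            labels[run[-1]] = False
    return labels


def local_day(timestamps) -> pd.Series:
    """Local civil calendar date of each timestamp (fixed UTC offset)."""
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    return (ts + pd.Timedelta(hours=LOCAL_UTC_OFFSET_H)).dt.normalize().dt.date


def daily_proportions(labeled: pd.DataFrame, clutch_init_date=None) -> pd.DataFrame:
    """Per-local-day slot counts and proportion of together slots.

    ``day_rel`` is the whole-day offset from the clutch initiation date
    (first-egg day = 0); left as NA when the clutch date is unknown.
    Days with zero paired slots yield no row.
    """
    if len(labeled) == 0:
        return pd.DataFrame(columns=["date", "day_rel", "n_slots", "n_together",
                                     "proportion_together"])
    day = local_day(labeled["slot_time"])
    grp = labeled.groupby(day.values)
    out = pd.DataFrame({
        "n_slots": grp.size(),
        "n_together": grp["together"].sum().astype(int),
    })
    out.index.name = "date"
    out = out.reset_index()
    out["proportion_together"] = out["n_together"] / out["n_slots"]
    if clutch_init_date is not None:
        cid = pd.Timestamp(clutch_init_date)
        out["day_rel"] = (pd.to_datetime(out["date"]) - cid).dt.days
    else:
        out["day_rel"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out[["date", "day_rel", "n_slots", "n_together", "proportion_together"]]


def window_mean(summaries: pd.DataFrame, day_rel_window: tuple[int, int],
                pair_col: str = "pair_id", weights: str = "slots"):
    """Descriptive window mean of the together proportion with a
    pair-clustered standard error.

    ``weights='slots'`` pools slots within pair then weights pairs by their
    slot counts; ``weights='days'`` averages unweighted pair means.
    Returns (mean, se, n_pairs).
    """
    lo, hi = day_rel_window
    sel = summaries[(summaries["day_rel"] >= lo) & (summaries["day_rel"] <= hi)]
    if len(sel) == 0:
        raise ValueError("no pair-days in the requested window")
    per_pair = sel.groupby(pair_col).agg(
        n_slots=("n_slots", "sum"), n_together=("n_together", "sum"))
    p = per_pair["n_together"] / per_pair["n_slots"]
    if weights == "slots":
        w = per_pair["n_slots"].to_numpy(dtype=float)
    elif weights == "days":
        w = np.ones(len(per_pair))
    else:
        raise ValueError("weights must be 'slots' or 'days'")
    w = w / w.sum()
    mean = float(np.sum(w * p))
    se = float(np.sqrt(np.sum(w ** 2 * (p - mean) ** 2)))
    return mean, se, len(per_pair)
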