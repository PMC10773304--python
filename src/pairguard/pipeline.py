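"""End-to-end analysis: from raw fixes to summary tables and models.

``run_all`` chains the stages in a fixed order — plausibility filtering,
per-dyad pairing and together classification, separation events, nest
attendance, the random-dyad null comparison, and the mixed models — and
returns every intermediate table plus a JSON-able results dictionary.
Everything downstream of the seed is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .filtering import FilterParams, FilterReport, filter_dataset
from .geo import DEFAULT_SITE
from .glmm import (ModelFit, ModelSpec, diurnal_terms, fit_glmm,
                   marginal_mean, select_quadratic)
from .nest import (NestRecord, attendance_day_summary, classify_at_nest,
                   first_nest_visit_day)
from .nullpairs import build_null_samples, null_comparison, null_daily_summaries
from .phenology import standardize_init_date
from .proximity import (TogetherParams, classify_together, daily_proportions,
                        local_day, pair_fixes, window_mean)
from .separation import (detect_separations, mover_displacement,
                         separation_distance_table)

log = logging.getLogger(__name__)

#: analysis windows in days relative to clutch initiation
DEFAULT_WINDOWS = {"prelaying": (-5, -1), "laying": (0, 3), "post": (4, 10)}


@dataclass
class PipelineResult:
    """All artifacts of one full run."""

    fixes: pd.DataFrame
    filter_report: FilterReport
    labeled: pd.DataFrame          # slot-level classification, all pairs
    daily: pd.DataFrame            # breeding pair-day together summaries
    events: pd.DataFrame           # separation events with day_rel
    attendance: pd.DataFrame       # per sex-day attendance decomposition
    first_visits: pd.DataFrame     # first at-nest day per nest
    dyad_daily: pd.DataFrame       # all male x female dyad-days (null basis)
    null_daily: pd.DataFrame       # sampled random-dyad day summaries
    models: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)


def _pair_label(fixes: pd.DataFrame, male_id: str, female_id: str,
                params: TogetherParams) -> pd.DataFrame:
    male = fixes[fixes["individual_id"] == male_id]
    female = fixes[fixes["individual_id"] == female_id]
    paired = pair_fixes(male, female, params=params)
    return classify_together(paired, params=params)


def breeding_pair_tables(fixes: pd.DataFrame, nests: pd.DataFrame,
                         params: TogetherParams = TogetherParams(),
                         windows: dict | None = None):
    """Slot, day, event, attendance and first-visit tables for all nests."""
    windows = windows or DEFAULT_WINDOWS
    labeled_rows, daily_rows, event_rows, att_rows, fv_rows = [], [], [], [], []
    for _, nest in nests.iterrows():
        cid = pd.Timestamp(nest["clutch_init_date"])
        lab = _pair_label(fixes, nest["male_id"], nest["female_id"], params)
        if len(lab) == 0:
            log.warning("nest %s: no paired fixes", nest["nest_id"])
            continue
        rec = NestRecord(nest_id=nest["nest_id"], male_id=nest["male_id"],
                         female_id=nest["female_id"], lon=nest["lon"],
                         lat=nest["lat"], clutch_init_date=cid)
        lab = classify_at_nest(lab, rec)
        lab.insert(0, "pair_id", nest["pair_id"])
        labeled_rows.append(lab)

        daily = daily_proportions(lab, cid)
        daily.insert(0, "pair_id", nest["pair_id"])
        daily.insert(1, "nest_id", nest["nest_id"])
        daily_rows.append(daily)

        ev = detect_separations(lab, nest["pair_id"])
        if len(ev):
            days = local_day(ev["event_time"])
            ev["day_rel"] = [(d - cid.date()).days for d in days]
            event_rows.append(ev)

        att = attendance_day_summary(lab, cid)
        att.insert(0, "pair_id", nest["pair_id"])
        att_rows.append(att)

        day, prior = first_nest_visit_day(lab, cid)
        fv_rows.append({"nest_id": nest["nest_id"],
                        "pair_id": nest["pair_id"],
                        "first_visit_day": day, "has_prior_data": prior})

    empty_ev = pd.DataFrame(columns=["pair_id", "event_time",
                                     "displacement_male", "displacement_female",
                                     "mover", "partner_stationary", "day_rel"])
    return (pd.concat(labeled_rows, ignore_index=True),
            pd.concat(daily_rows, ignore_index=True),
            pd.concat(event_rows, ignore_index=True) if event_rows else empty_ev,
            pd.concat(att_rows, ignore_index=True),
            pd.DataFrame(fv_rows))


def build_dyad_daily(fixes: pd.DataFrame, nests: pd.DataFrame,
                     params: TogetherParams = TogetherParams()) -> pd.DataFrame:
    """Daily together counts for every male x female dyad in the data.

    The basis table for random-pair eligibility and sampling; includes the
    breeding dyads themselves (excluded later at sampling time).
    """
    males = nests["male_id"].tolist()
    females = nests["female_id"].tolist()
    rows = []
    for i, male_id in enumerate(males):
        male = fixes[fixes["individual_id"] == male_id]
        for female_id in females:
            female = fixes[fixes["individual_id"] == female_id]
            lab = classify_together(pair_fixes(male, female, params=params),
                                    params=params)
            if len(lab) == 0:
                continue
            day = local_day(lab["slot_time"])
            grp = lab.groupby(day.values)["together"]
            part = pd.DataFrame({"n_slots": grp.size(),
                                 "n_together": grp.sum().astype(int)})
            part.index.name = "date"
            part = part.reset_index()
            part.insert(0, "male_id", male_id)
            part.insert(1, "female_id", female_id)
            rows.append(part)
        log.info("dyad daily: male %d/%d done", i + 1, len(males))
    return pd.concat(rows, ignore_index=True)


def _window_counts(daily: pd.DataFrame, window: tuple[int, int],
                   pair_col: str = "pair_id") -> pd.DataFrame:
    lo, hi = window
    sel = daily[(daily["day_rel"] >= lo) & (daily["day_rel"] <= hi)]
    grp = sel.groupby(pair_col)
    out = grp.agg(n_together=("n_together", "sum"),
                  n_slots=("n_slots", "sum")).reset_index()
    return out


def epp_contrast(daily: pd.DataFrame, nests: pd.DataFrame,
                 window: tuple[int, int] = (-5, -1)) -> dict:
    """Pre-laying together time for pairs with vs without extra-pair young.

    Fits a beta-binomial GLMM of window counts on the EPP flag (random
    intercept per pair) and returns group means plus the contrast test.
    """
    counts = _window_counts(daily, window)
    counts = counts.merge(nests[["pair_id", "epp"]], on="pair_id")
    counts["epp_flag"] = np.where(counts["epp"].astype(bool), "epp", "none")
    groups = counts.groupby("epp_flag").apply(
        lambda g: g["n_together"].sum() / g["n_slots"].sum(),
        include_groups=False).to_dict()
    out = {"window": list(window), "mean_by_group": groups,
           "n_pairs": counts.groupby("epp_flag").size().to_dict()}
    if counts["epp_flag"].nunique() == 2 and len(counts) >= 4:
        # one pooled row per pair: a random intercept would be confounded
        # with the dispersion, so use a plain beta-binomial GLM
        spec = ModelSpec("beta_binomial", ("n_together", "n_slots"),
                         ("epp_flag",))
        fit = fit_glmm(counts, spec)
        term = [t for t in fit.beta.index if t.startswith("epp_flag")][0]
        out["contrast"] = {"term": term,
                           "estimate": float(fit.beta[term]),
                           "se": float(fit.se[term]),
                           "p": float(fit.p[term])}
    return out


def fit_together_day_model(daily: pd.DataFrame) -> tuple[ModelSpec, ModelFit, ModelFit]:
    """Quadratic day trend in daily together proportion.

    Beta-binomial on pair-day counts, random intercept and day_rel slope per
    pair; the quadratic term is dropped if non-significant (single step).
    """
    spec = ModelSpec("beta_binomial", ("n_together", "n_slots"),
                     ("day_rel", "day_rel^2"), group="pair_id",
                     random_slope="day_rel")
    data = daily.dropna(subset=["day_rel"]).copy()
    data["day_rel"] = data["day_rel"].astype(float)
    return select_quadratic(data, spec)


def fit_null_models(comparison: dict[str, pd.DataFrame]) -> dict[str, ModelFit]:
    """Breeding vs random contrast per analysis window (random intercept
    per dyad)."""
    fits = {}
    for name, table in comparison.items():
        if len(table) == 0 or table["pair_type"].nunique() < 2:
            continue
        # binomial with a dyad random intercept: the dyad effect absorbs
        # the repeated measures, and the huge breeding/random contrast does
        # not hinge on a day-level dispersion parameter
        spec = ModelSpec("binomial", ("n_together", "n_slots"),
                         ("pair_type",), group="pair_id")
        fits[name] = fit_glmm(table, spec)
    return fits


def fit_diurnal_model(labeled: pd.DataFrame,
                      local_offset_h: float) -> ModelFit:
    """Time-of-day effect on being together, binomial on per-pair-hour
    counts (exactly equivalent to the slot-level model)."""
    terms = diurnal_terms(labeled["slot_time"], local_offset_h)
    df = pd.DataFrame({
        "pair_id": labeled["pair_id"].to_numpy(),
        "hour": ((pd.to_datetime(labeled["slot_time"])
                  + pd.Timedelta(hours=local_offset_h)).dt.hour),
        "together": labeled["together"].to_numpy(dtype=int),
    })
    grp = df.groupby(["pair_id", "hour"])
    counts = grp.agg(n_together=("together", "sum"),
                     n_slots=("together", "size")).reset_index()
    angle = 2.0 * math.pi * counts["hour"] / 24.0
    counts["sin_time"] = np.sin(angle)
    counts["cos_time"] = np.cos(angle)
    spec = ModelSpec("binomial", ("n_together", "n_slots"),
                     ("sin_time", "cos_time"), group="pair_id")
    return fit_glmm(counts, spec)


def diurnal_amplitude(fit: ModelFit) -> float:
    """Peak-to-trough difference of the fitted together probability."""
    beta = fit.beta
    hours = np.arange(0, 24, 0.25)
    angle = 2.0 * math.pi * hours / 24.0
    eta = (beta["intercept"] + beta["sin_time"] * np.sin(angle)
           + beta["cos_time"] * np.cos(angle))
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p.max() - p.min())


def run_all(fixes: pd.DataFrame, nests: pd.DataFrame,
            captures: Optional[pd.DataFrame] = None,
            filter_params: FilterParams = FilterParams(),
            together_params: TogetherParams = TogetherParams(),
            windows: dict | None = None,
            local_offset_h: float = -8.0,
            null_pairs_per_day: int = 50,
            include_null: bool = True,
            seed: int = 0) -> PipelineResult:
    """Run every stage and assemble the results dictionary."""
    windows = windows or DEFAULT_WINDOWS

    log.info("stage 1/6: plausibility filtering (%d fixes)", len(fixes))
    if captures is None:
        captures = pd.DataFrame({
            "individual_id": fixes["individual_id"].unique()})
        captures["lon"], captures["lat"] = DEFAULT_SITE
    fixes, report, _ = filter_dataset(fixes, captures, filter_params)

    log.info("stage 2/6: pairing + together classification (%d nests)",
             len(nests))
    labeled, daily, events, attendance, first_visits = breeding_pair_tables(
        fixes, nests, together_params, windows)

    log.info("stage 3/6: separation events (%d)", len(events))
    if len(events):
        events = events.copy()
        events["mover_displacement"] = mover_displacement(events)

    results: dict = {"filter": report.to_dict()}

    gap_median = float(labeled["gap_min"].median())
    day_profile = (daily.groupby("day_rel")
                   .apply(lambda g: g["n_together"].sum() / g["n_slots"].sum(),
                          include_groups=False))
    together = {"median_gap_min": gap_median,
                "day_profile": {int(k): float(v)
                                for k, v in day_profile.items()}}
    for name, win in windows.items():
        mean, se, n_pairs = window_mean(daily, win)
        together[f"{name}_mean"] = float(mean)
        together[f"{name}_se"] = float(se)
        together[f"{name}_n_pairs"] = int(n_pairs)
    results["together"] = together

    sep: dict = {"n_events": int(len(events))}
    if len(events):
        mv = events[events["mover"].isin(["M", "F"])]
        for name, (lo, hi) in windows.items():
            sel = mv[(mv["day_rel"] >= lo) & (mv["day_rel"] <= hi)]
            sep[f"{name}_female_share"] = (float((sel["mover"] == "F").mean())
                                           if len(sel) else None)
            sep[f"{name}_n"] = int(len(sel))
        sep["partner_stationary_share"] = float(events["partner_stationary"].mean())
        sep["distance_table"] = separation_distance_table(
            events, {k: windows[k] for k in ("prelaying", "laying")
                     if k in windows}).to_dict("records")
    results["separations"] = sep

    log.info("stage 4/6: nest attendance")
    att_profile = (attendance.groupby(["sex", "day_rel"])
                   .apply(lambda g: float(np.average(g["at_nest"],
                                                     weights=g["n_slots"])),
                          include_groups=False))
    fv = first_visits[first_visits["first_visit_day"].notna()
                      & first_visits["has_prior_data"]]
    results["nest"] = {
        "attendance_by_sex_day": {f"{s}:{int(d)}": v
                                  for (s, d), v in att_profile.items()},
        "first_visit_mean_day": (float(fv["first_visit_day"].mean())
                                 if len(fv) else None),
        "first_visit_sd_day": (float(fv["first_visit_day"].std(ddof=1))
                               if len(fv) > 1 else None),
        "first_visit_n": int(len(fv)),
    }

    models: dict[str, ModelFit] = {}
    log.info("stage 5/6: mixed models")
    final_spec, final_fit, initial_fit = fit_together_day_model(daily)
    models["together_day"] = final_fit
    models["together_day_initial"] = initial_fit
    results["models"] = {"together_day": final_fit.to_dict(),
                         "together_day_quadratic_p":
                             float(initial_fit.p.get("day_rel^2", np.nan))}
    dirn = fit_diurnal_model(labeled, local_offset_h)
    models["diurnal"] = dirn
    results["models"]["diurnal"] = dirn.to_dict()
    results["models"]["diurnal_amplitude"] = diurnal_amplitude(dirn)

    std = standardize_init_date(pd.Series(pd.to_datetime(
        nests["clutch_init_date"])))
    results["phenology"] = {"init_date_sd_within_year": float(std.std(ddof=1)),
                            "n_nests": int(len(nests))}

    dyad_daily = pd.DataFrame(columns=["male_id", "female_id", "date",
                                       "n_slots", "n_together"])
    null_daily = pd.DataFrame(columns=["focal_nest_id", "pair_id", "day_rel",
                                       "date", "n_slots", "n_together",
                                       "proportion_together"])
    if include_null:
        log.info("stage 6/6: random-dyad null comparison")
        dyad_daily = build_dyad_daily(fixes, nests, together_params)
        samples = build_null_samples(dyad_daily, nests,
                                     day_rel_range=(min(lo for lo, _ in windows.values()),
                                                    max(hi for _, hi in windows.values())),
                                     n=null_pairs_per_day, seed=seed)
        null_daily = null_daily_summaries(samples, dyad_daily)
        breeding_daily = daily.copy()
        comparison = null_comparison(breeding_daily, null_daily, windows)
        null_fits = fit_null_models(comparison)
        null_res = {}
        for name, table in comparison.items():
            by_type = table.groupby("pair_type").apply(
                lambda g: g["n_together"].sum() / g["n_slots"].sum(),
                include_groups=False)
            null_res[name] = {"mean_by_type": {k: float(v)
                                               for k, v in by_type.items()}}
            if name in null_fits:
                fit = null_fits[name]
                models[f"null_{name}"] = fit
                term = [t for t in fit.beta.index
                        if t.startswith("pair_type")][0]
                null_res[name]["contrast"] = {
                    "term": term, "estimate": float(fit.beta[term]),
                    "se": float(fit.se[term]), "p": float(fit.p[term])}
            shortfall = sum(s.shortfall for s in samples)
            null_res["n_shortfall_days"] = int(shortfall)
        results["null"] = null_res

    if "epp" in nests.columns:
        results["epp"] = epp_contrast(daily, nests,
                                      windows.get("prelaying", (-5, -1)))

    log.info("pipeline done")
    return PipelineResult(fixes=fixes, filter_report=report, labeled=labeled,
                          daily=daily, events=events, attendance=attendance,
                          first_visits=first_visits, dyad_daily=dyad_daily,
                          null_daily=null_daily, models=models,
                          results=results)


def save_figures(result: PipelineResult, out_dir) -> list:
    """Write the two headline figures (day profile, attendance) as PNGs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    profile = result.results["together"]["day_profile"]
    days = sorted(profile)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(days, [profile[d] for d in days], "o-", color="#2b6a99")
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("day relative to clutch initiation")
    ax.set_ylabel("proportion of slots together")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    path = out_dir / "together_day_profile.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    att = result.attendance
    fig, ax = plt.subplots(figsize=(7, 4))
    for sex, color in (("M", "#1f77b4"), ("F", "#d62728")):
        sub = (att[att["sex"] == sex].groupby("day_rel")
               .apply(lambda g: float(np.average(g["at_nest"],
                                                 weights=g["n_slots"])),
                      include_groups=False))
        ax.plot(sub.index, sub.values, "o-", color=color, label=sex)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("day relative to clutch initiation")
    ax.set_ylabel("proportion of slots at nest")
    ax.set_ylim(0, 1)
    ax.legend(title="sex")
    fig.tight_layout()
    path = out_dir / "nest_attendance.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
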