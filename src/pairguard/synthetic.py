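"""Synthetic paired GPS tracks with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without field data:

* two fix streams per pair on jittered 10-min grids (constant per-member
  schedule offsets tuned so pairing gaps have median ~2.6 min, plus +/-1 min
  per-fix jitter) with isotropic GPS noise;
* a two-state together/apart process per pair: daily together probabilities
  and daily separation rates set the stationary distribution and switching
  rates of a per-slot Markov chain;
* movement as a correlated random walk (wrapped-normal turning angles,
  gamma step lengths) attracted to a small set of shared foraging sites.
  While together both members sit near a shared centroid (< 30 m); while
  apart the members hold distinct sites and move independently, and two
  individuals from different pairs co-occur at a site often enough to give
  random dyads a together baseline of roughly 10%;
* separations as discrete flights: a scheduled mover (female with a
  day-dependent probability) jumps a log-normal distance while the partner
  stays within 30 m, giving unambiguous mover ground truth;
* nest visits: per-pair visit onset around 2.6 days before clutch
  initiation, then per-day per-sex attendance targets realised through a
  pair-at-nest probability while together and per-sex alone probabilities
  while apart (females alone are almost never at the nest);
* optional planted corruptions exercising each plausibility filter rule,
  recorded with the rule expected to remove them.

Everything is driven by one seeded generator: identical config + seed give
identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .geo import DEFAULT_SITE, LocalProjection

SLOTS_PER_DAY = 144
LOCAL_UTC_OFFSET_H = -8


def _default_together_prob():
    prob = {d: 0.85 for d in (-7, -6)}
    prob.update({d: 0.90 for d in range(-5, 0)})
    prob.update({0: 0.84, 1: 0.66, 2: 0.47, 3: 0.28})
    prob.update({d: 0.10 for d in range(4, 11)})
    return prob


def _default_separation_rate():
    rate = {d: 1.9 for d in range(-7, 0)}
    rate.update({d: 4.6 for d in range(0, 4)})
    rate.update({d: 3.0 for d in range(4, 11)})
    return rate


def _default_female_mover_prob():
    prob = {d: 0.45 for d in range(-7, 0)}
    prob.update({d: 0.52 for d in range(0, 11)})
    return prob


def _default_attendance():
    male = {d: 0.04 for d in range(-7, -2)}
    male.update({-2: 0.06, -1: 0.10, 0: 0.20, 1: 0.35, 2: 0.50, 3: 0.66})
    male.update({d: 0.80 for d in range(4, 11)})
    female = {d: 0.04 for d in range(-7, -2)}
    female.update({-2: 0.06, -1: 0.10, 0: 0.16, 1: 0.12, 2: 0.09, 3: 0.07})
    female.update({d: 0.02 for d in range(4, 11)})
    return {"M": male, "F": female}


@dataclass
class SimConfig:
    """Study conditions of the simulated season.

    Daily maps are keyed by day relative to clutch initiation; missing days
    reuse the nearest keyed day.  All probabilities must lie in [0, 1] and
    all lengths, durations and rates must be strictly positive.
    """

    n_pairs: int = 40
    season_start: str = "2019-06-05"
    clutch_init_dates: Optional[list] = None
    clutch_date_sd: float = 4.0                      # days, around the mean
    days_before: int = 7
    days_after: int = 10
    fix_interval_min: float = 10.0
    pair_lag_mean_min: float = 2.6                   # median pairing gap ~2.6
    pair_lag_sd_min: float = 1.2
    fix_jitter_min: float = 1.0
    gps_noise_sd: float = 5.0                        # m, per coordinate
    together_prob_by_day: dict = field(default_factory=_default_together_prob)
    separation_rate_by_day: dict = field(default_factory=_default_separation_rate)
    female_mover_prob_by_day: dict = field(default_factory=_default_female_mover_prob)
    separation_dist_logmean: float = math.log(155.0)  # log-m
    separation_dist_logsd: float = 0.5
    separation_dist_max: float = 2000.0               # m, honest flight cap
    nest_attendance_by_day_sex: dict = field(default_factory=_default_attendance)
    female_alone_at_nest_prob: float = 0.02
    nest_onset_mean: float = -2.6                     # day_rel of first visits
    nest_onset_sd: float = 1.2
    step_speed_together: float = 2.0                  # m/min of the centroid
    step_speed_apart: float = 2.4                     # m/min of lone birds
    turning_angle_sd: float = 0.8                     # rad, wrapped normal
    site_attraction: float = 0.7                      # pull toward site/slot
    n_sites: int = 3
    area_half_width: float = 800.0                    # m
    site_switch_prob: float = 0.04                    # per slot, lone birds
    site_switch_prob_together: float = 0.01           # per slot, pairs
    travel_step: float = 140.0                        # m/slot while relocating
    flight_render_threshold: float = 200.0            # m, jump vs glide
    nest_bout_rate: float = 1.0 / 12.0                # visit-chain switching
    within_pair_sd: float = 4.0                       # m, spread when together
    nest_scatter_sd: float = 3.0                      # m, spread on the nest
    nest_avoidance_m: float = 100.0                   # m, non-attending birds
    diurnal_amplitude: float = 0.0                    # together prob max-min
    epp_rate: float = 0.11
    outlier_rates: dict = field(default_factory=lambda: {
        "far": 0.0, "speed": 0.0, "single_outlier": 0.0})
    site_lonlat: tuple = DEFAULT_SITE
    rng_seed: int = 0

    def validate(self) -> None:
        positive = ["n_pairs", "fix_interval_min", "pair_lag_mean_min",
                    "pair_lag_sd_min",
                    "separation_dist_logsd", "step_speed_together",
                    "step_speed_apart", "within_pair_sd", "area_half_width",
                    "nest_scatter_sd", "separation_dist_max"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gps_noise_sd < 0 or self.fix_jitter_min < 0:
            raise ValueError("noise and jitter must be non-negative")
        prob_maps = [self.together_prob_by_day, self.female_mover_prob_by_day,
                     *self.nest_attendance_by_day_sex.values()]
        for m in prob_maps:
            for v in m.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("probabilities must lie in [0, 1]")
        for v in self.separation_rate_by_day.values():
            if v < 0:
                raise ValueError("separation rates must be non-negative")
        for v in self.outlier_rates.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("outlier rates must lie in [0, 1]")


@dataclass
class TruthLog:
    """Ground truth emitted alongside the fixes.

    ``slots``: one row per pair-slot (true together flag, at-nest flags,
    day_rel, nominal slot time).  ``separations``: one row per scripted
    flight (mover sex, flight distance, the not-together slot time).
    ``corrupted``: planted implausible fixes with the filter rule expected
    to remove them.
    """

    slots: pd.DataFrame
    separations: pd.DataFrame
    corrupted: pd.DataFrame


def _lookup(day_map: dict, day: int) -> float:
    if day in day_map:
        return day_map[day]
    keys = sorted(day_map)
    nearest = min(keys, key=lambda k: (abs(k - day), k))
    return day_map[nearest]


def _derive_attendance(cfg: SimConfig, day: int, p_together: float):
    """Split daily per-sex attendance targets into conditional probabilities
    consistent with the rule-2 coupling (together => both or neither)."""
    a_m = _lookup(cfg.nest_attendance_by_day_sex["M"], day)
    a_f = _lookup(cfg.nest_attendance_by_day_sex["F"], day)
    pf_alone = cfg.female_alone_at_nest_prob
    t = p_together
    if t >= 1.0 - 1e-9:
        return min(a_m, a_f, 1.0), 0.0, 0.0
    p_pair = np.clip((a_f - (1.0 - t) * pf_alone) / max(t, 1e-9), 0.0, 1.0)
    p_m_alone = np.clip((a_m - t * p_pair) / (1.0 - t), 0.0, 1.0)
    return float(p_pair), float(p_m_alone), pf_alone


def _wrap(angle):
    return (angle + math.pi) % (2 * math.pi) - math.pi


class _Walker:
    """CRW with site attraction: gamma step lengths (mean speed*dt),
    wrapped-normal turning angles, plus a pull toward the current site.

    Relocations between distant points can either teleport (one within-slot
    flight, used for lone birds) or proceed in bounded travel steps (used
    for pair centroids, so a flight never spans more than ``travel_step``
    per slot)."""

    def __init__(self, pos, site_idx, cfg, rng):
        self.pos = np.asarray(pos, dtype=float)
        self.site_idx = site_idx
        self.heading = rng.uniform(-math.pi, math.pi)
        self.travelling = False

    def begin_travel(self, site_idx):
        self.site_idx = site_idx
        self.travelling = True

    def _travel_step(self, target, cfg):
        delta = target - self.pos
        dist = float(np.hypot(*delta))
        if dist <= cfg.travel_step:
            self.pos = target.copy()
            self.travelling = False
        else:
            self.pos = self.pos + delta / dist * cfg.travel_step

    def step(self, sites, speed, cfg, rng, switch_prob, teleport_switch):
        if not self.travelling and rng.random() < switch_prob:
            choices = [k for k in range(cfg.n_sites) if k != self.site_idx]
            new_site = choices[rng.integers(len(choices))]
            if teleport_switch:
                self.site_idx = new_site
                self.pos = sites[new_site] + rng.normal(0.0, 40.0, size=2)
            else:
                self.begin_travel(new_site)
        if self.travelling:
            self._travel_step(sites[self.site_idx], cfg)
            return self.pos.copy()
        mean_step = speed * cfg.fix_interval_min
        length = rng.gamma(2.0, mean_step / 2.0)
        self.heading = _wrap(self.heading + rng.normal(0.0, cfg.turning_angle_sd))
        move = length * np.array([math.cos(self.heading), math.sin(self.heading)])
        pull = cfg.site_attraction * (sites[self.site_idx] - self.pos)
        pull_len = float(np.hypot(*pull))
        if pull_len > cfg.travel_step:
            # never cover more ground per slot than a directed travel step
            pull = pull * (cfg.travel_step / pull_len)
        self.pos = self.pos + move + pull
        return self.pos.copy()


def _simulate_pair(pair_idx, cfg, clutch_init, sites, rng):
    """One pair's season.  Returns per-member raw positions/times plus
    truth rows (slots, separations)."""
    n_days = cfg.days_before + cfg.days_after + 1
    days = np.arange(-cfg.days_before, cfg.days_after + 1)
    n_slots = n_days * SLOTS_PER_DAY

    # per-day schedule
    p_tog = np.array([_lookup(cfg.together_prob_by_day, d) for d in days])
    sep_rate = np.array([_lookup(cfg.separation_rate_by_day, d) for d in days])
    p_female = np.array([_lookup(cfg.female_mover_prob_by_day, d) for d in days])
    attend = [_derive_attendance(cfg, d, p) for d, p in zip(days, p_tog)]
    onset = int(np.clip(round(rng.normal(cfg.nest_onset_mean, cfg.nest_onset_sd)),
                        -cfg.days_before, -1))

    # nest location away from the foraging sites
    while True:
        nest = rng.uniform(-cfg.area_half_width, cfg.area_half_width, size=2)
        if min(np.hypot(*(nest - s)) for s in sites) > 250.0:
            break

    site0 = int(rng.integers(cfg.n_sites))
    start = sites[site0] + rng.normal(0.0, 30.0, size=2)
    centroid = _Walker(start, site0, cfg, rng)
    lone = {"M": None, "F": None}
    together = True
    last_mover = None
    pair_nest = False     # pair-level visit bout while together
    male_nest = False     # male's own visit bout while apart

    pos = {"M": np.empty((n_slots, 2)), "F": np.empty((n_slots, 2))}
    truth_tog = np.empty(n_slots, dtype=bool)
    truth_nest = {"M": np.zeros(n_slots, dtype=bool),
                  "F": np.zeros(n_slots, dtype=bool)}
    day_rel = np.repeat(days, SLOTS_PER_DAY)
    hours = np.tile(np.arange(SLOTS_PER_DAY) * cfg.fix_interval_min / 60.0,
                    n_days)
    seps = []  # (slot index, mover, flight length)

    for s in range(n_slots):
        di = s // SLOTS_PER_DAY
        fresh: set = set()   # walkers created this slot: no step yet
        p = p_tog[di]
        if cfg.diurnal_amplitude > 0:
            p = float(np.clip(p + 0.5 * cfg.diurnal_amplitude
                              * math.cos(2 * math.pi * (hours[s] - 12.0) / 24.0),
                              0.001, 0.999))
        p = min(max(p, 1e-3), 1 - 1e-3)
        p_ta = min(1.0, sep_rate[di] / (SLOTS_PER_DAY * p))
        p_at = min(1.0, p_ta * p / (1.0 - p))

        # state transition (skip at s=0; pairs start together)
        if s > 0:
            if together and rng.random() < p_ta:
                together = False
                mover = "F" if rng.random() < p_female[di] else "M"
                partner = "M" if mover == "F" else "F"
                flight = min(rng.lognormal(cfg.separation_dist_logmean,
                                           cfg.separation_dist_logsd),
                             cfg.separation_dist_max)
                ang = rng.uniform(-math.pi, math.pi)
                mover_pos = centroid.pos + flight * np.array([math.cos(ang),
                                                              math.sin(ang)])
                other = [k for k in range(cfg.n_sites) if k != centroid.site_idx]
                mover_site = other[rng.integers(len(other))]
                # the mover lands the flight distance away this slot and only
                # then starts commuting to its new site; the partner stays put
                lone[mover] = _Walker(mover_pos, centroid.site_idx, cfg, rng)
                lone[mover].begin_travel(mover_site)
                lone[partner] = _Walker(centroid.pos
                                        + rng.normal(0, cfg.within_pair_sd, 2),
                                        centroid.site_idx, cfg, rng)
                fresh = {mover, partner}
                male_nest = pair_nest and partner == "M"
                pair_nest = False
                last_mover = mover
                seps.append((s, mover, flight))
            elif not together and rng.random() < p_at:
                together = True
                stayer = "M" if last_mover == "F" else "F"
                centroid = _Walker(lone[stayer].pos, lone[stayer].site_idx,
                                   cfg, rng)
                pair_nest = male_nest and stayer == "M"
                male_nest = False
                lone = {"M": None, "F": None}

        # nest attendance: persistent visit bouts whose entry/exit rates
        # keep the configured daily occupancy while limiting transitions
        p_pair_nest, p_m_alone, p_f_alone = attend[di]
        at_nest = {"M": False, "F": False}
        if day_rel[s] >= onset:
            c_rate = cfg.nest_bout_rate
            if together:
                if pair_nest:
                    if rng.random() < (1.0 - p_pair_nest) * c_rate:
                        pair_nest = False
                        centroid.begin_travel(centroid.site_idx)
                elif rng.random() < p_pair_nest * c_rate:
                    pair_nest = True
                at_nest["M"] = at_nest["F"] = pair_nest
            else:
                if male_nest:
                    if rng.random() < (1.0 - p_m_alone) * c_rate:
                        male_nest = False
                        lone["M"].begin_travel(lone["M"].site_idx)
                elif rng.random() < p_m_alone * c_rate:
                    male_nest = True
                at_nest["M"] = male_nest
                # the female only checks the nest when the male is not
                # sitting on it (two birds on the nest would be "together")
                at_nest["F"] = (rng.random() < p_f_alone) and not male_nest
        else:
            pair_nest = male_nest = False

        # movement and emitted true positions
        if together:
            if at_nest["M"]:
                centroid.pos = nest.copy()
                c = nest
            else:
                c = centroid.step(sites, cfg.step_speed_together, cfg, rng,
                                  cfg.site_switch_prob_together,
                                  teleport_switch=False)
            for sex in ("M", "F"):
                sd = cfg.nest_scatter_sd if at_nest[sex] else cfg.within_pair_sd
                pos[sex][s] = c + rng.normal(0.0, sd, size=2)
        else:
            for sex in ("M", "F"):
                if at_nest[sex]:
                    lone[sex].pos = nest.copy()
                    pos[sex][s] = nest + rng.normal(0.0, cfg.nest_scatter_sd,
                                                    size=2)
                else:
                    # non-attending birds avoid the nest's surroundings, so
                    # truth "apart" stays consistent with the proximity
                    # criterion when the partner is sitting on the nest
                    if sex in fresh:
                        nxt = lone[sex].pos.copy()
                    else:
                        nxt = lone[sex].step(sites, cfg.step_speed_apart, cfg,
                                             rng, cfg.site_switch_prob,
                                             teleport_switch=True)
                    d_nest = np.hypot(*(nxt - nest))
                    if d_nest < cfg.nest_avoidance_m:
                        nxt = nest + (nxt - nest) / max(d_nest, 1e-9) \
                            * cfg.nest_avoidance_m
                        lone[sex].pos = nxt
                    pos[sex][s] = nxt

        truth_tog[s] = together
        truth_nest["M"][s] = at_nest["M"]
        truth_nest["F"][s] = at_nest["F"]

    return {"pos": pos, "together": truth_tog, "at_nest": truth_nest,
            "day_rel": day_rel, "seps": seps, "nest_xy": nest,
            "clutch_init": clutch_init, "onset": onset}


def _plant_outliers(xy, cfg, rng):
    """Corrupt positions in place; returns (slot index, rule) pairs.
    Corruptions are isolated (>= 3 slots apart) and chosen so each rule,
    and only that rule given the filter order, removes them."""
    n = len(xy)
    taken = np.zeros(n, dtype=bool)
    out = []

    def reserve(i):
        lo, hi = max(0, i - 3), min(n, i + 4)
        if taken[lo:hi].any():
            return False
        taken[lo:hi] = True
        return True

    for rule, rate in cfg.outlier_rates.items():
        if rate <= 0:
            continue
        n_corrupt = rng.binomial(n, rate)
        candidates = rng.permutation(np.arange(2, n - 2))
        placed = 0
        for i in candidates:
            if placed >= n_corrupt:
                break
            if rule == "single_outlier":
                if np.hypot(*(xy[i + 1] - xy[i - 1])) > 60.0:
                    continue
            if not reserve(i):
                continue
            ang = rng.uniform(-math.pi, math.pi)
            u = np.array([math.cos(ang), math.sin(ang)])
            if rule == "far":
                xy[i] = xy[i] + 600_000.0 * u
            elif rule == "speed":
                xy[i] = xy[i] + 25_000.0 * u
            else:
                xy[i] = xy[i] + 3_000.0 * u
            out.append((i, rule))
            placed += 1
    return out


def simulate_pair_tracks(config: SimConfig):
    """Simulate the full season.

    Returns ``(fixes, nests, truth)``: a long fix table (individual_id, sex,
    pair_id, timestamp UTC, lon, lat), a nest table and a :class:`TruthLog`.
    Bit-identical for identical config + seed.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    proj = LocalProjection(*cfg.site_lonlat)

    sites = [rng.uniform(-cfg.area_half_width, cfg.area_half_width, size=2)
             for _ in range(cfg.n_sites)]

    season_start = pd.Timestamp(cfg.season_start)
    if cfg.clutch_init_dates is not None:
        inits = [pd.Timestamp(d) for d in cfg.clutch_init_dates]
        if len(inits) != cfg.n_pairs:
            raise ValueError("clutch_init_dates must list one date per pair")
    else:
        offsets = np.round(rng.normal(10.0, cfg.clutch_date_sd, cfg.n_pairs))
        inits = [season_start + pd.Timedelta(days=int(o)) for o in offsets]

    fix_rows = []
    slot_rows = []
    sep_rows = []
    corrupt_rows = []
    nest_rows = []

    for p in range(cfg.n_pairs):
        pair_id = f"P{p:03d}"
        male_id, female_id = f"M{p:03d}", f"F{p:03d}"
        sim = _simulate_pair(p, cfg, inits[p], sites, rng)
        n_slots = len(sim["together"])

        # nominal slot times: local midnight of each day_rel, UTC storage
        local_midnight = (inits[p] + pd.to_timedelta(sim["day_rel"], unit="D"))
        minutes = np.tile(np.arange(SLOTS_PER_DAY) * cfg.fix_interval_min,
                          n_slots // SLOTS_PER_DAY)
        slot_utc = (local_midnight + pd.to_timedelta(minutes, unit="m")
                    - pd.Timedelta(hours=LOCAL_UTC_OFFSET_H))

        # the two tags run on independent schedules whose phase lag sets the
        # pairing-gap distribution; lag stays clear of 0 and of the half
        # interval so the median is the configured mean
        lag = float(np.clip(rng.normal(cfg.pair_lag_mean_min,
                                       cfg.pair_lag_sd_min),
                            0.3, cfg.fix_interval_min / 2.0 - 0.3))
        base = rng.uniform(0.0, cfg.fix_interval_min)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        offsets = {"M": base, "F": base + sign * lag}
        # long displacements are flights completed in well under a slot;
        # render them as a step at one shared random instant per segment
        # rather than a 10-minute glide
        tau = rng.uniform(size=n_slots)
        for sex, ind in (("M", male_id), ("F", female_id)):
            jitter = rng.uniform(-cfg.fix_jitter_min, cfg.fix_jitter_min,
                                 size=n_slots)
            # sample the continuous path at the member's actual fix times,
            # so asynchronous schedules see genuine movement-during-gap
            t_min = offsets[sex] + jitter + cfg.fix_interval_min * np.arange(n_slots)
            u = np.clip(t_min / cfg.fix_interval_min, 0.0, n_slots - 1.0)
            f = np.floor(u).astype(int)
            w = (u - f)[:, None]
            path = sim["pos"][sex]
            nxt = np.minimum(f + 1, n_slots - 1)
            seg_len = np.hypot(path[nxt][:, 0] - path[f][:, 0],
                               path[nxt][:, 1] - path[f][:, 1])
            glide = (1.0 - w) * path[f] + w * path[nxt]
            stepped = np.where(w < tau[f][:, None], path[f], path[nxt])
            xy = np.where((seg_len > cfg.flight_render_threshold)[:, None],
                          stepped, glide)
            corruptions = _plant_outliers(xy, cfg, rng)
            xy = xy + rng.normal(0.0, cfg.gps_noise_sd, size=xy.shape)
            times = slot_utc + pd.to_timedelta(t_min - cfg.fix_interval_min
                                               * np.arange(n_slots), unit="m")
            lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
            fix_rows.append(pd.DataFrame({
                "individual_id": ind, "sex": sex, "pair_id": pair_id,
                "timestamp": pd.DatetimeIndex(times).round("s"),
                "lon": lon, "lat": lat,
            }))
            for i, rule in corruptions:
                corrupt_rows.append({"individual_id": ind,
                                     "timestamp": fix_rows[-1]["timestamp"].iloc[i],
                                     "rule": rule})

        slot_rows.append(pd.DataFrame({
            "pair_id": pair_id,
            "slot_time": pd.DatetimeIndex(slot_utc),
            "day_rel": sim["day_rel"],
            "together": sim["together"],
            "at_nest_male": sim["at_nest"]["M"],
            "at_nest_female": sim["at_nest"]["F"],
        }))
        for s, mover, flight in sim["seps"]:
            sep_rows.append({"pair_id": pair_id,
                             "slot_time": slot_utc[s],
                             "day_rel": int(sim["day_rel"][s]),
                             "mover": mover,
                             "flight_distance": flight})
        nlon, nlat = proj.inverse(*sim["nest_xy"])
        nest_rows.append({
            "nest_id": f"N{p:03d}", "pair_id": pair_id,
            "male_id": male_id, "female_id": female_id,
            "lon": float(nlon), "lat": float(nlat),
            "clutch_init_date": inits[p].date(),
            "clutch_number": 1, "n_eggs": 4,
            "epp": bool(rng.random() < cfg.epp_rate),
            "nest_onset_day": sim["onset"],
        })

    fixes = pd.concat(fix_rows, ignore_index=True)
    nests = pd.DataFrame(nest_rows)
    truth = TruthLog(
        slots=pd.concat(slot_rows, ignore_index=True),
        separations=pd.DataFrame(
            sep_rows, columns=["pair_id", "slot_time", "day_rel", "mover",
                               "flight_distance"]),
        corrupted=pd.DataFrame(
            corrupt_rows, columns=["individual_id", "timestamp", "rule"]),
    )
    return fixes, nests, truth


# --------------------------------------------------------------------------
# hand-built miniature fixtures with frozen expected output

_TOY_NAMES = ("single-outlier", "last-fix-separation", "all-close",
              "three-rule-together")


def make_toy_fixture(name: str):
    """Tiny hand-constructed inputs plus the exact expected classifier
    output, for frozen regression tests.  See ``_TOY_NAMES``."""
    proj = LocalProjection()
    t0 = pd.Timestamp("2019-06-10 12:00:00")

    def fixes(ind, sex, xy_t):
        lon, lat = proj.inverse(np.array([p[0] for p in xy_t]),
                                np.array([p[1] for p in xy_t]))
        return pd.DataFrame({
            "individual_id": ind, "sex": sex,
            "timestamp": [t0 + pd.Timedelta(minutes=p[2]) for p in xy_t],
            "lon": lon, "lat": lat})

    if name == "single-outlier":
        # B sits 3 km off while its neighbours are 50 m apart
        track = fixes("X1", "M", [(0.0, 0.0, 0), (3000.0, 0.0, 10),
                                  (50.0, 0.0, 20)])
        return {"fixes": track, "expected_removed_timestamps":
                [t0 + pd.Timedelta(minutes=10)]}
    if name == "last-fix-separation":
        male = fixes("X1", "M", [(0, 0, 0), (5, 0, 10), (0, 0, 20)])
        female = fixes("X2", "F", [(8, 0, 0), (10, 0, 10), (80, 0, 20)])
        return {"fixes_male": male, "fixes_female": female,
                "expected_together": [True, True, False]}
    if name == "all-close":
        male = fixes("X1", "M", [(0, 0, i * 10) for i in range(4)])
        female = fixes("X2", "F", [(5, 0, i * 10) for i in range(4)])
        return {"fixes_male": male, "fixes_female": female,
                "expected_together": [True, True, True, True]}
    if name == "three-rule-together":
        # passes the dynamic threshold at large gaps but never dips below
        # the fixed 30 m threshold -> the whole bout is rejected
        male = fixes("X1", "M", [(0, 0, 0), (0, 0, 10)])
        female = fixes("X2", "F", [(40, 0, 5), (45, 0, 15)])
        return {"fixes_male": male, "fixes_female": female,
                "expected_together": [False, False]}
    raise ValueError(f"unknown fixture {name!r}; choose from {_TOY_NAMES}")
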