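"""Plausibility-filter unit, property and planted-corruption tests."""

import numpy as np
import pandas as pd
import pytest

from pairguard.filtering import (DataError, FilterParams, FilterReport,
                                 clip_to_deployment, filter_dataset,
                                 filter_far, filter_single_outlier,
                                 filter_speed, run_filters)
from pairguard.geo import DEFAULT_SITE, LocalProjection
from pairguard.synthetic import make_toy_fixture


def _track(xy_minutes, start="2019-06-10 12:00:00"):
    proj = LocalProjection()
    t0 = pd.Timestamp(start)
    lon, lat = proj.inverse(np.array([p[0] for p in xy_minutes], dtype=float),
                            np.array([p[1] for p in xy_minutes], dtype=float))
    return pd.DataFrame({
        "individual_id": "X1", "sex": "M",
        "timestamp": [t0 + pd.Timedelta(minutes=p[2]) for p in xy_minutes],
        "lon": lon, "lat": lat})


def test_far_filter_threshold_is_strict():
    # 499.9 km stays, 500.1 km goes (threshold 500 km, strict '>')
    track = _track([(0, 0, 0), (499_900, 0, 10), (500_100, 0, 20)])
    kept, removed = filter_far(track, DEFAULT_SITE)
    assert len(removed) == 1
    assert kept["timestamp"].iloc[-1] == track["timestamp"].iloc[1]


def test_speed_filter_drops_later_fix_of_fast_leg():
    # 20 km in 10 min = 120 km/h > 105 -> second fix dropped; the third is
    # re-checked against the first retained fix
    track = _track([(0, 0, 0), (20_000, 0, 10), (100, 0, 20)])
    kept, removed = filter_speed(track)
    assert list(removed) == [1]
    assert len(kept) == 2


def test_single_outlier_rule_toy():
    toy = make_toy_fixture("single-outlier")
    kept, removed = filter_single_outlier(toy["fixes"])
    assert list(kept["timestamp"]) == [
        t for t in toy["fixes"]["timestamp"]
        if t not in toy["expected_removed_timestamps"]]


def test_single_outlier_requires_close_neighbors():
    # same jumps, but A and C are 5 km apart -> not an isolated outlier
    track = _track([(0, 0, 0), (3000, 4000, 10), (5000, 0, 20)])
    kept, removed = filter_single_outlier(track)
    assert len(removed) == 0


def test_clip_to_deployment_closed_interval():
    track = _track([(0, 0, 0), (0, 0, 10), (0, 0, 20)])
    t0 = track["timestamp"].iloc[0]
    clipped = clip_to_deployment(track, t0, t0 + pd.Timedelta(minutes=10))
    assert len(clipped) == 2
    with pytest.raises(ValueError):
        clip_to_deployment(track, t0 + pd.Timedelta(minutes=1), t0)


def test_duplicate_timestamps_raise():
    track = _track([(0, 0, 0), (10, 0, 0)])
    with pytest.raises(DataError):
        filter_speed(track)


def test_params_must_be_positive():
    with pytest.raises(ValueError):
        FilterParams(max_speed=0.0)


def test_report_addition_and_retained():
    a = FilterReport(100, 1, 2, 3)
    b = FilterReport(50, 0, 1, 0)
    tot = a + b
    assert tot.n_input == 150
    assert tot.n_retained == 150 - 1 - 2 - 3 - 1


def test_conservation_and_idempotence(sim_corrupted):
    cfg, fixes, nests, truth = sim_corrupted
    captures = pd.DataFrame({"individual_id": fixes["individual_id"].unique()})
    captures["lon"], captures["lat"] = cfg.site_lonlat
    kept, report, per_ind = filter_dataset(fixes, captures)
    # conservation: every input fix is either retained or counted removed
    assert report.n_input == len(fixes)
    assert report.n_retained == len(kept)
    assert (report.n_input - report.removed_far - report.removed_speed
            - report.removed_single_outlier) == len(kept)
    assert sum(r.n_input for r in per_ind.values()) == report.n_input
    # idempotence: a second pass removes nothing
    kept2, report2, _ = filter_dataset(kept, captures)
    assert len(kept2) == len(kept)
    assert report2.n_retained == report2.n_input


def test_planted_corruptions_recovered_exactly(sim_corrupted):
    cfg, fixes, nests, truth = sim_corrupted
    assert len(truth.corrupted) > 0
    captures = pd.DataFrame({"individual_id": fixes["individual_id"].unique()})
    captures["lon"], captures["lat"] = cfg.site_lonlat
    kept, report, _ = filter_dataset(fixes, captures)
    kept_keys = set(zip(kept["individual_id"], kept["timestamp"]))
    planted = set(zip(truth.corrupted["individual_id"],
                      pd.to_datetime(truth.corrupted["timestamp"])))
    # recall: every planted corruption removed
    assert not (planted & kept_keys)
    # precision: nothing else removed
    n_removed = (report.removed_far + report.removed_speed
                 + report.removed_single_outlier)
    assert n_removed == len(planted)
    # per-rule attribution matches the planted rule
    rule_counts = truth.corrupted["rule"].value_counts().to_dict()
    assert report.removed_far == rule_counts.get("far", 0)
    assert report.removed_speed == rule_counts.get("speed", 0)
    assert report.removed_single_outlier == rule_counts.get("single_outlier", 0)
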