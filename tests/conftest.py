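"""Shared fixtures: one small simulated season reused across test modules."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from pairguard.pipeline import breeding_pair_tables
from pairguard.synthetic import SimConfig, simulate_pair_tracks


@pytest.fixture(scope="session")
def sim_small():
    """Six simulated pairs under default (study-like) conditions."""
    cfg = SimConfig(n_pairs=6, rng_seed=0)
    fixes, nests, truth = simulate_pair_tracks(cfg)
    return cfg, fixes, nests, truth


@pytest.fixture(scope="session")
def sim_tables(sim_small):
    """Breeding-pair tables (labeled, daily, events, attendance, visits)."""
    _, fixes, nests, _ = sim_small
    labeled, daily, events, attendance, first_visits = breeding_pair_tables(
        fixes, nests)
    return {"labeled": labeled, "daily": daily, "events": events,
            "attendance": attendance, "first_visits": first_visits}


@pytest.fixture(scope="session")
def sim_corrupted():
    """Four pairs with planted filter-rule violations."""
    cfg = dataclasses.replace(
        SimConfig(n_pairs=4, rng_seed=3),
        outlier_rates={"far": 0.002, "speed": 0.002, "single_outlier": 0.002})
    fixes, nests, truth = simulate_pair_tracks(cfg)
    return cfg, fixes, nests, truth


def make_labeled(together, minutes_apart=10):
    """Minimal classify_together-shaped frame from a boolean label list."""
    t0 = pd.Timestamp("2019-06-10 00:00:00")
    n = len(together)
    return pd.DataFrame({
        "slot_time": [t0 + pd.Timedelta(minutes=minutes_apart * i)
                      for i in range(n)],
        "together": list(together),
        "x_a": [0.0] * n, "y_a": [0.0] * n,
        "x_b": [0.0] * n, "y_b": [0.0] * n,
    })
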