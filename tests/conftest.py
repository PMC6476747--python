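import numpy as np
import pandas as pd
import pytest

from flocknet.events import ForagingEvent, GroupByIndividualMatrix, build_gbi


def make_event(site="S1", day=0, members_arrivals=None, start=None, end=None):
    """ForagingEvent from a {tag: first_arrival} mapping."""
    members_arrivals = members_arrivals or {"a": 100.0}
    arrivals = list(members_arrivals.values())
    start = min(arrivals) if start is None else start
    end = max(arrivals) + 10 if end is None else end
    return ForagingEvent(
        site_id=site,
        day=day,
        start_s=float(start),
        end_s=float(end),
        members=frozenset(members_arrivals),
        first_arrival=dict(members_arrivals),
    )


def make_gbi(matrix, days=None, individuals=None, site="S1", week=0):
    matrix = np.asarray(matrix, dtype=np.int8)
    n_ev, n_ind = matrix.shape
    if individuals is None:
        individuals = tuple(chr(ord("a") + j) for j in range(n_ind))
    if days is None:
        days = np.zeros(n_ev, dtype=int)
    return GroupByIndividualMatrix(
        matrix=matrix,
        individuals=tuple(individuals),
        days=np.asarray(days),
        site_id=site,
        week_id=week,
    )


def random_gbi(rng, n_ind=None, n_ev=None, n_days=2):
    """Random GBI with no all-zero rows; may have zero-occurrence columns."""
    n_ind = n_ind or int(rng.integers(3, 9))
    n_ev = n_ev or int(rng.integers(3, 21))
    m = (rng.random((n_ev, n_ind)) < rng.uniform(0.2, 0.7)).astype(np.int8)
    for r in range(n_ev):
        if not m[r].any():
            m[r, rng.integers(n_ind)] = 1
    days = rng.integers(0, n_days, size=n_ev)
    return make_gbi(m, days=days)


def truth_weekly_gbis(truth, site, days_per_week):
    """Weekly GBIs straight from ground-truth membership (skips detection)."""
    mem = truth.membership[truth.membership["site_id"] == site]
    tags = sorted(truth.ranks[truth.ranks["site_id"] == site]["tag_id"].unique())
    out = []
    for week, grp in mem.groupby(mem["day"] // days_per_week, sort=True):
        events = []
        for (day, e), evgrp in grp.groupby(["day", "event_idx"], sort=True):
            first = dict(zip(evgrp["tag_id"], evgrp["first_arrival_s"].astype(float)))
            events.append(
                ForagingEvent(
                    site_id=site,
                    day=int(day),
                    start_s=min(first.values()),
                    end_s=max(first.values()) + 1,
                    members=frozenset(first),
                    first_arrival=first,
                )
            )
        gbi = build_gbi(events, tags, site_id=site, week_id=int(week))
        if gbi.n_events:
            out.append(gbi)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_visits():
    """Three birds, one site, one day, two clear bursts."""
    rows = [
        ("S1", "a", 100, 110),
        ("S1", "b", 110, 125),
        ("S1", "a", 120, 130),
        ("S1", "b", 5000, 5009),
        ("S1", "c", 5010, 5020),
    ]
    return pd.DataFrame(rows, columns=["site_id", "tag_id", "arrival_s", "departure_s"])
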