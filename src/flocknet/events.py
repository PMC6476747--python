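"""Segmentation of a site-day visit stream into foraging events.

A one-dimensional Gaussian mixture is fitted to the arrival timestamps with
the number of components chosen by minimum BIC; visits are hard-assigned to
their maximum-responsibility component and components whose assigned time
ranges overlap are merged.  Days with very few visits fall back to a simple
gap rule.  Also houses the week-level inclusion filters and the
group-by-individual (GBI) incidence matrix.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .synthetic import SECONDS_PER_DAY

__all__ = [
    "ForagingEvent",
    "GroupByIndividualMatrix",
    "detect_events",
    "apply_inclusion_filters",
    "build_gbi",
    "day_of",
    "week_of",
]


def day_of(arrival_s) -> np.ndarray:
    """Calendar day index of a timestamp (integer division by 86400)."""
    return np.asarray(arrival_s) // SECONDS_PER_DAY


def week_of(day, days_per_week: int) -> np.ndarray:
    return np.asarray(day) // days_per_week


@dataclass(frozen=True)
class ForagingEvent:
    """A detected burst of visits at one site on one day."""

    site_id: str
    day: int
    start_s: float  # earliest member arrival
    end_s: float  # latest member departure
    members: frozenset
    first_arrival: dict

    def __post_init__(self):
        if self.end_s < self.start_s:
            raise ValueError("event end precedes start")
        if not self.members:
            raise ValueError("event with no members")
        if set(self.first_arrival) != set(self.members):
            raise ValueError("first_arrival keys must equal members")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _day_seed(seed: int, site_id: str, day: int) -> int:
    """Stable per-day RNG seed derived from (global seed, site, day)."""
    h = zlib.crc32(f"{site_id}:{day}".encode())
    return int(np.random.SeedSequence([seed & 0xFFFFFFFF, h, day & 0xFFFFFFFF]).generate_state(1)[0])


def _gap_split(order: np.ndarray, t: np.ndarray, bridge_s: float) -> np.ndarray:
    """Fallback labelling: new event whenever the arrival gap exceeds bridge_s."""
    labels = np.zeros(t.size, dtype=int)
    labels[1:] = np.cumsum(np.diff(t) > bridge_s)
    out = np.empty_like(labels)
    out[order] = labels
    return out


def detect_events(
    visits: pd.DataFrame,
    max_components: int = 15,
    seed: int = 0,
    bridge_s: float = 600.0,
    min_gmm_visits: int = 3,
    reg_covar_s2: float = 900.0,
    return_labels: bool = False,
):
    """Segment one site-day of visits into foraging events.

    Parameters
    ----------
    visits : DataFrame
        Columns ``site_id, tag_id, arrival_s, departure_s``; all rows must
        share one site and one calendar day.
    max_components : int
        Upper bound on the number of mixture components; the fitted K is
        chosen by minimum BIC over ``1..min(max_components, n_visits)``.
    seed : int
        Global seed; the per-day EM seed is derived from (seed, site, day).
    bridge_s : float
        Gap threshold of the small-n fallback (fewer than ``min_gmm_visits``
        visits skip the GMM and split on gaps larger than this).
    reg_covar_s2 : float
        Variance floor (seconds squared) of the mixture components — the
        smallest burst spread the model may resolve.  Too small a floor lets
        BIC shatter one burst into per-visit micro-clusters; the default
        corresponds to a 30 s within-burst standard deviation.
    return_labels : bool
        Also return the per-visit event index (row-aligned with ``visits``).

    Returns
    -------
    list of ForagingEvent, ordered by start time (plus labels if requested).
    """
    if len(visits) == 0:
        return ([], np.empty(0, dtype=int)) if return_labels else []
    arr = visits["arrival_s"].to_numpy(dtype=float)
    dep = visits["departure_s"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(arr)) and np.all(np.isfinite(dep))):
        raise ValueError("non-finite timestamp in visit stream")
    sites = visits["site_id"].unique()
    if len(sites) != 1:
        raise ValueError("detect_events expects a single site per call")
    days = np.unique(day_of(arr.astype(np.int64)))
    if len(days) != 1:
        raise ValueError("detect_events expects a single calendar day per call")
    site_id, day = str(sites[0]), int(days[0])

    n = arr.size
    order = np.argsort(arr, kind="mergesort")
    t_sorted = arr[order]
    if n < min_gmm_visits:
        labels = _gap_split(order, t_sorted, bridge_s)
    else:
        # centre on the earliest arrival so detection is exactly invariant to
        # a constant shift of all timestamps
        x = (arr - t_sorted[0]).reshape(-1, 1)
        k_max = min(max_components, len(np.unique(arr)))
        rs = _day_seed(seed, site_id, day)
        best_bic, best = np.inf, None
        since_improve = 0
        for k in range(1, k_max + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=5,
                init_params="k-means++",
                reg_covar=reg_covar_s2,
                random_state=rs,
            ).fit(x)
            bic = gm.bic(x)
            if bic < best_bic - 1e-9:
                best_bic, best = bic, gm
                since_improve = 0
            else:
                # BIC is near-convex in K here; stop after a stretch of
                # non-improvement instead of scanning all the way up
                since_improve += 1
                if since_improve >= 4:
                    break
        labels = best.predict(x)

    # assemble raw events, then merge any whose [start, end] spans overlap
    raw = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        raw.append(idx)
    raw.sort(key=lambda idx: arr[idx].min())
    merged: list[np.ndarray] = []
    for idx in raw:
        if merged and arr[idx].min() <= dep[merged[-1]].max():
            merged[-1] = np.concatenate([merged[-1], idx])
        else:
            merged.append(idx)

    events = []
    final_labels = np.empty(n, dtype=int)
    for e, idx in enumerate(merged):
        final_labels[idx] = e
        tags = visits["tag_id"].to_numpy()[idx]
        first = {}
        for tag, a in zip(tags, arr[idx]):
            if tag not in first or a < first[tag]:
                first[tag] = float(a)
        events.append(
            ForagingEvent(
                site_id=site_id,
                day=day,
                start_s=float(arr[idx].min()),
                end_s=float(dep[idx].max()),
                members=frozenset(first),
                first_arrival=first,
            )
        )
    if return_labels:
        return events, final_labels
    return events


def apply_inclusion_filters(
    visits: pd.DataFrame,
    days_per_week: int,
    min_weeks: int = 5,
    min_weekly_records: int = 5,
    strict: bool = True,
):
    """Weekly-presence and minimum-weeks filters on the visit stream.

    An individual is *present* in a week iff its visit count that week is
    strictly greater than ``min_weekly_records`` (``>=`` when ``strict`` is
    False).  Individuals present in fewer than ``min_weeks`` weeks are dropped
    from all downstream matrices.

    Returns
    -------
    (roster, presence) : (DataFrame ``site_id, tag_id``,
                          DataFrame ``site_id, tag_id, week, n_records, present``)
    """
    if len(visits) == 0:
        empty = pd.DataFrame(columns=["site_id", "tag_id"])
        pres = pd.DataFrame(columns=["site_id", "tag_id", "week", "n_records", "present"])
        return empty, pres
    v = visits.copy()
    v["week"] = week_of(day_of(v["arrival_s"].to_numpy()), days_per_week)
    counts = (
        v.groupby(["site_id", "tag_id", "week"], sort=True)
        .size()
        .rename("n_records")
        .reset_index()
    )
    if strict:
        counts["present"] = counts["n_records"] > min_weekly_records
    else:
        counts["present"] = counts["n_records"] >= min_weekly_records
    weeks_present = (
        counts[counts["present"]]
        .groupby(["site_id", "tag_id"], sort=True)
        .size()
        .rename("n_weeks_present")
        .reset_index()
    )
    roster = (
        weeks_present[weeks_present["n_weeks_present"] >= min_weeks][["site_id", "tag_id"]]
        .sort_values(["site_id", "tag_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return roster, counts


@dataclass
class GroupByIndividualMatrix:
    """Binary events-by-individuals incidence for one site-week.

    Columns follow ``individuals`` (sorted, fixed); each row carries the
    calendar-day label of its event (needed by the same-day permutation
    constraint).  Rows emptied by roster restriction are dropped at build
    time, so no all-zero rows exist.
    """

    matrix: np.ndarray  # (n_events, n_individuals) of 0/1, int8
    individuals: tuple
    days: np.ndarray  # (n_events,) calendar day per row
    site_id: str
    week_id: int

    def __post_init__(self):
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.int8)
        self.days = np.asarray(self.days, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("GBI matrix must be 2-D")
        if self.matrix.shape[0] != self.days.size:
            raise ValueError("one day label required per event row")
        if self.matrix.shape[1] != len(self.individuals):
            raise ValueError("column count must match individuals")
        if self.matrix.shape[0] and not self.matrix.any(axis=1).all():
            raise ValueError("GBI contains an all-zero event row")

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    def copy(self) -> "GroupByIndividualMatrix":
        return GroupByIndividualMatrix(
            matrix=self.matrix.copy(),
            individuals=tuple(self.individuals),
            days=self.days.copy(),
            site_id=self.site_id,
            week_id=self.week_id,
        )


def build_gbi(events, roster, site_id=None, week_id=0) -> GroupByIndividualMatrix:
    """Group-by-individual matrix for one site-week of events.

    ``roster`` is the iterable of individuals retained by the inclusion
    filters; events with no roster member are dropped.
    """
    individuals = tuple(sorted(set(roster)))
    if not individuals:
        raise ValueError("roster must be nonempty")
    col = {tag: j for j, tag in enumerate(individuals)}
    rows, days = [], []
    for ev in sorted(events, key=lambda ev: (ev.day, ev.start_s)):
        row = np.zeros(len(individuals), dtype=np.int8)
        hit = False
        for tag in ev.members:
            j = col.get(tag)
            if j is not None:
                row[j] = 1
                hit = True
        if hit:
            rows.append(row)
            days.append(ev.day)
        if site_id is None:
            site_id = ev.site_id
    matrix = np.asarray(rows, dtype=np.int8) if rows else np.zeros((0, len(individuals)), np.int8)
    return GroupByIndividualMatrix(
        matrix=matrix,
        individuals=individuals,
        days=np.asarray(days, dtype=np.int64),
        site_id=str(site_id),
        week_id=int(week_id),
    )
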