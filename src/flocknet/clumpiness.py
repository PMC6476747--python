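"""Entropy-based temporal clumpiness of point and span processes within a day.

The statistic works on the vector of interval lengths that partition a fixed
observation window.  Intervals are normalised to proportions ``p_i`` and the
(negative) entropy ``H_p = sum_i p_i * log(p_i)`` is rescaled by its lower
bound ``-log(n + 1)`` so that 0 means perfectly even spacing and 1 means all
mass concentrated in a single interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "raw_entropy",
    "rescaled_clumpiness",
    "clumpiness_of_arrivals",
    "clumpiness_of_events",
    "rescale_empirical",
    "DailySummary",
    "summarize_day",
]


def raw_entropy(x: Sequence[float]) -> float:
    """Entropy ``sum p_i log p_i`` of an interval-length vector.

    Parameters
    ----------
    x : sequence of float
        Nonnegative interval lengths (any time unit); they are normalised to
        proportions internally, so the result is scale invariant.

    Returns
    -------
    float
        ``sum_i p_i * log(p_i)`` with the convention ``0 * log 0 == 0``
        (natural log).  Always in ``[-log(len(x)), 0]``.  ``nan`` (with a
        warning) if the intervals sum to zero.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("raw_entropy: empty interval vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("raw_entropy: non-finite interval length")
    if np.any(x < 0):
        raise ValueError("raw_entropy: negative interval length")
    total = x.sum()
    if total <= 0:
        warnings.warn("raw_entropy: all intervals are zero; entropy undefined")
        return float("nan")
    p = x / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz])))


def rescaled_clumpiness(h_p: float, n: int) -> float:
    """Map a raw entropy onto [0, 1].

    ``n`` is the number of inter-item intervals, so the interval vector has
    ``n + 1`` entries and ``h_p`` is bounded below by ``-log(n + 1)``.
    Returns ``1 + h_p / log(n + 1)``: 0 for equal spacing, 1 for a point mass.
    """
    if not np.isfinite(h_p):
        return float("nan")
    if n < 1:
        warnings.warn("rescaled_clumpiness: n < 1, undefined")
        return float("nan")
    return float(1.0 + h_p / np.log(n + 1))


def _point_intervals(points: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Interval vector for sorted points inside a window (k points -> k+1)."""
    w0, w1 = window
    pts = np.clip(np.sort(np.asarray(points, dtype=float)), w0, w1)
    return np.diff(np.concatenate([[w0], pts, [w1]]))


def clumpiness_of_arrivals(events: Iterable, day_window: tuple[float, float]) -> float:
    """Clumpiness of every individual's first arrival to every event in a day.

    Each (individual, event) pair contributes one time point — the
    individual's first arrival to that event.  Points are sorted and the
    intervals between consecutive points, plus the two boundary intervals to
    the window edges, are fed to :func:`raw_entropy`; the result is rescaled
    with ``n = number of points``.

    Returns ``nan`` (with a warning) if there are no arrivals.
    """
    w0, w1 = day_window
    if not w1 > w0:
        raise ValueError("day_window must satisfy start < end")
    points = []
    for ev in events:
        points.extend(ev.first_arrival.values())
    if len(points) == 0:
        warnings.warn("clumpiness_of_arrivals: no arrivals in day")
        return float("nan")
    x = _point_intervals(np.asarray(points), day_window)
    return rescaled_clumpiness(raw_entropy(x), n=len(points))


def clumpiness_of_events(events: Iterable, day_window: tuple[float, float]) -> float:
    """Clumpiness of whole foraging events (spans) within a day.

    The interval vector consists of the gaps: window start to the first event
    start, between consecutive events (previous end to next start), and last
    event end to window end.  Events straddling the window are clipped to it.
    Rescaled with ``n = number of events``.  Events covering the whole window
    (all gaps zero) give ``nan`` with a warning.
    """
    w0, w1 = day_window
    if not w1 > w0:
        raise ValueError("day_window must satisfy start < end")
    spans = sorted(
        (max(ev.start_s, w0), min(ev.end_s, w1)) for ev in events
    )
    spans = [(s, max(s, e)) for s, e in spans if s <= w1 and e >= w0]
    if len(spans) == 0:
        warnings.warn("clumpiness_of_events: no events in day")
        return float("nan")
    edges = [spans[0][0] - w0]
    for (s0, e0), (s1, e1) in zip(spans[:-1], spans[1:]):
        edges.append(max(0.0, s1 - e0))
    edges.append(w1 - spans[-1][1])
    gaps = np.asarray(edges, dtype=float)
    if gaps.sum() <= 0:
        warnings.warn("clumpiness_of_events: events fill the entire window")
        return float("nan")
    return rescaled_clumpiness(raw_entropy(gaps), n=len(spans))


def rescale_empirical(h_values: Sequence[float]) -> np.ndarray:
    """Alternative min-max rescaling of raw entropies across a set of days.

    Maps the finite values linearly so the least clumpy day is 0 and the most
    clumpy is 1.  Provided as an empirical alternative to the theoretical
    ``log(n + 1)`` bound; values are only comparable within the input set.
    """
    h = np.asarray(h_values, dtype=float)
    out = np.full_like(h, np.nan)
    finite = np.isfinite(h)
    if finite.sum() == 0:
        return out
    lo, hi = h[finite].min(), h[finite].max()
    if hi == lo:
        out[finite] = 0.0
    else:
        out[finite] = (h[finite] - lo) / (hi - lo)
    return out


@dataclass
class DailySummary:
    """Per-day group-foraging metrics for one site."""

    site_id: str
    day: int
    n_events: int
    n_visits: int
    clump_arrivals: float
    clump_events: float
    #: one (n_individuals, duration_s) pair per event, in start order
    event_rows: list = field(default_factory=list)


def summarize_day(events, visits, day_window, site_id=None, day=None) -> DailySummary:
    """Summarise one site-day: counts, clumpiness, per-event size/duration.

    ``events`` is a list of detected foraging events (possibly empty),
    ``visits`` the visit table (or list) used purely for the visit count.
    """
    events = sorted(events, key=lambda ev: ev.start_s)
    n_visits = len(visits)
    if events:
        site_id = site_id if site_id is not None else events[0].site_id
        day = day if day is not None else events[0].day
        clump_a = clumpiness_of_arrivals(events, day_window)
        clump_e = clumpiness_of_events(events, day_window)
    else:
        clump_a = float("nan")
        clump_e = float("nan")
    rows = [(len(ev.members), ev.end_s - ev.start_s) for ev in events]
    return DailySummary(
        site_id=str(site_id),
        day=int(day) if day is not None else -1,
        n_events=len(events),
        n_visits=int(n_visits),
        clump_arrivals=clump_a,
        clump_events=clump_e,
        event_rows=rows,
    )
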