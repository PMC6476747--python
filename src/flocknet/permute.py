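"""Margin-preserving data-stream permutations of GBI matrices.

A single swap exchanges two individuals between two grouping events recorded
on the same calendar day (a "checkerboard" move), preserving every row sum
(event size), every column sum (individual observation count) and the per-day
event structure.  Repeated swaps form a cumulative chain of increasingly
randomised matrices; snapshots taken every ``swaps_between_saves`` swaps form
the null ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import GroupByIndividualMatrix

__all__ = ["PermutationPlan", "single_swap", "null_ensemble", "same_day_event_pairs"]

_REJECTION_TRIES = 500


@dataclass
class PermutationPlan:
    """Chain layout: how many snapshots and how far apart."""

    n_networks: int = 1000
    swaps_between_saves: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_networks < 1 or self.swaps_between_saves < 1:
            raise ValueError("PermutationPlan counts must be > 0")


def same_day_event_pairs(days: np.ndarray) -> np.ndarray:
    """All unordered pairs of event rows sharing a day label, shape (m, 2)."""
    pairs = []
    days = np.asarray(days)
    for day in np.unique(days):
        idx = np.flatnonzero(days == day)
        if idx.size < 2:
            continue
        for i in range(idx.size):
            for j in range(i + 1, idx.size):
                pairs.append((idx[i], idx[j]))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def _is_checkerboard(m, e1, e2, a, b) -> bool:
    return (
        m[e1, a] == 1 and m[e2, a] == 0 and m[e1, b] == 0 and m[e2, b] == 1
    )


def _apply(m, e1, e2, a, b) -> None:
    m[e1, a] = 0
    m[e2, a] = 1
    m[e1, b] = 1
    m[e2, b] = 0


def single_swap(
    gbi: GroupByIndividualMatrix,
    rng: np.random.Generator,
    pairs: np.ndarray | None = None,
) -> bool:
    """Perform one checkerboard swap in place; returns True on success.

    The swap is drawn uniformly among all valid checkerboard quadruples
    (two same-day events, two individuals occurring in exactly one each, on
    opposite sides) via rejection sampling with an exhaustive fallback.  If no
    valid quadruple exists the matrix is left unchanged and False is returned.
    """
    m = gbi.matrix
    ncols = m.shape[1]
    if pairs is None:
        pairs = same_day_event_pairs(gbi.days)
    if pairs.shape[0] == 0 or ncols < 2:
        return False
    # rejection sampling: ordered (e1,e2) x ordered (a,b); each checkerboard
    # has exactly two ordered representations, so acceptance is uniform.
    # candidates come from one uniform block per batch to keep Generator
    # call overhead off the hot path
    batch = 16
    n_pairs = pairs.shape[0]
    plist = pairs.tolist()
    for _ in range(_REJECTION_TRIES // batch + 1):
        u = rng.random(4 * batch)
        for t in range(batch):
            e1, e2 = plist[int(u[4 * t] * n_pairs)]
            if u[4 * t + 1] < 0.5:
                e1, e2 = e2, e1
            a = int(u[4 * t + 2] * ncols)
            b = int(u[4 * t + 3] * (ncols - 1))
            if b >= a:
                b += 1
            if _is_checkerboard(m, e1, e2, a, b):
                _apply(m, e1, e2, a, b)
                return True
    # exhaustive fallback (tiny or nearly-frozen matrices)
    valid = []
    for e1, e2 in pairs:
        r1, r2 = m[e1], m[e2]
        only1 = np.flatnonzero((r1 == 1) & (r2 == 0))
        only2 = np.flatnonzero((r1 == 0) & (r2 == 1))
        for a in only1:
            for b in only2:
                valid.append((e1, e2, int(a), int(b)))
    if not valid:
        return False
    e1, e2, a, b = valid[rng.integers(len(valid))]
    _apply(m, e1, e2, a, b)
    return True


def null_ensemble(
    gbi: GroupByIndividualMatrix,
    plan: PermutationPlan,
    statistic,
) -> np.ndarray:
    """Cumulative swap chain with a statistic recorded at every checkpoint.

    ``statistic`` is called with the (randomised) GBI after every
    ``swaps_between_saves`` swaps; failures are recorded as ``nan`` with a
    warning.  Returns an array of ``n_networks`` values.  Seed-deterministic.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    work = gbi.copy()
    pairs = same_day_event_pairs(work.days)
    out: list = []
    n_failed = 0
    for _ in range(plan.n_networks):
        for _ in range(plan.swaps_between_saves):
            single_swap(work, rng, pairs)
        try:
            out.append(np.asarray(statistic(work), dtype=float))
        except Exception as exc:  # noqa: BLE001 - contract: record and continue
            out.append(None)
            n_failed += 1
            if n_failed == 1:
                warnings.warn(f"statistic failed on a randomized matrix: {exc}")
    shape = next((v.shape for v in out if v is not None), ())
    values = np.stack(
        [v if v is not None else np.full(shape, np.nan) for v in out]
    )
    if n_failed:
        warnings.warn(f"{n_failed}/{plan.n_networks} null statistics missing")
    return values
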