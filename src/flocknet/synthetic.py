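"""Synthetic RFID feeder-visit streams with known ground truth.

Every downstream stage (event detection, weekly networks, the consistency
test, clumpiness) has a parameter-recovery test against the ground truth
produced here.  The generator controls three axes directly:

* temporal clumpiness of event start times, via interval proportions drawn
  from a symmetric Dirichlet whose concentration is calibrated in closed form
  (digamma identity) to hit a target rescaled entropy;
* individual rank structure, via per-bird latent quality perturbed weekly by
  ``rank_noise_sd``.  Each event is seeded by a uniformly chosen focal bird
  and recruits attendees with probability decaying in latent-quality distance
  to the focal at a rate set by ``attendance_slope``, giving the networks
  quality-assorted co-occurrence structure that margin-preserving
  permutations destroy — a purely count-driven Bernoulli model would hand
  its entire rank signal to the permutation null and leave the consistency
  test without power (see ``_event_attendance``);
* burst tightness, via ``within_event_sd_s``.

Timestamps are integer seconds since an epoch midnight; day ``d`` occupies
``[d*86400, (d+1)*86400)`` and week ``w`` covers ``days_per_week`` consecutive
simulated days.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma
from scipy.stats import rankdata

SECONDS_PER_DAY = 86400

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_dataset",
    "write_stream",
    "read_stream",
    "dirichlet_alpha_for_clumpiness",
    "expected_rescaled_clumpiness",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study design.

    The defaults mirror the shape of the study system: eight sites in two
    habitat types, flocks of ~10 birds, 13 weeks of weekly sampling.  ``n_weeks``
    below 13 is permitted (useful for small tests) but 13+ matches the design.
    """

    n_sites_urban: int = 4
    n_sites_rural: int = 4
    birds_per_site: int = 10
    n_weeks: int = 13
    days_per_week: int = 3
    day_window: tuple = (21600, 64800)  # 06:00-18:00
    events_per_day_mean: float = 5.0
    event_spacing_clumpiness: float = 0.5
    event_duration_mean_s: float = 240.0
    within_event_sd_s: float = 45.0
    attendance_slope: float = 6.0
    attendance_base: float = 0.9
    rank_noise_sd: float = 0.3
    visits_per_attendance_mean: float = 2.0
    dwell_mean_s: float = 20.0
    seed: int = 0
    # habitat-level modifiers (urban relative to rural), exercised by the
    # model-selection stage; 1.0 / 0.0 disables them
    urban_duration_factor: float = 1.0
    urban_clumpiness_shift: float = 0.0

    def validate(self) -> None:
        w0, w1 = self.day_window
        if not w1 > w0:
            raise ValueError("day_window start must precede end")
        for name in (
            "n_sites_urban", "n_sites_rural", "n_weeks", "days_per_week",
        ):
            if getattr(self, name) < 1 and name not in ("n_sites_urban", "n_sites_rural"):
                raise ValueError(f"{name} must be >= 1")
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.birds_per_site < 0:
            raise ValueError("birds_per_site must be >= 0")
        for name in (
            "events_per_day_mean", "event_duration_mean_s", "within_event_sd_s",
            "visits_per_attendance_mean", "dwell_mean_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.event_spacing_clumpiness <= 1.0:
            raise ValueError("event_spacing_clumpiness must lie in [0, 1]")
        if self.rank_noise_sd < 0:
            raise ValueError("rank_noise_sd must be >= 0")
        if not 0.0 < self.attendance_base <= 1.0:
            raise ValueError("attendance_base must lie in (0, 1]")
        window = w1 - w0
        if self.events_per_day_mean * self.event_duration_mean_s >= window:
            raise ValueError(
                "day too short: events_per_day_mean * event_duration_mean_s "
                f"({self.events_per_day_mean * self.event_duration_mean_s:.0f} s) "
                f"must be below the day_window length ({window} s)"
            )


@dataclass
class GroundTruth:
    """True event schedule, membership and weekly latent ranks.

    ``events``:     site_id, day, event_idx, start_s, end_s
    ``membership``: site_id, day, event_idx, tag_id, first_arrival_s
    ``ranks``:      site_id, week, tag_id, rank (1 = most dominant)
    """

    events: pd.DataFrame
    membership: pd.DataFrame
    ranks: pd.DataFrame
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)


def expected_rescaled_clumpiness(alpha: float, k: int) -> float:
    """Expected rescaled entropy of a symmetric Dirichlet(alpha) with k parts.

    Uses ``E[sum p_i log p_i] = digamma(alpha + 1) - digamma(k*alpha + 1)``.
    Decreasing in alpha: -> 1 as alpha -> 0, -> 0 as alpha -> inf.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    return 1.0 + (digamma(alpha + 1.0) - digamma(k * alpha + 1.0)) / math.log(k)


@lru_cache(maxsize=4096)
def dirichlet_alpha_for_clumpiness(target: float, k: int) -> float:
    """Concentration whose expected rescaled clumpiness equals ``target``."""
    if not 0.0 <= target <= 1.0:
        raise ValueError("target clumpiness must lie in [0, 1]")
    lo, hi = 1e-8, 1e8
    if target <= expected_rescaled_clumpiness(hi, k):
        return hi
    if target >= expected_rescaled_clumpiness(lo, k):
        return lo
    return brentq(
        lambda a: expected_rescaled_clumpiness(a, k) - target, lo, hi, xtol=1e-12
    )


def _site_ids(config: SimConfig) -> list[tuple[str, str]]:
    sites = [(f"U{i + 1:02d}", "urban") for i in range(config.n_sites_urban)]
    sites += [(f"R{i + 1:02d}", "rural") for i in range(config.n_sites_rural)]
    return sites


def _event_attendance(
    q: np.ndarray, slope: float, base: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one event's attendee mask.

    A focal bird is chosen uniformly and always attends; every other bird
    joins independently with probability ``base * exp(-slope * |q_j - q_f|)``
    where ``q`` is the week's standardised latent quality.  With
    ``slope == 0`` every bird has identical attendance probability ``base``.

    The quality-proximity recruitment is deliberate: it stores the rank
    signal in *who co-occurs with whom* rather than in per-bird visit counts.
    Margin-preserving permutations conserve counts exactly, so a model whose
    rank signal is count-mediated hands that signal to the null and leaves
    the consistency test without power; proximity structure is destroyed by
    swaps, which is what gives observed networks their stability advantage.
    """
    b = q.size
    focal = int(rng.integers(b))
    p = base * np.exp(-slope * np.abs(q - q[focal]))
    attend = rng.random(b) < p
    attend[focal] = True
    return attend


def simulate_dataset(config: SimConfig):
    """Generate a visit stream and its ground truth.

    Returns ``(stream, truth)`` where ``stream`` is a DataFrame with columns
    ``site_id, tag_id, arrival_s, departure_s`` (integer seconds, sorted) and
    ``truth`` is a :class:`GroundTruth`.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w0, w1 = config.day_window
    window = float(w1 - w0)
    target = config.event_spacing_clumpiness

    visit_rows = []
    event_rows = []
    member_rows = []
    rank_rows = []
    site_rows = []

    for site_id, habitat in _site_ids(config):
        site_rows.append((site_id, habitat))
        b = config.birds_per_site
        tags = [f"{site_id}b{j + 1:02d}" for j in range(b)]
        base = rng.normal(0.0, 1.0, size=b)
        dur_mean = config.event_duration_mean_s * (
            config.urban_duration_factor if habitat == "urban" else 1.0
        )
        site_target = target + (
            config.urban_clumpiness_shift if habitat == "urban" else 0.0
        )
        site_target = min(1.0, max(0.0, site_target))

        weekly_quality = np.empty((config.n_weeks, b))
        for w in range(config.n_weeks):
            score = base + rng.normal(0.0, config.rank_noise_sd, size=b)
            sd = score.std()
            weekly_quality[w] = (score - score.mean()) / sd if b > 1 and sd > 0 else 0.0
            ranks = rankdata(-score, method="ordinal") if b else np.empty(0)
            for tag, r in zip(tags, ranks):
                rank_rows.append((site_id, w, tag, int(r)))

        for w in range(config.n_weeks):
            q = weekly_quality[w] if b else np.empty(0)
            for d in range(config.days_per_week):
                day = w * config.days_per_week + d
                day0 = day * SECONDS_PER_DAY
                n_ev = int(rng.poisson(config.events_per_day_mean))
                if n_ev == 0:
                    continue
                alpha = dirichlet_alpha_for_clumpiness(round(site_target, 9), n_ev + 1)
                props = rng.dirichlet(np.full(n_ev + 1, alpha))
                starts = day0 + w0 + window * np.cumsum(props)[:-1]
                durs = rng.exponential(dur_mean, size=n_ev)
                next_start = np.append(starts[1:], day0 + w1)
                ends = np.minimum(starts + durs, next_start - 1e-6)
                ends = np.maximum(ends, starts)
                for e in range(n_ev):
                    event_rows.append(
                        (site_id, day, e, float(starts[e]), float(ends[e]))
                    )
                    if b == 0:
                        continue
                    attend = _event_attendance(
                        q, config.attendance_slope, config.attendance_base, rng
                    )
                    span = max(ends[e] - starts[e], 1.0)
                    mid = starts[e] + span / 2.0
                    for j in np.flatnonzero(attend):
                        n_vis = 1 + rng.poisson(
                            max(config.visits_per_attendance_mean - 1.0, 0.0)
                        )
                        arr = np.clip(
                            rng.normal(mid, config.within_event_sd_s, size=n_vis),
                            starts[e],
                            ends[e],
                        )
                        arr = np.sort(np.round(arr)).astype(np.int64)
                        dwell = np.maximum(
                            1, np.round(rng.exponential(config.dwell_mean_s, n_vis))
                        ).astype(np.int64)
                        dep = np.minimum(arr + dwell, day0 + w1)
                        for a_s, d_s in zip(arr, dep):
                            visit_rows.append((site_id, tags[j], int(a_s), int(d_s)))
                        member_rows.append(
                            (site_id, day, e, tags[j], int(arr[0]))
                        )

    stream = pd.DataFrame(
        visit_rows, columns=["site_id", "tag_id", "arrival_s", "departure_s"]
    )
    stream = stream.sort_values(
        ["site_id", "arrival_s", "tag_id", "departure_s"], kind="mergesort"
    ).reset_index(drop=True)
    truth = GroundTruth(
        events=pd.DataFrame(
            event_rows, columns=["site_id", "day", "event_idx", "start_s", "end_s"]
        ),
        membership=pd.DataFrame(
            member_rows,
            columns=["site_id", "day", "event_idx", "tag_id", "first_arrival_s"],
        ),
        ranks=pd.DataFrame(rank_rows, columns=["site_id", "week", "tag_id", "rank"]),
        sites=pd.DataFrame(site_rows, columns=["site_id", "habitat"]),
    )
    return stream, truth


STREAM_COLUMNS = ["site_id", "tag_id", "arrival_s", "departure_s"]


def write_stream(stream: pd.DataFrame, path) -> None:
    """Write a visit stream to CSV (header always present)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(STREAM_COLUMNS)
        for row in stream.itertuples(index=False):
            writer.writerow([row.site_id, row.tag_id, int(row.arrival_s), int(row.departure_s)])


def read_stream(path) -> pd.DataFrame:
    """Read a visit stream CSV, reporting malformed rows with line numbers."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != STREAM_COLUMNS:
            raise ValueError(f"{path}: line 1: expected header {','.join(STREAM_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
            site, tag, arr, dep = row[0], row[1], row[2], row[3]
            try:
                arr_i, dep_i = int(arr), int(dep)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric timestamp {arr!r}/{dep!r}"
                ) from exc
            if dep_i < arr_i:
                raise ValueError(f"{path}: line {lineno}: departure before arrival")
            rows.append((site, tag, arr_i, dep_i))
    return pd.DataFrame(rows, columns=STREAM_COLUMNS)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-derived) mapping; unknown keys rejected."""
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
    d = dict(d)
    if "day_window" in d:
        d["day_window"] = tuple(d["day_window"])
    return SimConfig(**d)


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["day_window"] = list(d["day_window"])
    return d
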