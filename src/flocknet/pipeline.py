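"""End-to-end pipeline: simulate -> detect -> networks -> consistency ->
foraging -> repeatability -> model selection.

Every stage reads its inputs from, and writes its outputs to, plain CSV files
in the run directory, so stages can be toggled off and re-run from prior
outputs.  All randomness derives from the single ``seed`` in the run config;
re-running with an identical config is byte-identical.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clumpiness import summarize_day
from .consistency import (
    adjusted_repeatability,
    compare_habitats,
    consistency_test,
    metric_rank_vector,
    repeatability_p_vs_null,
)
from .events import (
    ForagingEvent,
    apply_inclusion_filters,
    build_gbi,
    day_of,
    detect_events,
    week_of,
)
from .glmm import fit_lmm
from .modelsel import CandidateSpec, fit_candidates, model_average, rank_models
from .network import sri_matrix
from .permute import PermutationPlan, same_day_event_pairs, single_swap
from .synthetic import (
    SECONDS_PER_DAY,
    config_from_dict,
    config_to_dict,
    read_stream,
    simulate_dataset,
    write_stream,
)

__all__ = ["run_all", "default_config", "load_config", "RESPONSES"]

FLOAT_FMT = "%.10g"

#: response -> (table, family) for repeatability and model selection
RESPONSES = {
    "n_events": ("daily", "poisson"),
    "n_visits": ("daily", "poisson"),
    "clump_arrivals": ("daily", "gaussian"),
    "clump_events": ("daily", "gaussian"),
    "n_individuals": ("event", "poisson"),
    "duration_s": ("event", "gaussian"),
}

STAGES = (
    "simulate",
    "detect",
    "networks",
    "consistency",
    "foraging",
    "repeatability",
    "select",
    "report",
)


def default_config() -> dict:
    return {
        "seed": 0,
        "stages": {s: True for s in STAGES},
        "sim": {},
        "detect": {"max_components": 12, "bridge_s": 600.0, "reg_covar_s2": 900.0},
        "filters": {"min_weeks": 5, "min_weekly_records": 5, "strict": True},
        "permutation": {"n_networks": 100, "swaps_between_saves": 10},
        "repeatability": {"n_boot": 40},
    }


def merge_defaults(user: dict) -> dict:
    """Overlay a (possibly partial) user config on the defaults."""
    cfg = default_config()
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return merge_defaults(yaml.safe_load(fh) or {})


def _stage_seed(seed: int, stage: str, extra: int = 0) -> int:
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence([seed & 0xFFFFFFFF, idx, extra]).generate_state(1)[0]
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------- stages


def stage_simulate(outdir: Path, cfg: dict) -> None:
    sim_cfg = config_from_dict({**cfg.get("sim", {}), "seed": cfg["seed"]})
    stream, truth = simulate_dataset(sim_cfg)
    write_stream(stream, outdir / "stream.csv")
    _write(truth.sites, outdir / "sites.csv")
    _write(truth.events, outdir / "truth_events.csv")
    _write(truth.membership, outdir / "truth_membership.csv")
    _write(truth.ranks, outdir / "truth_ranks.csv")
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(sim_cfg), fh, sort_keys=True)


def stage_detect(outdir: Path, cfg: dict) -> None:
    stream = read_stream(outdir / "stream.csv")
    det = cfg["detect"]
    seed = _stage_seed(cfg["seed"], "detect")
    stream = stream.assign(day=day_of(stream["arrival_s"].to_numpy()))
    ev_rows, mem_rows = [], []
    for (site, day), grp in stream.groupby(["site_id", "day"], sort=True):
        events = detect_events(
            grp.drop(columns="day"),
            max_components=det["max_components"],
            seed=seed,
            bridge_s=det["bridge_s"],
            reg_covar_s2=det["reg_covar_s2"],
        )
        for e, ev in enumerate(events):
            ev_rows.append((site, int(day), e, ev.start_s, ev.end_s))
            for tag in sorted(ev.members):
                mem_rows.append((site, int(day), e, tag, ev.first_arrival[tag]))
    _write(
        pd.DataFrame(
            ev_rows, columns=["site_id", "day", "event_idx", "start_s", "end_s"]
        ),
        outdir / "events.csv",
    )
    _write(
        pd.DataFrame(
            mem_rows,
            columns=["site_id", "day", "event_idx", "tag_id", "first_arrival_s"],
        ),
        outdir / "membership.csv",
    )


def _load_events(outdir: Path) -> list[ForagingEvent]:
    events = pd.read_csv(outdir / "events.csv")
    membership = pd.read_csv(outdir / "membership.csv")
    mem = {
        key: dict(zip(grp["tag_id"], grp["first_arrival_s"]))
        for key, grp in membership.groupby(["site_id", "day", "event_idx"], sort=True)
    }
    out = []
    for row in events.itertuples(index=False):
        first = mem.get((row.site_id, row.day, row.event_idx), {})
        if not first:
            continue
        out.append(
            ForagingEvent(
                site_id=row.site_id,
                day=int(row.day),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                members=frozenset(first),
                first_arrival=first,
            )
        )
    return out


def _days_per_week(cfg: dict) -> int:
    return int(cfg.get("sim", {}).get("days_per_week", 3))


def stage_networks(outdir: Path, cfg: dict) -> None:
    stream = read_stream(outdir / "stream.csv")
    dpw = _days_per_week(cfg)
    filt = cfg["filters"]
    roster, presence = apply_inclusion_filters(
        stream,
        days_per_week=dpw,
        min_weeks=filt["min_weeks"],
        min_weekly_records=filt["min_weekly_records"],
        strict=filt["strict"],
    )
    _write(roster, outdir / "roster.csv")
    _write(presence, outdir / "presence.csv")

    events = _load_events(outdir)
    gbi_rows, metric_rows = [], []
    for site, site_roster in roster.groupby("site_id", sort=True):
        tags = sorted(site_roster["tag_id"])
        if len(tags) < 2:
            continue
        site_events = [ev for ev in events if ev.site_id == site]
        by_week: dict[int, list] = {}
        for ev in site_events:
            by_week.setdefault(int(week_of(ev.day, dpw)), []).append(ev)
        for week in sorted(by_week):
            gbi = build_gbi(by_week[week], tags, site_id=site, week_id=week)
            if gbi.n_events == 0:
                continue
            for r in range(gbi.n_events):
                for j, tag in enumerate(gbi.individuals):
                    if gbi.matrix[r, j]:
                        gbi_rows.append((site, week, r, int(gbi.days[r]), tag))
            net = sri_matrix(gbi)
            for j, tag in enumerate(net.individuals):
                metric_rows.append(
                    (
                        site,
                        week,
                        tag,
                        net.weighted_degree[j],
                        net.eigen_centrality[j],
                        net.rank_degree[j],
                        net.rank_eigen[j],
                    )
                )
    _write(
        pd.DataFrame(
            gbi_rows, columns=["site_id", "week", "row", "day", "tag_id"]
        ),
        outdir / "gbi.csv",
    )
    _write(
        pd.DataFrame(
            metric_rows,
            columns=[
                "site_id",
                "week",
                "tag_id",
                "weighted_degree",
                "eigen_centrality",
                "rank_degree",
                "rank_eigen",
            ],
        ),
        outdir / "metrics.csv",
    )


def _load_gbis(outdir: Path) -> dict[str, list]:
    """Rebuild per-site weekly GBI objects from gbi.csv.

    Columns are the full site roster (as at build time), so weeks where only
    part of the roster was seen reload identically."""
    long = pd.read_csv(outdir / "gbi.csv")
    roster = pd.read_csv(outdir / "roster.csv")
    roster_by_site = {
        site: tuple(sorted(grp["tag_id"]))
        for site, grp in roster.groupby("site_id", sort=True)
    }
    out: dict[str, list] = {}
    for (site, week), grp in long.groupby(["site_id", "week"], sort=True):
        individuals = roster_by_site.get(site) or tuple(sorted(grp["tag_id"].unique()))
        col = {t: j for j, t in enumerate(individuals)}
        n_rows = int(grp["row"].max()) + 1
        matrix = np.zeros((n_rows, len(individuals)), dtype=np.int8)
        days = np.zeros(n_rows, dtype=np.int64)
        for rec in grp.itertuples(index=False):
            matrix[rec.row, col[rec.tag_id]] = 1
            days[rec.row] = rec.day
        from .events import GroupByIndividualMatrix

        out.setdefault(site, []).append(
            GroupByIndividualMatrix(
                matrix=matrix,
                individuals=individuals,
                days=days,
                site_id=site,
                week_id=int(week),
            )
        )
    return out


def stage_consistency(outdir: Path, cfg: dict) -> None:
    sites = pd.read_csv(outdir / "sites.csv").set_index("site_id")["habitat"]
    gbis_by_site = _load_gbis(outdir)
    perm = cfg["permutation"]
    rows = []
    for i, site in enumerate(sorted(gbis_by_site)):
        gbis = gbis_by_site[site]
        if len(gbis) < 2:
            warnings.warn(f"site {site}: fewer than 2 weekly networks, skipped")
            continue
        for metric in ("degree", "eigen"):
            plan = PermutationPlan(
                n_networks=perm["n_networks"],
                swaps_between_saves=perm["swaps_between_saves"],
                seed=_stage_seed(cfg["seed"], "consistency", extra=2 * i + (metric == "eigen")),
            )
            res = consistency_test(gbis, metric=metric, plan=plan)
            rows.append(
                {
                    "site_id": site,
                    "habitat": sites.get(site, "unknown"),
                    "metric": metric,
                    "n_individuals": res.n_individuals,
                    "sv_o": res.sv_o,
                    "p": res.p,
                }
            )
    _write(pd.DataFrame(rows), outdir / "consistency.csv")


def _month_of_day(day: int) -> str:
    return f"m{int(day) // 28:02d}"


def _network_rank_long(gbis_by_site: dict, dpw: int) -> pd.DataFrame:
    rows = []
    for site in sorted(gbis_by_site):
        for gbi in gbis_by_site[site]:
            net = sri_matrix(gbi)
            month = _month_of_day(gbi.week_id * dpw)
            for j, tag in enumerate(net.individuals):
                rows.append(
                    {
                        "site_id": site,
                        "week": gbi.week_id,
                        "month": month,
                        "tag_id": tag,
                        "rank_degree": net.rank_degree[j],
                        "rank_eigen": net.rank_eigen[j],
                    }
                )
    return pd.DataFrame(rows)


def _null_network_r(gbis_by_site, dpw, metric, plan, fixed, extra_random):
    """Null ensemble of network-metric repeatabilities from joint chains.

    The long-table row layout (which individual appears in which site-week
    network) is invariant under margin-preserving swaps, so the design matrix
    and groupings are built once; only the rank values are refreshed at each
    checkpoint.
    """
    import patsy

    rng = np.random.default_rng(plan.seed)
    flat = []  # (site, chain gbi, swap-pair cache, y-slice)
    long = _network_rank_long(gbis_by_site, dpw)
    y = long["rank_degree" if metric == "degree" else "rank_eigen"].to_numpy(float).copy()
    X = np.asarray(patsy.dmatrix(fixed, long, return_type="matrix"))
    groups = long["tag_id"].to_numpy()
    groups2 = long[extra_random].to_numpy() if extra_random else None
    offset = 0
    for s in sorted(gbis_by_site):
        for gbi in gbis_by_site[s]:
            chain = gbi.copy()
            n_in_net = int((np.asarray(gbi.matrix).sum(axis=0) > 0).sum())
            flat.append(
                (chain, same_day_event_pairs(chain.days), slice(offset, offset + n_in_net))
            )
            offset += n_in_net
    assert offset == len(long)
    out = np.empty(plan.n_networks)
    warm = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(plan.n_networks):
            for chain, pr, sl in flat:
                for _ in range(plan.swaps_between_saves):
                    single_swap(chain, rng, pr)
                y[sl] = metric_rank_vector(chain, metric)
            fit = fit_lmm(y, X, groups, groups2=groups2, x0=warm, reml=True)
            if groups2 is not None and fit.sigma2_e > 0:
                warm = [
                    np.log(max(fit.sigma2_g / fit.sigma2_e, 1e-6)),
                    np.log(max(fit.sigma2_g2 / fit.sigma2_e, 1e-6)),
                ]
            denom = fit.sigma2_g + fit.sigma2_g2 + fit.sigma2_e
            out[i] = fit.sigma2_g / denom if denom > 0 else 0.0
    return out


def stage_repeatability(outdir: Path, cfg: dict) -> None:
    sites = pd.read_csv(outdir / "sites.csv")
    habitat = sites.set_index("site_id")["habitat"]
    dpw = _days_per_week(cfg)
    n_boot = cfg["repeatability"]["n_boot"]
    perm = cfg["permutation"]

    # --- network metrics: grouping = individual, p vs permutation null
    gbis_by_site = _load_gbis(outdir)
    long = _network_rank_long(gbis_by_site, dpw)
    long["habitat"] = long["site_id"].map(habitat)
    net_rows = []
    for mi, metric in enumerate(("degree", "eigen")):
        col = "rank_degree" if metric == "degree" else "rank_eigen"
        for si, subset in enumerate(("all", "urban", "rural")):
            d = long if subset == "all" else long[long["habitat"] == subset]
            if d.empty or d["tag_id"].nunique() < 2:
                continue
            if subset == "all":
                fixed, extra = "C(month) + week", "site_id"
            else:
                fixed, extra = "C(site_id) + C(month) + week", None
            rep = adjusted_repeatability(
                d,
                response=col,
                group="tag_id",
                fixed=fixed,
                family="gaussian",
                extra_random=extra,
                subset=subset,
                n_boot=n_boot,
                seed=_stage_seed(cfg["seed"], "repeatability", extra=10 + 6 * mi + si),
                p_method="none",
            )
            plan = PermutationPlan(
                n_networks=perm["n_networks"],
                swaps_between_saves=perm["swaps_between_saves"],
                seed=_stage_seed(cfg["seed"], "repeatability", extra=100 + 6 * mi + si),
            )
            subset_gbis = {
                s: g
                for s, g in gbis_by_site.items()
                if subset == "all" or habitat.get(s) == subset
            }
            null_r = _null_network_r(subset_gbis, dpw, metric, plan, fixed, extra)
            rep.p = repeatability_p_vs_null(rep.r, null_r)
            rep.p_method = "permutation"
            net_rows.append(
                {
                    "metric": f"rank_{metric}",
                    "subset": subset,
                    "R": rep.r,
                    "ci_low": rep.ci_low,
                    "ci_high": rep.ci_high,
                    "ci_level": rep.ci_level,
                    "p": rep.p,
                    "p_method": rep.p_method,
                }
            )
    _write(pd.DataFrame(net_rows), outdir / "repeatability_networks.csv")

    # --- foraging metrics: grouping = site, p via boundary-corrected LRT
    tables = _foraging_tables(outdir, cfg)
    rows, comparisons = [], []
    for ri, (response, (table, family)) in enumerate(RESPONSES.items()):
        d_all = tables[table].dropna(subset=[response])
        reps = {}
        for si, subset in enumerate(("all", "urban", "rural")):
            d = d_all if subset == "all" else d_all[d_all["habitat"] == subset]
            if d.empty or d["site_id"].nunique() < 2:
                continue
            rep = adjusted_repeatability(
                d,
                response=response,
                group="site_id",
                fixed="group_size + C(month) + day",
                family=family,
                subset=subset,
                n_boot=n_boot,
                seed=_stage_seed(cfg["seed"], "repeatability", extra=1000 + 10 * ri + si),
                p_method="lrt",
            )
            reps[subset] = rep
            rows.append(
                {
                    "metric": response,
                    "subset": subset,
                    "R": rep.r,
                    "ci_low": rep.ci_low,
                    "ci_high": rep.ci_high,
                    "ci_level": rep.ci_level,
                    "p": rep.p,
                    "p_method": rep.p_method,
                }
            )
        if "urban" in reps and "rural" in reps:
            cmp = compare_habitats(reps["urban"], reps["rural"])
            comparisons.append(
                {
                    "metric": response,
                    "differs": cmp["differs"],
                    "overlap": cmp["overlap"],
                }
            )
    _write(pd.DataFrame(rows), outdir / "repeatability_foraging.csv")
    _write(pd.DataFrame(comparisons), outdir / "habitat_comparison.csv")


def stage_foraging(outdir: Path, cfg: dict) -> None:
    stream = read_stream(outdir / "stream.csv")
    sites = pd.read_csv(outdir / "sites.csv")
    habitat = sites.set_index("site_id")["habitat"]
    sim = cfg.get("sim", {})
    w0, w1 = sim.get("day_window", (21600, 64800))
    n_days = int(sim.get("n_weeks", 13)) * _days_per_week(cfg)
    events = _load_events(outdir)
    by_site_day: dict[tuple, list] = {}
    for ev in events:
        by_site_day.setdefault((ev.site_id, ev.day), []).append(ev)
    stream = stream.assign(day=day_of(stream["arrival_s"].to_numpy()))
    visit_counts = stream.groupby(["site_id", "day"]).size()

    daily_rows, event_rows = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for site in sorted(sites["site_id"]):
            for day in range(n_days):
                evs = by_site_day.get((site, day), [])
                window = (day * SECONDS_PER_DAY + w0, day * SECONDS_PER_DAY + w1)
                summary = summarize_day(
                    evs,
                    range(int(visit_counts.get((site, day), 0))),
                    window,
                    site_id=site,
                    day=day,
                )
                daily_rows.append(
                    {
                        "site_id": site,
                        "habitat": habitat.get(site, "unknown"),
                        "day": day,
                        "n_events": summary.n_events,
                        "n_visits": summary.n_visits,
                        "clump_arrivals": summary.clump_arrivals,
                        "clump_events": summary.clump_events,
                    }
                )
                for e, (n_ind, dur) in enumerate(summary.event_rows):
                    event_rows.append(
                        {
                            "site_id": site,
                            "habitat": habitat.get(site, "unknown"),
                            "day": day,
                            "event_idx": e,
                            "n_individuals": n_ind,
                            "duration_s": dur,
                        }
                    )
    _write(pd.DataFrame(daily_rows), outdir / "daily.csv")
    _write(pd.DataFrame(event_rows), outdir / "event_metrics.csv")


def _foraging_tables(outdir: Path, cfg: dict) -> dict[str, pd.DataFrame]:
    """Daily and event-level tables joined with covariates."""
    roster = pd.read_csv(outdir / "roster.csv")
    group_size = roster.groupby("site_id").size().rename("group_size")
    out = {}
    for name, fname in (("daily", "daily.csv"), ("event", "event_metrics.csv")):
        df = pd.read_csv(outdir / fname)
        df["month"] = [_month_of_day(d) for d in df["day"]]
        df = df.join(group_size, on="site_id")
        df["group_size"] = df["group_size"].fillna(0).astype(int)
        out[name] = df
    return out


def stage_select(outdir: Path, cfg: dict) -> None:
    tables = _foraging_tables(outdir, cfg)
    for response, (table, family) in RESPONSES.items():
        d = tables[table].dropna(subset=[response]).reset_index(drop=True)
        spec = CandidateSpec(response=response, family=family)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_candidates(d, spec)
            ranking = rank_models(fits)
            avg = model_average(fits)
        _write(ranking, outdir / f"model_rank_{response}.csv")
        _write(avg, outdir / f"model_avg_{response}.csv")


def stage_report(outdir: Path, cfg: dict) -> None:
    report: dict = {"version": __version__, "seed": cfg["seed"]}
    for name, fname in (
        ("consistency", "consistency.csv"),
        ("repeatability_networks", "repeatability_networks.csv"),
        ("repeatability_foraging", "repeatability_foraging.csv"),
        ("habitat_comparison", "habitat_comparison.csv"),
    ):
        path = outdir / fname
        if path.exists():
            df = pd.read_csv(path)
            report[name] = json.loads(df.to_json(orient="records"))
    top = {}
    for response in RESPONSES:
        path = outdir / f"model_rank_{response}.csv"
        if path.exists():
            df = pd.read_csv(path)
            if len(df):
                top[response] = df.iloc[0]["model"]
    report["top_models"] = top
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "networks": stage_networks,
    "consistency": stage_consistency,
    "foraging": stage_foraging,
    "repeatability": stage_repeatability,
    "select": stage_select,
    "report": stage_report,
}


def run_all(cfg: dict, outdir) -> Path:
    """Run every enabled stage in order; returns the run directory.

    A stage failure raises with the stage name; outputs of completed stages
    are preserved on disk.
    """
    cfg = merge_defaults(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    for stage in STAGES:
        if not cfg.get("stages", {}).get(stage, True):
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](outdir, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        timings[stage] = round(time.time() - t0, 3)
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "stages": [s for s in STAGES if cfg.get("stages", {}).get(s, True)],
        "outputs": {
            p.name: sum(1 for _ in open(p)) - 1
            for p in sorted(outdir.glob("*.csv"))
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    # timing log kept out of the manifest so reruns are byte-identical
    with open(outdir / "timings.log", "w") as fh:
        for stage, dt in timings.items():
            fh.write(f"{stage}\t{dt}\n")
    return outdir
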