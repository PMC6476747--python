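import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from flocknet.clumpiness import raw_entropy, rescaled_clumpiness
from flocknet.synthetic import (
    SimConfig,
    dirichlet_alpha_for_clumpiness,
    expected_rescaled_clumpiness,
    read_stream,
    simulate_dataset,
    write_stream,
)

ONE_SITE = dict(n_sites_urban=1, n_sites_rural=0)


def tiny_config(**kw):
    base = dict(
        **ONE_SITE,
        birds_per_site=4,
        n_weeks=2,
        days_per_week=2,
        events_per_day_mean=3.0,
        visits_per_attendance_mean=1.5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestValidation:
    def test_day_too_short(self):
        cfg = tiny_config(events_per_day_mean=500.0, event_duration_mean_s=600.0)
        with pytest.raises(ValueError, match="day too short"):
            simulate_dataset(cfg)

    def test_bad_window(self):
        with pytest.raises(ValueError, match="day_window"):
            tiny_config(day_window=(5000, 100)).validate()

    def test_bad_clumpiness(self):
        with pytest.raises(ValueError, match="event_spacing_clumpiness"):
            tiny_config(event_spacing_clumpiness=1.5).validate()

    def test_negative_rate(self):
        with pytest.raises(ValueError, match="events_per_day_mean"):
            tiny_config(events_per_day_mean=-1.0).validate()


class TestSimulate:
    def test_seed_determinism(self, tmp_path):
        s1, _ = simulate_dataset(tiny_config(seed=42))
        s2, _ = simulate_dataset(tiny_config(seed=42))
        pd.testing.assert_frame_equal(s1, s2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_stream(s1, p1)
        write_stream(s2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_seed_changes_stream(self):
        s1, _ = simulate_dataset(tiny_config(seed=1))
        s2, _ = simulate_dataset(tiny_config(seed=2))
        assert not s1.equals(s2)

    def test_no_birds_empty_stream(self):
        stream, truth = simulate_dataset(tiny_config(birds_per_site=0))
        assert len(stream) == 0
        assert len(truth.membership) == 0

    def test_visits_inside_day_window(self):
        cfg = tiny_config(seed=3, dwell_mean_s=300.0)
        stream, _ = simulate_dataset(cfg)
        w0, w1 = cfg.day_window
        day = stream["arrival_s"] // 86400
        rel_arr = stream["arrival_s"] - day * 86400
        rel_dep = stream["departure_s"] - day * 86400
        assert ((rel_arr >= w0) & (rel_arr <= w1)).all()
        assert (rel_dep <= w1).all()
        assert (stream["departure_s"] >= stream["arrival_s"]).all()

    def test_every_visit_inside_exactly_one_truth_event(self):
        cfg = tiny_config(seed=5, events_per_day_mean=4.0)
        stream, truth = simulate_dataset(cfg)
        ev = truth.events
        for row in stream.itertuples(index=False):
            day = row.arrival_s // 86400
            dayev = ev[(ev["site_id"] == row.site_id) & (ev["day"] == day)]
            inside = (
                (dayev["start_s"] - 0.5 <= row.arrival_s)
                & (row.arrival_s <= dayev["end_s"] + 0.5)
            ).sum()
            assert inside >= 1

    def test_truth_events_non_overlapping(self):
        _, truth = simulate_dataset(tiny_config(seed=7, events_per_day_mean=8.0))
        for (_, _), grp in truth.events.groupby(["site_id", "day"]):
            g = grp.sort_values("start_s")
            assert (g["end_s"].to_numpy()[:-1] <= g["start_s"].to_numpy()[1:]).all()

    def test_membership_within_roster(self):
        _, truth = simulate_dataset(tiny_config(seed=8))
        roster = set(truth.ranks["tag_id"])
        assert set(truth.membership["tag_id"]) <= roster

    def test_event_count_monte_carlo_mean(self):
        # 1 site, 1 event/day expected, 13 days -> mean count ~ 13
        counts = []
        for seed in range(200):
            cfg = SimConfig(
                **ONE_SITE,
                birds_per_site=1,
                n_weeks=13,
                days_per_week=1,
                events_per_day_mean=1.0,
                visits_per_attendance_mean=1.0,
                seed=seed,
            )
            _, truth = simulate_dataset(cfg)
            counts.append(len(truth.events))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - 13.0) <= 3 * se + 1e-9


class TestRankDial:
    def test_zero_noise_identical_weekly_orderings(self):
        _, truth = simulate_dataset(tiny_config(rank_noise_sd=0.0, n_weeks=5, seed=9))
        piv = truth.ranks.pivot_table(index="tag_id", columns="week", values="rank")
        assert (piv.nunique(axis=1) == 1).all()

    def test_large_noise_exchangeable_orderings(self):
        cfg = SimConfig(
            **ONE_SITE,
            birds_per_site=8,
            n_weeks=30,
            days_per_week=1,
            events_per_day_mean=1.0,
            visits_per_attendance_mean=1.0,
            rank_noise_sd=100.0,
            seed=11,
        )
        _, truth = simulate_dataset(cfg)
        piv = truth.ranks.pivot_table(index="tag_id", columns="week", values="rank")
        cors = [
            spearmanr(piv[w1], piv[w2]).statistic
            for w1 in piv.columns
            for w2 in piv.columns
            if w1 < w2
        ]
        assert abs(np.mean(cors)) < 0.1


class TestClumpinessCalibration:
    @pytest.mark.parametrize("k", [3, 6, 11])
    def test_closed_form_matches_monte_carlo(self, k):
        rngl = np.random.default_rng(0)
        alpha = 0.7
        draws = rngl.dirichlet(np.full(k, alpha), size=20000)
        with np.errstate(all="ignore"):
            h = np.nansum(np.where(draws > 0, draws * np.log(draws), 0.0), axis=1)
        mc = 1 + h.mean() / np.log(k)
        assert expected_rescaled_clumpiness(alpha, k) == pytest.approx(mc, abs=0.01)

    def test_inversion_roundtrip(self):
        for target in (0.1, 0.5, 0.9):
            for k in (3, 8):
                a = dirichlet_alpha_for_clumpiness(target, k)
                assert expected_rescaled_clumpiness(a, k) == pytest.approx(
                    target, abs=1e-8
                )

    @pytest.mark.parametrize("target", [0.1, 0.5, 0.9])
    def test_realized_start_clumpiness(self, target):
        # mean realized rescaled H_p of event starts over ~200 days within 0.05
        cfg = SimConfig(
            **ONE_SITE,
            birds_per_site=1,
            n_weeks=30,
            days_per_week=7,
            events_per_day_mean=6.0,
            event_spacing_clumpiness=target,
            visits_per_attendance_mean=1.0,
            seed=100,
        )
        _, truth = simulate_dataset(cfg)
        w0, w1 = cfg.day_window
        vals = []
        for day, grp in truth.events.groupby("day"):
            starts = np.sort(grp["start_s"].to_numpy() - day * 86400)
            if starts.size < 1:
                continue
            x = np.diff(np.concatenate([[w0], starts, [w1]]))
            vals.append(rescaled_clumpiness(raw_entropy(x), n=starts.size))
        assert len(vals) >= 195
        assert np.mean(vals) == pytest.approx(target, abs=0.05)


class TestAttendanceSlope:
    def test_zero_slope_symmetric_attendance(self):
        # with slope 0 every bird has the same expected attendance count
        per_bird = []
        for seed in range(60):
            cfg = SimConfig(
                **ONE_SITE,
                birds_per_site=5,
                n_weeks=3,
                days_per_week=3,
                events_per_day_mean=5.0,
                attendance_slope=0.0,
                visits_per_attendance_mean=1.0,
                seed=seed,
            )
            _, truth = simulate_dataset(cfg)
            counts = truth.membership.groupby("tag_id").size()
            per_bird.append(counts / len(truth.events))
        df = pd.DataFrame(per_bird)
        means = df.mean(axis=0)
        sem = df.std(axis=0, ddof=1) / math.sqrt(len(df))
        assert ((means - means.mean()).abs() <= 4 * sem + 1e-9).all()

    def test_positive_slope_gives_consistent_centralities(self):
        # stable latent quality + proximity recruitment -> weekly degree
        # orderings strongly correlated across weeks
        from flocknet.network import sri_matrix
        from conftest import truth_weekly_gbis

        cfg = SimConfig(
            **ONE_SITE,
            birds_per_site=8,
            n_weeks=4,
            days_per_week=4,
            events_per_day_mean=8.0,
            attendance_slope=6.0,
            rank_noise_sd=0.0,
            visits_per_attendance_mean=1.0,
            seed=21,
        )
        _, truth = simulate_dataset(cfg)
        gbis = truth_weekly_gbis(truth, "U01", days_per_week=4)
        degs = []
        for gbi in gbis:
            net = sri_matrix(gbi)
            degs.append(
                {t: d for t, d in zip(net.individuals, net.weighted_degree)}
            )
        rhos = []
        for i in range(len(degs)):
            for j in range(i + 1, len(degs)):
                common = sorted(set(degs[i]) & set(degs[j]))
                rhos.append(
                    spearmanr(
                        [degs[i][t] for t in common], [degs[j][t] for t in common]
                    ).statistic
                )
        assert np.mean(rhos) > 0.6


class TestStreamIO:
    def test_round_trip_identity(self, tmp_path):
        stream, _ = simulate_dataset(tiny_config(seed=13))
        path = tmp_path / "stream.csv"
        write_stream(stream, path)
        back = read_stream(path)
        pd.testing.assert_frame_equal(stream, back)

    def test_empty_round_trip(self, tmp_path):
        stream, _ = simulate_dataset(tiny_config(birds_per_site=0))
        path = tmp_path / "empty.csv"
        write_stream(stream, path)
        back = read_stream(path)
        assert len(back) == 0
        assert list(back.columns) == ["site_id", "tag_id", "arrival_s", "departure_s"]

    def test_three_row_fixture(self, tmp_path):
        df = pd.DataFrame(
            [("S1", "a", 10, 12), ("S1", "b", 20, 25), ("S2", "c", 30, 31)],
            columns=["site_id", "tag_id", "arrival_s", "departure_s"],
        )
        path = tmp_path / "f.csv"
        write_stream(df, path)
        pd.testing.assert_frame_equal(read_stream(path), df)

    def test_non_numeric_timestamp_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "site_id,tag_id,arrival_s,departure_s\nS1,a,10,12\nS1,b,oops,25\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_stream(path)

    def test_missing_field_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site_id,tag_id,arrival_s,departure_s\nS1,a,10\n")
        with pytest.raises(ValueError, match="line 2"):
            read_stream(path)

    def test_bad_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y\n1,2\n")
        with pytest.raises(ValueError, match="line 1"):
            read_stream(path)
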