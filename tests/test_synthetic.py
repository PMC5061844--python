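"""Synthetic generator: counts, schedules, step bands, kill times, offsets."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest

from foragerisk.config import BerryParams, KillParams, SimConfig
from foragerisk.solar import hunting_window, solar_times
from foragerisk.synthetic import (
    DIRECTION_MAP,
    generate_berry_field,
    generate_foraging_observations,
    generate_kill_times,
    generate_tracks,
    plot_offset,
)
from oracles import ztnb_truncated_mean_bruteforce


def test_fix_count_forced_by_interval_arithmetic():
    cfg = replace(
        SimConfig(),
        n_bears=2,
        start_date=date(2014, 8, 7),
        end_date=date(2014, 8, 10),
        dropout=0.0,
    )
    fixes, truth = generate_tracks(cfg)
    assert len(fixes) == 2 * 4 * 48
    assert len(truth) == len(fixes)


def test_config_validation_rejects_bad_inputs():
    with pytest.raises(ValueError):
        replace(SimConfig(), end_date=date(2014, 8, 1))  # end <= start
    with pytest.raises(ValueError):
        replace(SimConfig(), schedule={})
    with pytest.raises(ValueError):
        replace(SimConfig(), fix_interval_minutes=7)
    with pytest.raises(ValueError):
        replace(SimConfig(), step_bands={"rest": (0, 100), "forage": (50, 300)})
    with pytest.raises(ValueError):
        BerryParams(count_theta=-1.0)


def test_hourly_foraging_frequency_is_bimodal_with_midday_trough(default_study):
    """Empirical foraging frequency peaks in 02-07 and 13-20, lowest 09-11."""
    truth = default_study.truth.copy()
    truth["hour"] = pd.to_datetime(truth["timestamp"]).dt.hour
    freq = truth.groupby("hour")["state"].apply(lambda s: (s == "forage").mean())
    top2 = freq.nlargest(8).index
    assert any(2 <= h < 7 for h in top2)
    assert any(13 <= h < 20 for h in top2)
    assert freq.idxmin() in (9, 10, 11)


def test_forage_steps_stay_inside_band_with_expected_mean():
    cfg = replace(SimConfig(), seed=3)
    lo, hi = cfg.step_bands["forage"]
    rng = np.random.default_rng(42)
    draws = rng.uniform(lo, hi, 10_000)  # direct sampling oracle
    # generator steps attributed to the forage state
    study_fixes, truth = generate_tracks(replace(cfg, dropout=0.0))
    merged = study_fixes.merge(truth, on=["animal_id", "timestamp"])
    forage_steps = []
    for _, grp in merged.groupby("animal_id"):
        g = grp.sort_values("timestamp")
        d = np.hypot(np.diff(g["x"]), np.diff(g["y"]))
        forage_steps.append(d[(g["state"].to_numpy() == "forage")[:-1]])
    steps = np.concatenate(forage_steps)
    assert steps.min() >= lo and steps.max() <= hi
    se = draws.std() / np.sqrt(len(steps))
    assert abs(steps.mean() - draws.mean()) < 3 * se


def test_schedule_marginals_are_respected():
    """Despite serial persistence, per-hour foraging rates match the schedule."""
    cfg = replace(SimConfig(), n_bears=40, dropout=0.0, seed=9)
    _, truth = generate_tracks(cfg)
    truth["hour"] = pd.to_datetime(truth["timestamp"]).dt.hour
    truth["d"] = pd.to_datetime(truth["timestamp"]).dt.date
    pre = truth[truth["d"] < cfg.site.hunting_start]
    rates = pre.groupby("hour")["state"].apply(lambda s: (s == "forage").mean())
    sched = cfg.schedule["prehunting"]
    # per-hour binomial SE on n = 40 bears * 14 days draws (2 fixes/hour share a draw)
    n_draws = 40 * 14
    for h in range(24):
        se = max(np.sqrt(sched[h] * (1 - sched[h]) / n_draws), 1e-3)
        assert abs(rates[h] - sched[h]) < 4 * se, f"hour {h}"


def test_berry_field_counts_truncated_and_mean_matches_pmf_oracle():
    """With a flat phenology each habitat stratum has a single (mu, theta);
    the stratum mean must match the truncated-mean pmf-summation oracle."""
    bp = BerryParams(
        count_log_intercepts={"mature_forest": 2.0, "clearcut": 3.2},
        count_date_slope=0.0,
        count_theta=1.6,
    )
    cfg = replace(SimConfig(), berry_params=bp, seed=5)
    plots = generate_berry_field(cfg, 10_000, sugar_fraction=1.0)
    assert (plots["count"] >= 1).all()
    for hab, log_mu in bp.count_log_intercepts.items():
        sub = plots[plots["habitat"] == hab]["count"]
        oracle = ztnb_truncated_mean_bruteforce(np.exp(log_mu), bp.count_theta, 200_000)
        se = sub.std() / np.sqrt(len(sub))
        assert abs(sub.mean() - oracle) < 3 * se, hab


def test_equal_intercepts_zero_slope_gives_equal_habitat_means():
    bp = BerryParams(
        count_log_intercepts={"mature_forest": 2.5, "clearcut": 2.5},
        count_date_slope=0.0,
    )
    cfg = replace(SimConfig(), berry_params=bp, seed=6)
    plots = generate_berry_field(cfg, 8000)
    g = plots.groupby("habitat")["count"]
    means, counts = g.mean(), g.size()
    pooled_sd = plots["count"].std()
    se = pooled_sd * np.sqrt(1 / counts.iloc[0] + 1 / counts.iloc[1])
    assert abs(means.iloc[0] - means.iloc[1]) < 3 * se


def test_foraging_observations_null_offsets_center_on_expectation(default_study):
    cfg = replace(
        default_study.config,
        selection_offsets={k: 0.0 for k in default_study.config.selection_offsets},
        sugar_offsets={k: 0.0 for k in default_study.config.sugar_offsets},
    )
    obs, truth = generate_foraging_observations(
        default_study.sampled_positions, cfg, rng=np.random.default_rng(11)
    )
    diff = obs["count"].to_numpy() - truth["true_expected_count"].to_numpy()
    for (p, b), grp in obs.assign(diff=diff).groupby(["period", "bout"]):
        se = grp["diff"].std() / np.sqrt(len(grp))
        assert abs(grp["diff"].mean()) < 3 * se, (p, b)


def test_noise_free_observation_is_exact_arithmetic(default_study):
    obs, truth = generate_foraging_observations(
        default_study.sampled_positions, default_study.config,
        rng=np.random.default_rng(1), noise_free=True,
    )
    np.testing.assert_allclose(
        obs["count"].to_numpy(),
        np.maximum(truth["true_expected_count"] + truth["injected_offset"], 0.0),
    )


def test_offsets_missing_a_cell_are_rejected():
    cfg = SimConfig()
    broken = {k: v for k, v in cfg.selection_offsets.items() if k[1] != "morning"}
    with pytest.raises(ValueError, match="offsets"):
        replace(cfg, selection_offsets=broken)


def test_kill_times_inside_window_and_morning_heavy():
    st = solar_times(61.5, 15.05, date(2014, 8, 28), 2.0)
    w = hunting_window(st)
    hours = generate_kill_times(1000, w, seed=4)
    lo = w.start.hour + w.start.minute / 60
    hi = w.end.hour + w.end.minute / 60
    assert hours.min() >= lo and hours.max() <= hi
    assert (hours < 12).mean() > (hours >= 12).mean()


def test_kill_times_symmetric_components_split_evenly():
    st = solar_times(61.5, 15.05, date(2014, 8, 28), 2.0)
    w = hunting_window(st)
    kp = KillParams(morning_weight=0.5, morning_mean=9.0, morning_sd=1.5,
                    afternoon_mean=14.0, afternoon_sd=1.5)
    hours = generate_kill_times(100_000, w, kp, seed=5)
    before = (hours < 11.5).mean()
    se = 0.5 / np.sqrt(len(hours))  # binomial oracle at p = 1/2
    assert abs(before - 0.5) < 3 * se


def test_plot_offset_zero_and_known_cases():
    assert plot_offset(123.0, 450.0) == (123.0, 450.0)  # Y ends in 0
    assert plot_offset(100.0, 203.0) == (100.0, 206.0)  # X digit 0 -> N, magnitude 3


def test_plot_offset_exhaustive_digit_grid():
    """All (magnitude, direction) combinations appear under the mapping."""
    seen = set()
    for xd in range(10):
        for yd in range(10):
            nx, ny = plot_offset(1000 + xd, 2000 + yd)
            dx, dy = nx - (1000 + xd), ny - (2000 + yd)
            mag = abs(dx) + abs(dy)
            assert mag == yd
            direction = DIRECTION_MAP[xd % 4]
            expected = {"N": (0, yd), "E": (yd, 0), "S": (0, -yd), "W": (-yd, 0)}[direction]
            assert (dx, dy) == expected
            seen.add((yd, direction))
    assert seen == {(m, d) for m in range(10) for d in "NESW"}


def test_fixed_seed_reproduces_byte_identical_output():
    cfg = replace(SimConfig(), n_bears=2, end_date=date(2014, 8, 12), seed=21)
    a = generate_tracks(cfg)
    b = generate_tracks(cfg)
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    pa = generate_berry_field(cfg, 200)
    pb = generate_berry_field(cfg, 200)
    assert pa.to_csv(index=False) == pb.to_csv(index=False)


def test_config_yaml_roundtrip(tmp_path):
    cfg = SimConfig()
    path = tmp_path / "cfg.yaml"
    path.write_text(cfg.to_yaml())
    from foragerisk.config import load_sim_config

    again = load_sim_config(path)
    assert again == cfg
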