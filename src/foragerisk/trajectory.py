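"""Step trajectories, foraging classification, and activity profiles.

A *step* is the straight-line displacement between two consecutive 30-min
GPS fixes.  Berry foraging is identified as slow, continuous movement: a
maximal run of consecutive valid steps in which every step covers 25-300 m
and the run spans at least ``min_run`` steps.  Runs outside that band are
labeled "other" behavior (resting, long-distance travel) when they span at
least three positions and are discarded otherwise.  Steps whose duration
deviates from the fix schedule by more than a tolerance are invalid and
break runs.

Field-sampling positions follow the anti-autocorrelation protocol: the
second position of each foraging trajectory, plus the second-to-last when
the trajectory exceeds seven positions.

Activity profiles pool all animals and report, per time-of-day bin, the
proportion of fixes classified as foraging among all fixes; kill-hour risk
densities are per-hour relative frequencies.

Bookkeeping convention: each classified fix carries the label of the
trajectory that owns its *outgoing* step (the movement in the following
interval); the final fix of a run, which has no outgoing step inside it,
takes the label of the trajectory it terminates.  A trajectory of ``k``
steps therefore spans ``k + 1`` positions, while two trajectories abutting
inside one valid run share their boundary fix only in the position lists,
never in the per-fix labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StepTrajectory",
    "build_steps",
    "classify_foraging",
    "sample_positions",
    "sample_all_positions",
    "activity_profile",
    "risk_density",
    "classification_scores",
]

VALID_PERIODS = ("prehunting", "hunting")


@dataclass(frozen=True)
class StepTrajectory:
    """A maximal run of consecutive valid steps with a behavior label."""

    trajectory_id: str
    animal_id: str
    label: str  # "foraging" | "other"
    positions: pd.DataFrame = field(repr=False)  # ordered fixes incl. both endpoints
    step_lengths: np.ndarray = field(repr=False)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def start(self):
        return self.positions["timestamp"].iloc[0]

    @property
    def end(self):
        return self.positions["timestamp"].iloc[-1]


def build_steps(
    fixes: pd.DataFrame,
    tolerance_minutes: float = 5.0,
    expected_minutes: float = 30.0,
) -> pd.DataFrame:
    """Build one step per consecutive fix pair, per animal.

    Steps whose duration falls outside ``expected_minutes`` +/- the
    tolerance (missed fixes, irregular schedules) are flagged invalid; they
    carry a length but never join a trajectory.  Raises on duplicate
    timestamps within an animal.
    """
    required = {"animal_id", "timestamp", "x", "y"}
    missing = required - set(fixes.columns)
    if missing:
        raise ValueError(f"fixes table missing columns: {sorted(missing)}")
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    if not np.all(np.isfinite(fixes[["x", "y"]].to_numpy(dtype=float))):
        raise ValueError("fix coordinates must be finite")
    out = []
    for animal, grp in fixes.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        dup = grp["timestamp"].duplicated()
        if dup.any():
            t = grp.loc[dup.idxmax(), "timestamp"]
            raise ValueError(f"duplicate timestamp for animal {animal!r} at {t}")
        if len(grp) < 2:
            continue
        dx = np.diff(grp["x"].to_numpy(dtype=float))
        dy = np.diff(grp["y"].to_numpy(dtype=float))
        lengths = np.hypot(dx, dy)
        durations = np.diff(grp["timestamp"].to_numpy()).astype("timedelta64[s]").astype(float) / 60.0
        valid = np.abs(durations - expected_minutes) <= tolerance_minutes
        step = pd.DataFrame(
            {
                "animal_id": animal,
                "t_from": grp["timestamp"].iloc[:-1].to_numpy(),
                "t_to": grp["timestamp"].iloc[1:].to_numpy(),
                "x_from": grp["x"].iloc[:-1].to_numpy(),
                "y_from": grp["y"].iloc[:-1].to_numpy(),
                "x_to": grp["x"].iloc[1:].to_numpy(),
                "y_to": grp["y"].iloc[1:].to_numpy(),
                "length": lengths,
                "duration_minutes": durations,
                "valid": valid,
            }
        )
        out.append(step)
    if not out:
        return pd.DataFrame(
            columns=[
                "animal_id", "t_from", "t_to", "x_from", "y_from",
                "x_to", "y_to", "length", "duration_minutes", "valid",
            ]
        )
    return pd.concat(out, ignore_index=True)


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def classify_foraging(
    steps: pd.DataFrame,
    min_len: float = 25.0,
    max_len: float = 300.0,
    min_run: int = 3,
) -> tuple[list[StepTrajectory], pd.DataFrame]:
    """Segment steps into foraging / other trajectories and label fixes.

    Within each maximal run of consecutive valid steps, sub-runs whose
    every length lies in the closed band ``[min_len, max_len]`` and that
    span at least ``min_run`` steps become foraging trajectories; the
    remaining sub-runs become "other" trajectories when they span at least
    three positions and are discarded otherwise.

    Returns ``(trajectories, labeled_fixes)``.  ``labeled_fixes`` has one
    row per fix that anchors a step, with ``label`` in {"foraging",
    "other", "unclassified"}; every fix appears exactly once.
    """
    trajectories: list[StepTrajectory] = []
    label_rows = []
    if len(steps) == 0:
        labeled = pd.DataFrame(columns=["animal_id", "timestamp", "x", "y", "label"])
        return trajectories, labeled

    counter = 0
    for animal, grp in steps.groupby("animal_id", sort=True):
        grp = grp.sort_values("t_from").reset_index(drop=True)
        lengths = grp["length"].to_numpy()
        valid = grp["valid"].to_numpy(bool)
        # consecutive = valid and contiguous in time with the previous step
        contig = np.ones(len(grp), dtype=bool)
        contig[1:] = grp["t_from"].to_numpy()[1:] == grp["t_to"].to_numpy()[:-1]
        fix_label = np.full(len(grp), "unclassified", dtype=object)
        last_fix_label = "unclassified"

        # maximal valid runs, broken at invalid steps and time gaps
        run_mask = valid.copy()
        seq_starts = []
        for start, stop in _runs(run_mask):
            s = start
            for i in range(start + 1, stop):
                if not contig[i]:
                    seq_starts.append((s, i))
                    s = i
            seq_starts.append((s, stop))
        for s, e in seq_starts:
            in_band = (lengths[s:e] >= min_len) & (lengths[s:e] <= max_len)
            bounds = [s] + [s + i for i in range(1, e - s) if in_band[i] != in_band[i - 1]] + [e]
            for a, b in zip(bounds, bounds[1:]):
                n_steps = b - a
                forage = bool(in_band[a - s])
                n_pos = n_steps + 1
                if forage and n_steps >= min_run:
                    label = "foraging"
                elif n_pos >= 3:
                    label = "other"
                else:
                    label = None
                if label is not None:
                    counter += 1
                    pos = pd.DataFrame(
                        {
                            "animal_id": animal,
                            "timestamp": np.concatenate(
                                [grp["t_from"].to_numpy()[a:b], [grp["t_to"].to_numpy()[b - 1]]]
                            ),
                            "x": np.concatenate(
                                [grp["x_from"].to_numpy()[a:b], [grp["x_to"].to_numpy()[b - 1]]]
                            ),
                            "y": np.concatenate(
                                [grp["y_from"].to_numpy()[a:b], [grp["y_to"].to_numpy()[b - 1]]]
                            ),
                        }
                    )
                    trajectories.append(
                        StepTrajectory(
                            trajectory_id=f"traj_{counter:05d}",
                            animal_id=animal,
                            label=label,
                            positions=pos,
                            step_lengths=lengths[a:b].copy(),
                        )
                    )
                    fix_label[a:b] = label
                    if b == e:  # run's trailing fix takes the closing label
                        last_fix_label = label
                else:
                    if b == e:
                        last_fix_label = "unclassified"
            # trailing fix of the valid run (owns no outgoing step in run)
            label_rows.append(
                (
                    animal,
                    grp["t_to"].iloc[e - 1],
                    grp["x_to"].iloc[e - 1],
                    grp["y_to"].iloc[e - 1],
                    last_fix_label,
                )
            )
            last_fix_label = "unclassified"
        for i in range(len(grp)):
            label_rows.append(
                (animal, grp["t_from"].iloc[i], grp["x_from"].iloc[i], grp["y_from"].iloc[i],
                 fix_label[i])
            )

    labeled = pd.DataFrame(label_rows, columns=["animal_id", "timestamp", "x", "y", "label"])
    labeled = labeled.drop_duplicates(subset=["animal_id", "timestamp"], keep="last")
    labeled = labeled.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)
    return trajectories, labeled


def sample_positions(traj: StepTrajectory) -> pd.DataFrame:
    """Field-sampling positions of a foraging trajectory.

    Returns the second position; when the trajectory spans more than seven
    positions (> 3.5 h of continuous foraging), also the second-to-last.
    """
    if traj.label != "foraging":
        raise ValueError("sample_positions expects a foraging trajectory")
    n = traj.n_positions
    if n < 3:
        raise ValueError(f"trajectory {traj.trajectory_id} has {n} positions (< 3)")
    rows = [1]  # position #2, 1-based
    if n > 7:
        rows.append(n - 2)  # position #(n-1)
    out = traj.positions.iloc[rows].copy()
    out.insert(0, "trajectory_id", traj.trajectory_id)
    return out.reset_index(drop=True)


def sample_all_positions(trajectories) -> pd.DataFrame:
    """Sampling positions pooled over all foraging trajectories."""
    frames = [sample_positions(t) for t in trajectories if t.label == "foraging"]
    if not frames:
        return pd.DataFrame(columns=["trajectory_id", "animal_id", "timestamp", "x", "y"])
    return pd.concat(frames, ignore_index=True)


def activity_profile(
    labeled_fixes: pd.DataFrame,
    period: pd.Series | np.ndarray | str,
    bin_minutes: int = 30,
) -> pd.DataFrame:
    """Pooled foraging-activity profile by time of day.

    ``period`` tags every fix as "prehunting" or "hunting" (a scalar tags
    them all).  Per time-of-day bin the profile reports the proportion of
    foraging-labeled fixes among all fixes pooled over animals; bins with
    no fixes get a missing (NaN) proportion, not zero.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    fixes = labeled_fixes.copy()
    fixes["period"] = period
    bad = set(fixes["period"].unique()) - set(VALID_PERIODS)
    if bad:
        raise ValueError(f"unknown period tag(s): {sorted(bad)}")
    ts = pd.to_datetime(fixes["timestamp"])
    minutes = ts.dt.hour * 60 + ts.dt.minute
    fixes["bin_start_minutes"] = (minutes // bin_minutes) * bin_minutes
    n_bins = 1440 // bin_minutes
    grid = pd.MultiIndex.from_product(
        [sorted(fixes["period"].unique()), range(0, n_bins * bin_minutes, bin_minutes)],
        names=["period", "bin_start_minutes"],
    )
    grouped = fixes.groupby(["period", "bin_start_minutes"])
    prof = pd.DataFrame(
        {
            "n_fixes": grouped.size(),
            "n_foraging": grouped["label"].apply(lambda s: int((s == "foraging").sum())),
        }
    ).reindex(grid)
    prof["n_fixes"] = prof["n_fixes"].fillna(0).astype(int)
    prof["n_foraging"] = prof["n_foraging"].fillna(0).astype(int)
    prof["p_forage"] = np.where(
        prof["n_fixes"] > 0, prof["n_foraging"] / prof["n_fixes"].replace(0, 1), np.nan
    )
    prof = prof.reset_index()
    prof["hour"] = prof["bin_start_minutes"] / 60.0
    return prof


def risk_density(kill_hours, smooth: bool = False) -> pd.Series:
    """Per-hour relative frequency of kills (hunting mortality risk).

    The density is indexed by hour 0-23 and sums to one.  With
    ``smooth=True`` a circular 3-h moving average is returned instead — a
    derived, smoothed variant, not the raw recorded frequencies.
    """
    hours = np.asarray(kill_hours, dtype=int)
    if hours.size == 0:
        raise ValueError("no kill hours supplied")
    if hours.min() < 0 or hours.max() > 23:
        raise ValueError("kill hours must lie in 0-23")
    counts = np.bincount(hours, minlength=24).astype(float)
    dens = counts / counts.sum()
    if smooth:
        dens = (np.roll(dens, 1) + dens + np.roll(dens, -1)) / 3.0
        dens = dens / dens.sum()
    return pd.Series(dens, index=pd.RangeIndex(24, name="hour"), name="density")


def classification_scores(
    labeled_fixes: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Per-fix precision/recall of foraging classification vs ground truth.

    Joins on (animal_id, timestamp).  Each animal's final fix is excluded:
    its true state governs a step that was never observed.
    """
    t = truth.copy()
    t["timestamp"] = pd.to_datetime(t["timestamp"])
    last = t.groupby("animal_id")["timestamp"].transform("max")
    t = t[t["timestamp"] < last]
    merged = t.merge(labeled_fixes, on=["animal_id", "timestamp"], how="left")
    merged["label"] = merged["label"].fillna("unclassified")
    truth_pos = merged["state"] == "forage"
    pred_pos = merged["label"] == "foraging"
    tp = int((truth_pos & pred_pos).sum())
    fp = int((~truth_pos & pred_pos).sum())
    fn = int((truth_pos & ~pred_pos).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp, "fn": fn}
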