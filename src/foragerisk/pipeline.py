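"""End-to-end convenience wrappers over the analysis stages.

``simulate_study`` runs the full synthetic study for one seed: GPS tracks
-> step trajectories -> foraging classification -> field-sampling
positions -> berry observations, plus the random berry-plot sample.
``efficiency_recovery`` then fits the availability baselines and summarises
cell-mean efficiency against the injected ground truth.  These wrappers
keep scripts and examples thin; every step is an ordinary call into the
stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import baselines, indices, synthetic, trajectory
from .config import SimConfig

__all__ = ["StudyData", "simulate_study", "efficiency_recovery"]


@dataclass
class StudyData:
    """Everything one synthetic study run produces."""

    config: SimConfig
    fixes: pd.DataFrame
    truth: pd.DataFrame
    trajectories: list
    labeled_fixes: pd.DataFrame
    sampled_positions: pd.DataFrame
    observations: pd.DataFrame
    observation_truth: pd.DataFrame
    random_plots: pd.DataFrame

    def write(self, outdir) -> None:
        """Write the study as CSV tables plus the config YAML for provenance.

        Emits ``fixes.csv``, ``truth.csv`` (sidecar ground truth),
        ``labeled_fixes.csv``, ``observations.csv``, ``observation_truth.csv``,
        ``random_plots.csv`` and ``config.yaml`` (ISO-8601 timestamps,
        comma-separated, header row).
        """
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("fixes", "truth", "labeled_fixes", "observations",
                     "observation_truth", "random_plots"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "config.yaml").write_text(self.config.to_yaml())


def simulate_study(
    config: SimConfig | None = None,
    seed: int | None = None,
    n_random_plots: int = 154,
    noise_free_observations: bool = False,
) -> StudyData:
    """Simulate one complete study and run the segmentation stages."""
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fixes, truth = synthetic.generate_tracks(config, rng=rng)
    steps = trajectory.build_steps(fixes)
    trajs, labeled = trajectory.classify_foraging(steps)
    positions = trajectory.sample_all_positions(trajs)
    obs, obs_truth = synthetic.generate_foraging_observations(
        positions, config, rng=rng, noise_free=noise_free_observations
    )
    plots = synthetic.generate_berry_field(config, n_random_plots, rng=rng)
    return StudyData(
        config=config,
        fixes=fixes,
        truth=truth,
        trajectories=trajs,
        labeled_fixes=labeled,
        sampled_positions=positions,
        observations=obs,
        observation_truth=obs_truth,
        random_plots=plots,
    )


def efficiency_recovery(study: StudyData, scale: str = "truncated"):
    """Fit baselines, build the efficiency table, and summarise cells.

    Returns ``(table, summary)`` where ``summary`` has one row per
    (period, bout) cell with the mean efficiency and its 95% CI (baseline
    prediction uncertainty propagated), ready to compare against the
    injected selection offsets.
    """
    count_fit = baselines.fit_ztnb(study.random_plots)
    sugar_fit = baselines.fit_sugar(study.random_plots)
    table = indices.build_efficiency_table(
        study.observations, count_fit, sugar_fit, scale=scale
    )
    summary = indices.cell_summary(table, count_fit=count_fit, scale=scale)
    offsets = study.config.selection_offsets
    summary["injected_offset"] = [
        offsets[(p, b)] for p, b in zip(summary["period"], summary["bout"])
    ]
    summary["covered"] = (summary["ci_low"] <= summary["injected_offset"]) & (
        summary["injected_offset"] <= summary["ci_high"]
    )
    return table, summary
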