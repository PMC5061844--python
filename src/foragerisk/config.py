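"""Study-site and simulation configuration.

``SiteConfig`` holds the geographic/temporal constants of the study design
(site coordinates in central Sweden, UTC offset, season boundary, bout
split).  ``SimConfig`` parameterizes the synthetic-data generator: the
circadian foraging schedule, per-behavior step-length bands, berry-field
phenology, selection offsets at used foraging sites, and kill-time mixture.
Both load from / dump to YAML for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from datetime import date as Date

import yaml

__all__ = ["SiteConfig", "KillParams", "BerryParams", "SimConfig", "DEFAULT_SITE"]

HABITATS = ("mature_forest", "clearcut")
STATES = ("rest", "forage", "travel")
PERIODS = ("prehunting", "hunting")
BOUTS = ("morning", "afternoon")


@dataclass(frozen=True)
class SiteConfig:
    """Geographic and regulatory constants of the study area."""

    lat: float = 61.5
    lon: float = 15.05
    utc_offset: float = 2.0
    hunting_start: Date = Date(2014, 8, 21)
    bout_split_hour: float = 10.0
    window_round_minutes: int = 30

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


DEFAULT_SITE = SiteConfig()


def _default_schedule() -> dict[str, list[float]]:
    """Per-hour probability that a bear is in the foraging state.

    Sharply bimodal: high in the early-morning (02-07) and afternoon/evening
    (13-20) activity peaks, with moderate shoulders directly adjacent to the
    peaks and near-total resting in the midday trough (minimum around
    09:00-10:00) and the middle of the night.  In the hunting period the
    morning peak is lowered by 0.10 (bears forage less in the high-risk
    morning hours) while the afternoon is unchanged.
    """
    pre = [0.03] * 24
    for h in range(2, 7):
        pre[h] = 0.90
    for h in range(13, 20):
        pre[h] = 0.90
    for h in (7, 20):
        pre[h] = 0.25  # shoulders next to the peaks
    pre[8] = 0.05
    pre[9] = 0.02
    pre[10] = 0.02
    pre[11] = 0.03
    pre[12] = 0.05
    pre[21] = 0.06
    hunt = list(pre)
    for h in range(2, 7):
        hunt[h] = pre[h] - 0.10
    return {"prehunting": pre, "hunting": hunt}


def _default_offsets() -> dict[tuple[str, str], float]:
    # Mean extra ripe berries per m2 at used foraging sites, relative to the
    # availability baseline, by (period, bout).
    return {
        ("prehunting", "morning"): 34.0,
        ("hunting", "morning"): 10.0,
        ("prehunting", "afternoon"): 20.0,
        ("hunting", "afternoon"): 20.0,
    }


def _default_sugar_offsets() -> dict[tuple[str, str], float]:
    # Mean extra sugar (%Brix) at used sites relative to baseline.
    return {
        ("prehunting", "morning"): -0.35,
        ("hunting", "morning"): -0.99,
        ("prehunting", "afternoon"): -0.09,
        ("hunting", "afternoon"): -0.09,
    }


@dataclass(frozen=True)
class KillParams:
    """Two-component kill-time mixture inside the legal window (hours)."""

    morning_weight: float = 0.65
    morning_mean: float = 9.5
    morning_sd: float = 2.0
    afternoon_mean: float = 17.0
    afternoon_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.morning_weight <= 1.0:
            raise ValueError("morning_weight must be in [0, 1]")
        if self.morning_sd <= 0 or self.afternoon_sd <= 0:
            raise ValueError("kill-time component sd must be positive")


@dataclass(frozen=True)
class BerryParams:
    """Berry-field phenology: NB2 counts and linear sugar vs habitat/date.

    Counts: log mu = log-intercept(habitat) + slope * (julian - ref_julian),
    dispersion ``theta`` (NB2: var = mu + mu^2/theta).  Sugar (%Brix):
    intercept(habitat) + slope * (julian - ref_julian) + N(0, sd).
    ``obs_theta``/``sugar_obs_sd`` govern extra noise at used foraging sites.
    """

    count_log_intercepts: dict[str, float] = field(
        default_factory=lambda: {"mature_forest": 2.48, "clearcut": 3.40}
    )
    count_date_slope: float = 0.015
    count_theta: float = 2.5
    sugar_intercepts: dict[str, float] = field(
        default_factory=lambda: {"mature_forest": 7.5, "clearcut": 8.5}
    )
    sugar_date_slope: float = 0.03
    sugar_sd: float = 1.2
    ref_julian: int = 219  # 7 August (non-leap year)
    obs_theta: float = 6.0
    sugar_obs_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.count_theta <= 0 or self.obs_theta <= 0:
            raise ValueError("negative binomial dispersion theta must be positive")
        if self.sugar_sd < 0 or self.sugar_obs_sd < 0:
            raise ValueError("sugar residual sd must be non-negative")
        for hab in HABITATS:
            if hab not in self.count_log_intercepts or hab not in self.sugar_intercepts:
                raise ValueError(f"missing habitat intercept for {hab!r}")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic study.

    Defaults emulate the study conditions: 7 bears tracked at 30-min fixes
    over 7 Aug - 3 Sep, a bimodal circadian foraging schedule with a midday
    trough near 10:00, disjoint per-behavior step-length bands matching the
    25-300 m foraging rule, berry phenology increasing through the season,
    and selection offsets of 34 / 10 / 20 / 20 berries per m2 for the
    (prehunting, hunting) x (morning, afternoon) cells.
    """

    n_bears: int = 7
    start_date: Date = Date(2014, 8, 7)
    end_date: Date = Date(2014, 9, 3)
    fix_interval_minutes: int = 30
    schedule: dict[str, list[float]] = field(default_factory=_default_schedule)
    schedule_persistence: float = 0.85
    travel_given_not_foraging: float = 0.25
    step_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "rest": (0.0, 20.0),
            "forage": (30.0, 260.0),
            "travel": (330.0, 1500.0),
        }
    )
    dropout: float = 0.02
    berry_params: BerryParams = field(default_factory=BerryParams)
    selection_offsets: dict[tuple[str, str], float] = field(default_factory=_default_offsets)
    sugar_offsets: dict[tuple[str, str], float] = field(default_factory=_default_sugar_offsets)
    p_clearcut: float = 0.5
    kill_params: KillParams = field(default_factory=KillParams)
    site: SiteConfig = field(default_factory=SiteConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValueError("end_date must fall after start_date")
        if self.fix_interval_minutes <= 0 or 1440 % self.fix_interval_minutes != 0:
            raise ValueError("fix_interval_minutes must divide 1440")
        if not self.schedule:
            raise ValueError("schedule must define at least one period")
        for period, probs in self.schedule.items():
            if len(probs) != 24:
                raise ValueError(f"schedule[{period!r}] needs 24 hourly probabilities")
            if any(p < 0.0 or p > 1.0 for p in probs):
                raise ValueError(f"schedule[{period!r}] probabilities must lie in [0, 1]")
        if not -1.0 < self.schedule_persistence < 1.0:
            raise ValueError("schedule_persistence must lie in (-1, 1)")
        if not self.step_bands:
            raise ValueError("step_bands must define at least one behavioral state")
        bands = sorted(self.step_bands.values())
        for (lo, hi), (lo2, _) in zip(bands, bands[1:]):
            if hi > lo2:
                raise ValueError("per-state step-length bands must be ordered and disjoint")
        for lo, hi in bands:
            if lo < 0 or hi <= lo:
                raise ValueError("each step band needs 0 <= low < high")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for cells in (self.selection_offsets, self.sugar_offsets):
            for period in PERIODS:
                for bout in BOUTS:
                    if (period, bout) not in cells:
                        raise ValueError(f"selection offsets missing cell {(period, bout)}")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def fixes_per_day(self) -> int:
        return 1440 // self.fix_interval_minutes

    def period_of(self, d: Date) -> str:
        return "hunting" if d >= self.site.hunting_start else "prehunting"

    def to_yaml(self) -> str:
        raw = asdict(self)
        raw["selection_offsets"] = {f"{p}/{b}": v for (p, b), v in self.selection_offsets.items()}
        raw["sugar_offsets"] = {f"{p}/{b}": v for (p, b), v in self.sugar_offsets.items()}
        return yaml.safe_dump(raw, sort_keys=False)


def load_sim_config(path) -> SimConfig:
    """Read a SimConfig from a YAML file written by :meth:`SimConfig.to_yaml`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("selection_offsets", "sugar_offsets"):
        if key in raw:
            raw[key] = {tuple(k.split("/")): float(v) for k, v in raw[key].items()}
    if "berry_params" in raw and isinstance(raw["berry_params"], dict):
        raw["berry_params"] = BerryParams(**raw["berry_params"])
    if "kill_params" in raw and isinstance(raw["kill_params"], dict):
        raw["kill_params"] = KillParams(**raw["kill_params"])
    if "site" in raw and isinstance(raw["site"], dict):
        raw["site"] = SiteConfig(**raw["site"])
    if "step_bands" in raw:
        raw["step_bands"] = {k: tuple(v) for k, v in raw["step_bands"].items()}
    return SimConfig(**raw)
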