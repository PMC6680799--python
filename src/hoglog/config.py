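"""Study configuration and phase calendar.

The default values reproduce the layout of the field campaign this package
models: eight tagged animals (sexes balanced), a 19-day baseline ("pre") phase
followed by a 19-day disturbance ("festival") phase, triaxial acceleration
bursts of 2.5 s at 100 Hz once per minute, and GPS bursts of five fixes every
five minutes between 19:00 and 07:00 local time.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


@dataclass
class EffectConfig:
    """Disturbance effects injected during the festival phase.

    onset_delay_min
        Mean shift (minutes) of nightly activity onset past civil dusk.
    area_scale
        Multiplier on the nightly utilization *area* (not radius); must lie
        in (0, 1].  Movement radius is scaled by ``sqrt(area_scale)``.
    dfc_noise_gain
        Fraction in [0, 1] by which the 24-h activity profile is flattened
        toward an arrhythmic (constant-rate) profile; weakens the Degree of
        Functional Coupling monotonically.
    male_nest_hazard_mult
        Multiplier on the daily nest-change probability of males.
    *_sd
        Between-individual heterogeneity of the corresponding effect.
    """

    onset_delay_min: float = 0.0
    area_scale: float = 1.0
    dfc_noise_gain: float = 0.0
    male_nest_hazard_mult: float = 1.0
    onset_delay_sd_min: float = 0.0
    area_scale_sd: float = 0.0
    dfc_noise_gain_sd: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.area_scale <= 1.0):
            raise ConfigError(f"area_scale must be in (0, 1], got {self.area_scale}")
        if not (0.0 <= self.dfc_noise_gain <= 1.0):
            raise ConfigError(
                f"dfc_noise_gain must be in [0, 1], got {self.dfc_noise_gain}"
            )
        if self.male_nest_hazard_mult <= 0:
            raise ConfigError(
                f"male_nest_hazard_mult must be > 0, got {self.male_nest_hazard_mult}"
            )
        for name in ("onset_delay_sd_min", "area_scale_sd", "dfc_noise_gain_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class StudyConfig:
    """Full parameterization of one simulated deployment."""

    n_individuals: int = 8
    pre_days: int = 19
    festival_days: int = 19
    post_days: int = 5  # nest checks continue a few days past the disturbance
    start_date: dt.date = dt.date(2016, 8, 10)

    burst_hz: float = 100.0
    burst_len_s: float = 2.5  # 2.64 s produces the alternative 264-sample bursts
    bursts_per_day: int = 1440
    burst_dropout_rate: float = 0.0

    gps_interval_min: int = 5
    gps_burst_size: int = 5
    gps_night_start_hour: int = 19
    gps_night_end_hour: int = 7
    gps_noise_sd_m: float = 15.0
    gps_artifact_rate: float = 0.0

    seed: int = 0
    effects: EffectConfig = field(default_factory=EffectConfig)

    # waveform signature parameters (free parameters of the emulation;
    # chosen for clean class separation, see docs/methods.md)
    noise_sd_g: float = 0.03
    locomotion_amp_g: float = 0.4
    locomotion_freq_hz: tuple[float, float] = (1.0, 3.0)
    other_amp_g: float = 0.12

    # movement / nest model
    home_sigma_m: float = 60.0
    home_spacing_m: float = 250.0
    movement_tau_min: float = 30.0
    nest_change_prob: float = 0.2
    onset_jitter_sd_min: float = 2.0

    def validate(self) -> None:
        for name in (
            "n_individuals",
            "pre_days",
            "festival_days",
            "bursts_per_day",
            "gps_interval_min",
            "gps_burst_size",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.post_days < 0:
            raise ConfigError(f"post_days must be >= 0, got {self.post_days}")
        if self.burst_hz <= 0:
            raise ConfigError(f"burst_hz must be > 0, got {self.burst_hz}")
        if self.burst_len_s <= 0:
            raise ConfigError(f"burst_len_s must be > 0, got {self.burst_len_s}")
        if not (0.0 <= self.burst_dropout_rate < 1.0):
            raise ConfigError(
                f"burst_dropout_rate must be in [0, 1), got {self.burst_dropout_rate}"
            )
        if not (0.0 <= self.gps_artifact_rate < 1.0):
            raise ConfigError(
                f"gps_artifact_rate must be in [0, 1), got {self.gps_artifact_rate}"
            )
        self.effects.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def samples_per_burst(self) -> int:
        return int(round(self.burst_hz * self.burst_len_s))

    @property
    def acc_days(self) -> int:
        """Days with accelerometer/GPS coverage (pre + festival)."""
        return self.pre_days + self.festival_days

    @property
    def nest_days(self) -> int:
        """Days with nest checks (pre + festival + post)."""
        return self.acc_days + self.post_days

    def dates(self, include_post: bool = False) -> list[dt.date]:
        n = self.nest_days if include_post else self.acc_days
        return [self.start_date + dt.timedelta(days=i) for i in range(n)]

    def calendar(self) -> "PhaseCalendar":
        pre_end = self.start_date + dt.timedelta(days=self.pre_days - 1)
        fest_start = pre_end + dt.timedelta(days=1)
        fest_end = fest_start + dt.timedelta(days=self.festival_days - 1)
        post_end = fest_end + dt.timedelta(days=self.post_days)
        return PhaseCalendar(
            pre_start=self.start_date,
            pre_end=pre_end,
            festival_start=fest_start,
            festival_end=fest_end,
            post_end=post_end,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d


@dataclass
class PhaseCalendar:
    """Pre / festival / post phase boundaries (inclusive dates).

    The default corresponds to the study calendar: baseline 10–28 Aug 2016,
    disturbance 29 Aug – 16 Sep 2016, nest monitoring until 21 Sep 2016.
    """

    pre_start: dt.date = dt.date(2016, 8, 10)
    pre_end: dt.date = dt.date(2016, 8, 28)
    festival_start: dt.date = dt.date(2016, 8, 29)
    festival_end: dt.date = dt.date(2016, 9, 16)
    post_end: dt.date = dt.date(2016, 9, 21)

    def __post_init__(self) -> None:
        if not (self.pre_start <= self.pre_end < self.festival_start <= self.festival_end):
            raise ConfigError("phases must be ordered and non-overlapping")
        if self.post_end < self.festival_end:
            raise ConfigError("post_end must not precede festival_end")

    def phase_of(self, date: dt.date) -> str | None:
        if self.pre_start <= date <= self.pre_end:
            return "pre"
        if self.festival_start <= date <= self.festival_end:
            return "festival"
        if self.festival_end < date <= self.post_end:
            return "post"
        return None

    @property
    def pre_dates(self) -> list[dt.date]:
        n = (self.pre_end - self.pre_start).days + 1
        return [self.pre_start + dt.timedelta(days=i) for i in range(n)]

    @property
    def festival_dates(self) -> list[dt.date]:
        n = (self.festival_end - self.festival_start).days + 1
        return [self.festival_start + dt.timedelta(days=i) for i in range(n)]
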