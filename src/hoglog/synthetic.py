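"""Synthetic bio-logging study generator.

Emulates a small-mammal disturbance study: nocturnal animals carrying
accelerometer/GPS loggers through a baseline phase and a disturbance
("festival") phase.  Every stream the analysis pipeline consumes is generated
here with known ground truth:

* per-minute behaviour states from a two-level stochastic model — a slow
  active/quiet bout process whose occupancy follows the nocturnal activity
  profile, and a per-minute behaviour Markov chain within each regime;
* triaxial acceleration bursts with behaviour-specific waveform signatures;
* nightly GPS fix bursts around a per-individual home centre, with optional
  outlier artifacts;
* daily nest checks with a configurable nest-change hazard;
* a smooth seasonal civil-twilight table (template, not an ephemeris).

Disturbance effects (delayed activity onset, shrunken nightly area, flattened
24-h activity profile, elevated male nest-change hazard) are injected during
the festival phase with per-individual heterogeneity, and recorded in the
returned :class:`GroundTruth` so downstream estimators can be validated
against the injected values.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, StudyConfig

BEHAVIORS = ("immobile", "balling", "locomotion", "other")
_BIDX = {b: i for i, b in enumerate(BEHAVIORS)}

# per-minute behaviour transition matrices (rows: from-state, cols: to-state,
# state order as BEHAVIORS) for the active and quiet regimes
_T_ACTIVE = np.array(
    [
        [0.25, 0.02, 0.63, 0.10],
        [0.20, 0.10, 0.60, 0.10],
        [0.10, 0.01, 0.79, 0.10],
        [0.15, 0.02, 0.63, 0.20],
    ]
)
# the quiet regime emits only resting postures (the animal is in its nest);
# the locomotion/other rows only decay transient state after a regime flip
_T_QUIET = np.array(
    [
        [0.93, 0.07, 0.00, 0.00],
        [0.15, 0.85, 0.00, 0.00],
        [0.75, 0.10, 0.10, 0.05],
        [0.80, 0.15, 0.00, 0.05],
    ]
)
_REGIME_SWITCH_RATE = 0.25  # per-minute rate scale of the bout process

# relative per-axis dynamic amplitudes for locomotion (surge, sway, heave)
_LOC_AXIS_SCALE = np.array([1.0, 0.6, 0.8])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    burst_labels: pd.DataFrame | None
    minutes: pd.DataFrame
    onsets: pd.DataFrame
    night_areas: pd.DataFrame
    nest_changes: pd.DataFrame
    gps_artifacts: pd.DataFrame
    home_centers: pd.DataFrame
    individuals: pd.DataFrame


@dataclass
class StudyData:
    bursts: pd.DataFrame | None
    gps: pd.DataFrame
    nests: pd.DataFrame
    twilight: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# twilight template
# ---------------------------------------------------------------------------


def _twilight_dates(config: StudyConfig) -> list[dt.date]:
    """Study dates plus one day on each side: the evening before the study
    (warm-start night) and the dawn after the last day both need twilight."""
    return [
        config.start_date + dt.timedelta(days=i) for i in range(-1, config.nest_days + 1)
    ]

def seasonal_twilight(dates: list[dt.date]) -> pd.DataFrame:
    """Civil dawn/dusk from a smooth seasonal template (central-European
    latitudes).  This is a deliberately simple sinusoid in day-of-year, not an
    ephemeris: the analysis treats twilight as an external input table."""
    rows = []
    for d in dates:
        doy = d.timetuple().tm_yday
        phase = 2.0 * np.pi * (doy - 172) / 365.25
        dawn_min = 373.0 - 101.0 * np.cos(phase)
        dusk_min = 1178.0 + 114.0 * np.cos(phase)
        base = dt.datetime.combine(d, dt.time())
        rows.append(
            {
                "date": d,
                "civil_dawn": base + dt.timedelta(minutes=float(dawn_min)),
                "civil_dusk": base + dt.timedelta(minutes=float(dusk_min)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-minute behaviour model
# ---------------------------------------------------------------------------

def _behavior_asd(config: StudyConfig) -> np.ndarray:
    """Expected accumulated SD (sum of per-axis SDs) for each behaviour,
    matching the waveform synthesis parameters."""
    s = config.noise_sd_g
    loc = np.sum(np.sqrt((config.locomotion_amp_g * _LOC_AXIS_SCALE) ** 2 / 2.0 + s**2))
    oth = 3.0 * np.sqrt(config.other_amp_g**2 + s**2)
    return np.array([3.0 * s, 3.0 * s, loc, oth])


def generate_minutes(
    config: StudyConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the per-minute behaviour/activity stream for all individuals.

    Returns ``(minutes, onsets, individuals)`` where *minutes* has one row per
    individual-minute (behavior label, active-regime flag, true accumulated-SD
    activity level) and *onsets* holds the injected nightly activity-onset
    instants.  This is the fast path used when raw waveforms are not needed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cal = config.calendar()
    dates = config.dates()
    twilight = seasonal_twilight(_twilight_dates(config))
    dawn = {r.date: r.civil_dawn for r in twilight.itertuples()}
    dusk = {r.date: r.civil_dusk for r in twilight.itertuples()}

    n_min = len(dates) * 1440
    t0 = dt.datetime.combine(config.start_date, dt.time())
    minute_index = pd.date_range(t0, periods=n_min, freq="min")
    asd_levels = _behavior_asd(config)

    individuals = _individual_table(config, rng)
    all_minutes = []
    onset_rows = []
    for ind in individuals.itertuples():
        # nightly activity windows: dusk (+ injected delay during festival,
        # + daily jitter) until shortly before the next dawn
        p = np.full(n_min, 0.0)  # the animal rests in its nest by day
        window_starts = []
        window_ends = []
        # include the night that began the evening before the study so the
        # first morning carries its tail (an ongoing deployment, not a cold
        # start); it contributes no onset row
        for d in [dates[0] - dt.timedelta(days=1)] + dates:
            delay = ind.onset_delay if cal.phase_of(d) == "festival" else 0.0
            jitter = rng.normal(0.0, config.onset_jitter_sd_min)
            start = dusk[d] + dt.timedelta(minutes=delay + jitter)
            end = dawn[d + dt.timedelta(days=1)] - dt.timedelta(minutes=15)
            i0_raw = int((start - t0).total_seconds() // 60)
            i0 = max(i0_raw, 0)
            i1 = min(int((end - t0).total_seconds() // 60), n_min)
            if i0 >= n_min or i1 <= i0:
                continue
            p[i0:i1] = 0.95
            if i1 < n_min:
                window_ends.append(i1)
            if i0_raw < 0:
                continue  # warm-start night: profile only, no onset
            window_starts.append(i0)
            onset_rows.append(
                {
                    "individual_id": ind.individual_id,
                    "date": d,
                    "true_onset": minute_index[i0],
                    "delay_min": delay,
                }
            )
        # festival arrhythmia: flatten the profile toward its own mean
        g = ind.dfc_gain
        if g > 0:
            for d in dates:
                if cal.phase_of(d) != "festival":
                    continue
                i0 = int((dt.datetime.combine(d, dt.time()) - t0).total_seconds() // 60)
                i1 = min(i0 + 1440, n_min)
                day_mean = p[i0:i1].mean()
                p[i0:i1] = (1.0 - g) * p[i0:i1] + g * day_mean

        active = np.zeros(n_min, dtype=bool)
        behavior = np.zeros(n_min, dtype=np.int8)
        u_reg = rng.random(n_min)
        u_beh = rng.random(n_min)
        forced = set(window_starts)
        # force quiet at window end so last night's bout cannot spill past
        # the coming dawn into the next dawn-to-dawn day
        forced_end = set(window_ends) - forced
        state_active = False
        state_beh = _BIDX["immobile"]
        cum_a = _T_ACTIVE.cumsum(axis=1)
        cum_q = _T_QUIET.cumsum(axis=1)
        for t in range(n_min):
            if t in forced:
                state_active = True
            elif t in forced_end:
                state_active = False
            else:
                if state_active:
                    if u_reg[t] < _REGIME_SWITCH_RATE * (1.0 - p[t]):
                        state_active = False
                else:
                    if u_reg[t] < _REGIME_SWITCH_RATE * p[t]:
                        state_active = True
            cum = cum_a if state_active else cum_q
            state_beh = int(np.searchsorted(cum[state_beh], u_beh[t]))
            active[t] = state_active
            behavior[t] = state_beh

        asd = asd_levels[behavior] * np.exp(rng.normal(0.0, 0.12, n_min))
        all_minutes.append(
            pd.DataFrame(
                {
                    "individual_id": ind.individual_id,
                    "timestamp": minute_index,
                    "behavior": np.array(BEHAVIORS, dtype=object)[behavior],
                    "active": active,
                    "asd_true": asd,
                }
            )
        )
    minutes = pd.concat(all_minutes, ignore_index=True)
    onsets = pd.DataFrame(onset_rows)
    return minutes, onsets, individuals


def _individual_table(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    eff = config.effects
    rows = []
    for i in range(config.n_individuals):
        angle = 2.0 * np.pi * i / max(config.n_individuals, 1)
        posture_pitch = rng.normal(0.0, 8.0)
        posture_roll = rng.normal(0.0, 8.0)
        rows.append(
            {
                "individual_id": f"id{i + 1:02d}",
                "sex": "m" if i % 2 == 0 else "f",
                "home_x": config.home_spacing_m * np.cos(angle),
                "home_y": config.home_spacing_m * np.sin(angle),
                "onset_delay": max(
                    0.0, eff.onset_delay_min + rng.normal(0.0, eff.onset_delay_sd_min)
                ),
                "area_scale": float(
                    np.clip(eff.area_scale + rng.normal(0.0, eff.area_scale_sd), 0.05, 1.0)
                ),
                "dfc_gain": float(
                    np.clip(eff.dfc_noise_gain + rng.normal(0.0, eff.dfc_noise_gain_sd), 0.0, 1.0)
                ),
                "posture_pitch_deg": posture_pitch,
                "posture_roll_deg": posture_roll,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _posture_vector(pitch_deg: float, roll_deg: float) -> np.ndarray:
    p = np.deg2rad(pitch_deg)
    r = np.deg2rad(roll_deg)
    return np.array([np.sin(p), np.cos(p) * np.sin(r), np.cos(p) * np.cos(r)])


def synthesize_burst(
    behavior: str,
    posture: np.ndarray,
    rng: np.random.Generator,
    config: StudyConfig | None = None,
) -> np.ndarray:
    """One triaxial burst (n_samples x 3, units of g) for a behaviour label.

    ``posture`` is the unit gravity vector in the sensor frame.  Immobile
    bursts are posture plus sensor noise; balling uses a distinctly rotated
    posture; locomotion adds a 1-3 Hz periodic dynamic component; "other" is
    an irregular broadband segment.
    """
    if config is None:
        config = StudyConfig()
    if behavior not in BEHAVIORS:
        raise ValueError(f"unknown behavior label: {behavior!r}")
    posture = np.asarray(posture, dtype=float)
    if not np.isclose(np.linalg.norm(posture), 1.0, atol=1e-6):
        raise ValueError("posture must be a unit gravity vector (|s| = 1 g)")
    return _synthesize_batch(np.array([_BIDX[behavior]]), posture, rng, config)[0]


def _synthesize_batch(
    behavior_idx: np.ndarray,
    posture: np.ndarray,
    rng: np.random.Generator,
    config: StudyConfig,
) -> np.ndarray:
    """Vectorized burst synthesis: (n_bursts, n_samples, 3) in g."""
    n = len(behavior_idx)
    s = config.samples_per_burst
    t = np.arange(s) / config.burst_hz
    out = np.empty((n, s, 3))
    noise = rng.normal(0.0, 1.0, (n, s, 3)) * config.noise_sd_g

    # balling posture: the same animal frame rotated into a curled position
    pitch = np.degrees(np.arctan2(posture[0], np.hypot(posture[1], posture[2])))
    roll = np.degrees(np.arctan2(posture[1], posture[2]))
    ball_posture = _posture_vector(pitch + 50.0, roll + 35.0)

    static = np.where((behavior_idx == _BIDX["balling"])[:, None], ball_posture, posture)
    out[:] = static[:, None, :] + noise

    loc = behavior_idx == _BIDX["locomotion"]
    if loc.any():
        m = int(loc.sum())
        f = rng.uniform(*config.locomotion_freq_hz, m)
        phase = rng.uniform(0.0, 2.0 * np.pi, (m, 3))
        jitter_sd = getattr(config, "locomotion_amp_jitter_sd", 0.2)
        amp = (
            config.locomotion_amp_g
            * _LOC_AXIS_SCALE
            * np.exp(rng.normal(0.0, jitter_sd, (m, 1)))
        )
        dyn = amp[:, None, :] * np.sin(
            2.0 * np.pi * f[:, None, None] * t[None, :, None] + phase[:, None, :]
        )
        out[loc] += dyn

    oth = behavior_idx == _BIDX["other"]
    if oth.any():
        m = int(oth.sum())
        w = rng.normal(0.0, 1.0, (m, s, 3))
        # irregular broadband: white noise plus a short-window moving average
        kernel = np.ones(7) / 7.0
        smooth = np.apply_along_axis(lambda v: np.convolve(v, kernel, "same"), 1, w)
        out[oth] += config.other_amp_g * (0.7 * w + 1.5 * smooth)
    return out


# ---------------------------------------------------------------------------
# GPS
# ---------------------------------------------------------------------------

def _night_event_times(config: StudyConfig, evening: dt.date) -> pd.DatetimeIndex:
    start = dt.datetime.combine(evening, dt.time(config.gps_night_start_hour))
    end = dt.datetime.combine(
        evening + dt.timedelta(days=1), dt.time(config.gps_night_end_hour)
    )
    return pd.date_range(start, end, freq=f"{config.gps_interval_min}min", inclusive="left")


def _generate_gps(
    config: StudyConfig,
    rng: np.random.Generator,
    individuals: pd.DataFrame,
    minutes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    cal = config.calendar()
    dates = config.dates()
    rho = float(np.exp(-config.gps_interval_min / config.movement_tau_min))
    fix_rows = []
    area_rows = []
    minutes_by_ind = {k: v.set_index("timestamp") for k, v in minutes.groupby("individual_id")}
    t0 = minutes["timestamp"].min()
    for ind in individuals.itertuples():
        act = minutes_by_ind[ind.individual_id]["active"]
        nest_pos = np.array([ind.home_x + 12.0, ind.home_y + 6.0])
        for evening in dates[:-1]:
            phase = cal.phase_of(evening)
            radius = config.home_sigma_m * (
                np.sqrt(ind.area_scale) if phase == "festival" else 1.0
            )
            events = _night_event_times(config, evening)
            z = np.empty((len(events), 2))
            z[0] = rng.normal(0.0, radius, 2)
            innov = rng.normal(0.0, radius, (len(events) - 1, 2)) * np.sqrt(1 - rho**2)
            for k in range(1, len(events)):
                z[k] = rho * z[k - 1] + innov[k - 1]
            center = np.array([ind.home_x, ind.home_y])
            ev_minutes = events.floor("min")
            is_active = act.reindex(ev_minutes, fill_value=False).to_numpy()
            true_pos = np.where(is_active[:, None], center + z, nest_pos)
            for k, ev in enumerate(events):
                for j in range(config.gps_burst_size):
                    fix_rows.append(
                        (
                            ind.individual_id,
                            ev + dt.timedelta(seconds=10 * j),
                            true_pos[k, 0] + rng.normal(0.0, config.gps_noise_sd_m),
                            true_pos[k, 1] + rng.normal(0.0, config.gps_noise_sd_m),
                        )
                    )
            area_rows.append(
                {
                    "individual_id": ind.individual_id,
                    "night": evening,
                    "phase": phase,
                    "radius_m": radius,
                    "true_area_ha": 2.0 * np.pi * np.log(2.0) * radius**2 / 1e4,
                }
            )
    gps = pd.DataFrame(fix_rows, columns=["individual_id", "timestamp", "x_m", "y_m"])
    night_areas = pd.DataFrame(area_rows)
    artifacts = pd.DataFrame(columns=["individual_id", "timestamp", "kind"])
    if config.gps_artifact_rate > 0:
        gps, artifacts = inject_gps_artifacts(
            gps, config.gps_artifact_rate, rng, site_center=(0.0, 0.0),
            event_interval_min=config.gps_interval_min,
        )
    return gps, night_areas, artifacts


def inject_gps_artifacts(
    fixes: pd.DataFrame,
    rate: float,
    rng: np.random.Generator | None = None,
    site_center: tuple[float, float] = (0.0, 0.0),
    event_interval_min: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a fraction ``rate`` of fixes with the two artifact kinds the
    cleaning pipeline targets: far outliers (> 1000 m from the site centre)
    and event-level jumps implying > 2 m/s between consecutive events.

    Returns ``(fixes, flags)`` where *flags* lists every corrupted fix with
    its artifact kind (``far`` or ``speed``).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"artifact rate must be in [0, 1), got {rate}")
    fixes = fixes.reset_index(drop=True).copy()
    if rate == 0.0 or len(fixes) == 0:
        return fixes, pd.DataFrame(columns=["individual_id", "timestamp", "kind"])
    if rng is None:
        rng = np.random.default_rng(0)
    cx, cy = site_center
    n = len(fixes)
    flag_rows = []

    # far outliers on individual fixes (half the budget)
    far_mask = rng.random(n) < rate / 2.0
    if far_mask.any():
        m = int(far_mask.sum())
        ang = rng.uniform(0.0, 2.0 * np.pi, m)
        dist = rng.uniform(1100.0, 2500.0, m)
        fixes.loc[far_mask, "x_m"] = cx + dist * np.cos(ang)
        fixes.loc[far_mask, "y_m"] = cy + dist * np.sin(ang)
        for i in np.nonzero(far_mask)[0]:
            flag_rows.append(
                (fixes.at[i, "individual_id"], fixes.at[i, "timestamp"], "far")
            )

    # event-level jumps: displace all fixes of a sampled event together
    ev_key = pd.Series(
        pd.to_datetime(fixes["timestamp"]).dt.floor(f"{event_interval_min}min"),
        index=fixes.index,
    )
    groups = fixes.groupby([fixes["individual_id"], ev_key]).indices
    keys = list(groups)
    n_ev = max(1, int(round(rate / 2.0 * n / max(1, n // max(1, len(keys))))))
    chosen = rng.choice(len(keys), size=min(n_ev, len(keys)), replace=False)
    for ci in chosen:
        idx = np.asarray(groups[keys[ci]])
        if far_mask[idx].any():
            continue
        ang = rng.uniform(0.0, 2.0 * np.pi)
        jump = rng.uniform(750.0, 950.0)
        fixes.loc[idx, "x_m"] += jump * np.cos(ang)
        fixes.loc[idx, "y_m"] += jump * np.sin(ang)
        for i in idx:
            flag_rows.append(
                (fixes.at[i, "individual_id"], fixes.at[i, "timestamp"], "speed")
            )
    flags = pd.DataFrame(flag_rows, columns=["individual_id", "timestamp", "kind"])
    return fixes, flags


# ---------------------------------------------------------------------------
# nests
# ---------------------------------------------------------------------------

def _generate_nests(
    config: StudyConfig, rng: np.random.Generator, individuals: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cal = config.calendar()
    rows = []
    change_rows = []
    for ind in individuals.itertuples():
        nest_no = 1
        for i, d in enumerate(config.dates(include_post=True)):
            if i > 0:
                p = config.nest_change_prob
                if ind.sex == "m" and cal.phase_of(d) == "festival":
                    p = min(0.9, p * config.effects.male_nest_hazard_mult)
                if rng.random() < p:
                    nest_no += 1
                    change_rows.append(
                        {
                            "individual_id": ind.individual_id,
                            "date": d,
                            "new_nest": f"{ind.individual_id}_N{nest_no:03d}",
                        }
                    )
            rows.append(
                {
                    "individual_id": ind.individual_id,
                    "sex": ind.sex,
                    "date": d,
                    "nest_id": f"{ind.individual_id}_N{nest_no:03d}",
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(change_rows)


# ---------------------------------------------------------------------------
# whole-study assembly
# ---------------------------------------------------------------------------

_MAX_INMEMORY_SAMPLES = 30_000_000


def generate_study(config: StudyConfig, include_bursts: bool = True) -> StudyData:
    """Generate the complete simulated study.

    With the full-size default configuration the long-format burst table holds
    ~115 M samples and does not fit comfortably in memory; use
    :func:`write_study` (which streams per individual-day) or a scaled
    configuration for in-memory work.
    """
    config.validate()
    n_samples = (
        config.n_individuals
        * config.acc_days
        * config.bursts_per_day
        * config.samples_per_burst
    )
    if include_bursts and n_samples > _MAX_INMEMORY_SAMPLES:
        raise ConfigError(
            f"burst table would hold {n_samples} samples; "
            "use write_study() to stream to disk or scale the config down"
        )
    rng_minutes = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_gps = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rng_nest = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rng_wave = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))

    minutes, onsets, individuals = generate_minutes(config, rng_minutes)
    twilight = seasonal_twilight(_twilight_dates(config))
    gps, night_areas, artifacts = _generate_gps(config, rng_gps, individuals, minutes)
    nests, nest_changes = _generate_nests(config, rng_nest, individuals)

    bursts = None
    labels = None
    if include_bursts:
        frames = [
            frame
            for _, frame, _ in iter_burst_frames(config, minutes, individuals, rng_wave)
        ]
        bursts = pd.concat(frames, ignore_index=True)
        labels = minutes.loc[
            minutes["burst_kept"], ["individual_id", "burst_id", "timestamp", "behavior"]
        ].reset_index(drop=True)

    truth = GroundTruth(
        burst_labels=labels,
        minutes=minutes,
        onsets=onsets,
        night_areas=night_areas,
        nest_changes=nest_changes,
        gps_artifacts=artifacts,
        home_centers=individuals[["individual_id", "home_x", "home_y"]].copy(),
        individuals=individuals,
    )
    return StudyData(bursts=bursts, gps=gps, nests=nests, twilight=twilight, truth=truth)


def iter_burst_frames(
    config: StudyConfig,
    minutes: pd.DataFrame,
    individuals: pd.DataFrame,
    rng: np.random.Generator,
):
    """Yield ``(key, long_frame, labels)`` per individual-day; annotates
    ``minutes`` in place with burst ids and kept flags.

    Each day emits ``bursts_per_day`` bursts (the first bursts of the day's
    1440 minutes), minus dropout: dropped-out bursts are either omitted
    entirely or truncated to a random shorter length, exercising both the
    completeness filter and per-burst validation downstream.
    """
    s = config.samples_per_burst
    minutes["burst_id"] = [
        f"{i}:{t:%Y%m%dT%H%M}" for i, t in zip(minutes["individual_id"], minutes["timestamp"])
    ]
    minutes["burst_kept"] = False
    postures = {
        r.individual_id: _posture_vector(r.posture_pitch_deg, r.posture_roll_deg)
        for r in individuals.itertuples()
    }
    for (ind_id, date), day in minutes.groupby(
        ["individual_id", minutes["timestamp"].dt.date], sort=True
    ):
        day = day.iloc[: config.bursts_per_day]
        drop = rng.random(len(day)) < config.burst_dropout_rate
        truncate = drop & (rng.random(len(day)) < 0.5)
        omit = drop & ~truncate
        keep = ~omit
        kept = day.loc[keep]
        minutes.loc[kept.index, "burst_kept"] = True
        bidx = np.array([_BIDX[b] for b in kept["behavior"]])
        waves = _synthesize_batch(bidx, postures[ind_id], rng, config)
        n_keep = len(kept)
        lengths = np.full(n_keep, s)
        trunc_mask = truncate[keep.to_numpy() if hasattr(keep, "to_numpy") else keep].copy()
        trunc_pos = np.nonzero(trunc_mask)[0]
        if len(trunc_pos):
            lengths[trunc_pos] = rng.integers(s // 2, s, len(trunc_pos))
        rows_per_burst = lengths
        total = int(rows_per_burst.sum())
        frame = pd.DataFrame(
            {
                "individual_id": np.repeat(kept["individual_id"].to_numpy(), rows_per_burst),
                "burst_id": np.repeat(kept["burst_id"].to_numpy(), rows_per_burst),
                "timestamp": np.repeat(kept["timestamp"].to_numpy(), rows_per_burst),
                "sample_idx": np.concatenate([np.arange(k) for k in rows_per_burst]),
                "ax_g": np.concatenate([waves[i, : rows_per_burst[i], 0] for i in range(n_keep)]),
                "ay_g": np.concatenate([waves[i, : rows_per_burst[i], 1] for i in range(n_keep)]),
                "az_g": np.concatenate([waves[i, : rows_per_burst[i], 2] for i in range(n_keep)]),
            }
        )
        assert len(frame) == total
        labels = kept[["individual_id", "burst_id", "timestamp", "behavior"]]
        yield (ind_id, date), frame, labels


def write_study(config: StudyConfig, outdir) -> dict:
    """Stream the full study to CSV files under ``outdir``.

    Writes bursts.csv, gps.csv, nests.csv, twilight.csv and truth_*.csv.
    Returns a small manifest dict with row counts.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_minutes = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_gps = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rng_nest = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rng_wave = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))

    minutes, onsets, individuals = generate_minutes(config, rng_minutes)
    twilight = seasonal_twilight(_twilight_dates(config))
    gps, night_areas, artifacts = _generate_gps(config, rng_gps, individuals, minutes)
    nests, nest_changes = _generate_nests(config, rng_nest, individuals)

    counts = {"bursts_rows": 0}
    burst_path = outdir / "bursts.csv"
    label_frames = []
    with open(burst_path, "w") as fh:
        header = True
        for _, frame, labels in iter_burst_frames(config, minutes, individuals, rng_wave):
            frame.to_csv(fh, index=False, header=header)
            header = False
            counts["bursts_rows"] += len(frame)
            label_frames.append(labels)
    gps.to_csv(outdir / "gps.csv", index=False)
    nests.to_csv(outdir / "nests.csv", index=False)
    twilight.to_csv(outdir / "twilight.csv", index=False)
    pd.concat(label_frames, ignore_index=True).to_csv(
        outdir / "truth_burst_labels.csv", index=False
    )
    onsets.to_csv(outdir / "truth_onsets.csv", index=False)
    night_areas.to_csv(outdir / "truth_night_areas.csv", index=False)
    nest_changes.to_csv(outdir / "truth_nest_changes.csv", index=False)
    artifacts.to_csv(outdir / "truth_gps_artifacts.csv", index=False)
    individuals.to_csv(outdir / "truth_individuals.csv", index=False)
    counts.update(
        gps_rows=len(gps), nests_rows=len(nests), twilight_rows=len(twilight)
    )
    return counts
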