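"""Generator contracts: determinism, counts, nocturnality, waveform
signatures, GPS artifacts, and monotone disturbance effects."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from hoglog import (
    ConfigError,
    EffectConfig,
    StudyConfig,
    generate_minutes,
    generate_study,
    inject_gps_artifacts,
    seasonal_twilight,
    synthesize_burst,
)
from hoglog.spatial import clean_fixes


def small_config(**kw) -> StudyConfig:
    base = dict(
        n_individuals=2,
        pre_days=2,
        festival_days=2,
        post_days=1,
        bursts_per_day=120,
        burst_len_s=0.5,
        seed=42,
    )
    base.update(kw)
    return StudyConfig(**base)


def test_same_seed_reproduces_every_stream_exactly():
    a = generate_study(small_config())
    b = generate_study(small_config())
    for name in ("bursts", "gps", "nests", "twilight"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    pd.testing.assert_frame_equal(a.truth.onsets, b.truth.onsets)


def test_burst_counts_without_dropout_are_exact():
    cfg = small_config(n_individuals=1, pre_days=1, festival_days=1, post_days=0)
    study = generate_study(cfg)
    n_bursts = study.bursts["burst_id"].nunique()
    assert n_bursts == 2 * cfg.bursts_per_day
    per_burst = study.bursts.groupby("burst_id").size()
    assert (per_burst == cfg.samples_per_burst).all()
    assert len(study.truth.burst_labels) == n_bursts


def test_default_config_matches_study_layout():
    cfg = StudyConfig()
    assert cfg.n_individuals == 8
    assert cfg.acc_days == 38
    assert cfg.bursts_per_day == 1440
    assert cfg.samples_per_burst == 250
    assert StudyConfig(burst_len_s=2.64).samples_per_burst == 264


def test_invalid_config_errors_name_the_field():
    with pytest.raises(ConfigError, match="n_individuals"):
        StudyConfig(n_individuals=0).validate()
    with pytest.raises(ConfigError, match="area_scale"):
        StudyConfig(effects=EffectConfig(area_scale=0.0)).validate()
    with pytest.raises(ConfigError, match="burst_dropout_rate"):
        StudyConfig(burst_dropout_rate=1.0).validate()


def test_twilight_table_covers_every_study_date():
    cfg = small_config()
    study = generate_study(cfg)
    dates = set(pd.to_datetime(study.twilight["date"]).dt.date)
    assert set(cfg.dates(include_post=True)) <= dates
    tw = seasonal_twilight(cfg.dates())
    assert (tw["civil_dawn"] < tw["civil_dusk"]).all()


def test_locomotion_is_overwhelmingly_nocturnal():
    cfg = StudyConfig(
        n_individuals=3, pre_days=4, festival_days=4, post_days=0, seed=1
    )
    minutes, _, _ = generate_minutes(cfg)
    tw = seasonal_twilight(cfg.dates(include_post=True))
    dusk = dict(zip(tw["date"], tw["civil_dusk"]))
    dawn = dict(zip(tw["date"], tw["civil_dawn"]))
    loc = minutes[minutes["behavior"] == "locomotion"]

    def at_night(ts):
        d = ts.date()
        return ts >= dusk[d] or ts < dawn[d]

    frac = np.mean([at_night(t) for t in loc["timestamp"]])
    assert frac >= 0.90


def test_gps_fixes_only_in_the_night_window():
    study = generate_study(small_config())
    hours = pd.to_datetime(study.gps["timestamp"]).dt.hour
    assert ((hours >= 19) | (hours < 7)).all()


class TestSynthesizeBurst:
    def test_unknown_label_raises(self, rng):
        with pytest.raises(ValueError, match="unknown behavior"):
            synthesize_burst("sprinting", np.array([0.0, 0.0, 1.0]), rng)

    def test_nonunit_posture_raises(self, rng):
        with pytest.raises(ValueError, match="unit gravity"):
            synthesize_burst("immobile", np.array([0.0, 0.0, 2.0]), rng)

    def test_immobile_zero_noise_equals_posture(self, rng):
        cfg = StudyConfig(noise_sd_g=0.0, burst_len_s=0.5)
        posture = np.array([0.0, 0.0, 1.0])
        w = synthesize_burst("immobile", posture, rng, cfg)
        assert np.allclose(w, posture)

    def test_locomotion_peak_to_peak_is_twice_amplitude(self, rng):
        cfg = StudyConfig(noise_sd_g=0.0, locomotion_amp_g=0.4, burst_len_s=2.0)
        cfg.locomotion_amp_jitter_sd = 0.0
        w = synthesize_burst("locomotion", np.array([0.0, 0.0, 1.0]), rng, cfg)
        ptp = w[:, 0].max() - w[:, 0].min()
        assert ptp == pytest.approx(2 * 0.4, rel=0.05)

    def test_balling_posture_is_distinct_from_resting(self, rng):
        cfg = StudyConfig(noise_sd_g=0.0, burst_len_s=0.5)
        posture = np.array([0.0, 0.0, 1.0])
        rest = synthesize_burst("immobile", posture, rng, cfg).mean(axis=0)
        ball = synthesize_burst("balling", posture, rng, cfg).mean(axis=0)
        angle = np.degrees(
            np.arccos(np.clip(np.dot(rest, ball) / np.linalg.norm(ball), -1, 1))
        )
        assert angle > 30.0


def test_feature_space_separates_the_three_classes(day_features):
    """Pairwise feature distances separate immobile/balling/locomotion:
    silhouette > 0 on one generated day."""
    from sklearn.metrics import silhouette_score
    from sklearn.preprocessing import StandardScaler

    from hoglog import FEATURE_COLUMNS

    sub = day_features[
        day_features["label"].isin(("immobile", "balling", "locomotion"))
        & ~day_features["missing"]
    ]
    X = StandardScaler().fit_transform(sub[FEATURE_COLUMNS])
    assert silhouette_score(X, sub["label"]) > 0.0


class TestGpsArtifacts:
    def _fixes(self, n=500):
        rng = np.random.default_rng(5)
        ts = pd.date_range("2016-08-15 19:00", periods=n // 5, freq="5min")
        rows = []
        for t in ts:
            for j in range(5):
                rows.append(("id01", t + pd.Timedelta(seconds=10 * j),
                             rng.normal(0, 40), rng.normal(0, 40)))
        return pd.DataFrame(rows, columns=["individual_id", "timestamp", "x_m", "y_m"])

    def test_rate_zero_is_identity(self):
        fixes = self._fixes()
        out, flags = inject_gps_artifacts(fixes, 0.0)
        pd.testing.assert_frame_equal(out, fixes)
        assert flags.empty

    def test_rate_targets_expected_artifact_count(self):
        fixes = self._fixes(500)
        out, flags = inject_gps_artifacts(fixes, 0.1, np.random.default_rng(1))
        assert 20 <= len(flags) <= 90  # ~50 expected
        assert set(flags["kind"]) <= {"far", "speed"}

    def test_cleaning_removes_most_flagged_artifacts(self):
        """Far-outlier fixes must fall to the 1000-m rule; jump events must
        fall to the speed filter: together >= 95% of artifacts removed."""
        fixes = self._fixes(1000)
        out, flags = inject_gps_artifacts(fixes, 0.1, np.random.default_rng(2))
        events = clean_fixes(out)
        kept_events = set(
            zip(events["individual_id"], pd.to_datetime(events["timestamp"]))
        )
        removed = 0
        for r in flags.itertuples():
            if r.kind == "far":
                fix = out[
                    (out["individual_id"] == r.individual_id)
                    & (pd.to_datetime(out["timestamp"]) == pd.Timestamp(r.timestamp))
                ]
                removed += bool((np.hypot(fix["x_m"], fix["y_m"]) > 1000.0).all())
            else:  # speed artifact: its whole event must be gone
                ev = (r.individual_id, pd.Timestamp(r.timestamp).floor("5min"))
                removed += ev not in kept_events
        assert removed >= 0.95 * len(flags)


def test_festival_onset_shift_is_monotone_in_config():
    shifts = []
    for delay in (0.0, 20.0, 60.0):
        cfg = StudyConfig(
            n_individuals=2, pre_days=3, festival_days=3, post_days=0, seed=8,
            effects=EffectConfig(onset_delay_min=delay),
        )
        _, onsets, _ = generate_minutes(cfg)
        cal = cfg.calendar()
        onsets["phase"] = [cal.phase_of(d) for d in onsets["date"]]
        tw = seasonal_twilight(cfg.dates(include_post=True))
        dusk = dict(zip(tw["date"], tw["civil_dusk"]))
        rel = [
            (r.true_onset - dusk[r.date]).total_seconds() / 60
            for r in onsets[onsets["phase"] == "festival"].itertuples()
        ]
        shifts.append(np.mean(rel))
    assert shifts[0] < shifts[1] < shifts[2]


def test_oversize_inmemory_request_is_refused():
    with pytest.raises(ConfigError, match="stream"):
        generate_study(StudyConfig())  # full size must go through write_study


def test_dropout_produces_short_and_missing_bursts():
    cfg = small_config(burst_dropout_rate=0.2, n_individuals=1, post_days=0)
    study = generate_study(cfg)
    sizes = study.bursts.groupby("burst_id").size()
    assert (sizes < cfg.samples_per_burst).any()  # truncated bursts exist
    assert study.bursts["burst_id"].nunique() < cfg.acc_days * cfg.bursts_per_day
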