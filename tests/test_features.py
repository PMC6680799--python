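"""Feature extraction: per-axis moments, spectral weighted mean, attitude,
ODBA, burst validation and the 25-column contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hoglog import (
    FEATURE_COLUMNS,
    attitude,
    featurize,
    odba,
    per_axis_stats,
    spectral_wmean,
    validate_bursts,
)


def make_long(bursts: dict[str, np.ndarray]) -> pd.DataFrame:
    """Long-format table from {burst_id: (n, 3) array}."""
    frames = []
    for bid, w in bursts.items():
        w = np.asarray(w, dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": "id01",
                    "burst_id": bid,
                    "timestamp": pd.Timestamp("2016-08-15 12:00"),
                    "sample_idx": np.arange(len(w)),
                    "ax_g": w[:, 0],
                    "ay_g": w[:, 1],
                    "az_g": w[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestPerAxisStats:
    def test_hand_arithmetic(self):
        s = per_axis_stats([1.0, 2.0, 3.0])
        assert s["mean"] == 2.0
        assert s["var"] == 1.0
        assert s["sd"] == 1.0
        assert s["icv"] == 2.0

    def test_constant_samples_flag_undefined_stats(self):
        s = per_axis_stats([5.0] * 10)
        assert s["sd"] == 0.0
        assert np.isnan(s["icv"])
        assert np.isnan(s["kurtosis"])
        assert np.isnan(s["skewness"])

    def test_normal_sample_moments(self, rng):
        x = rng.standard_normal(2000)
        s = per_axis_stats(x)
        assert s["kurtosis"] == pytest.approx(3.0, abs=0.3)
        assert s["skewness"] == pytest.approx(0.0, abs=0.3)


class TestSpectralWmean:
    def test_pure_tone_recovers_its_frequency(self):
        t = np.arange(250) / 100.0
        assert spectral_wmean(np.sin(2 * np.pi * 2.0 * t), 100.0) == pytest.approx(
            2.0, abs=100.0 / 250
        )

    def test_constant_signal_is_zero_by_convention(self):
        assert spectral_wmean(np.full(250, 0.7), 100.0) == 0.0

    def test_two_equal_lines_average(self):
        t = np.arange(200) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 3.0 * t)
        assert spectral_wmean(x, 100.0) == pytest.approx(2.0, abs=100.0 / 200)


class TestAttitude:
    @pytest.mark.parametrize(
        "static, q, pitch, roll",
        [
            ((0.0, 0.0, 1.0), 1.0, 0.0, 0.0),
            ((1.0, 0.0, 0.0), 1.0, 90.0, 0.0),
            ((0.0, 1 / np.sqrt(2), 1 / np.sqrt(2)), 1.0, 0.0, 45.0),
        ],
    )
    def test_reference_orientations(self, static, q, pitch, roll):
        samples = np.tile(np.asarray(static), (10, 1))
        got_q, got_pitch, got_roll = attitude(samples)
        assert got_q == pytest.approx(q)
        assert got_pitch == pytest.approx(pitch)
        assert got_roll == pytest.approx(roll)

    def test_zero_vector_flags_angles_missing(self):
        q, pitch, roll = attitude(np.zeros((5, 3)))
        assert q == 0.0
        assert np.isnan(pitch) and np.isnan(roll)


class TestOdba:
    def test_constant_burst_is_zero(self):
        assert odba(np.tile([0.1, -0.2, 1.0], (20, 1))) == pytest.approx(0.0, abs=1e-12)

    def test_gravity_offset_invariance(self, rng):
        w = rng.normal(0, 0.3, (100, 3))
        assert odba(w + [0.0, 0.0, 1.0]) == pytest.approx(odba(w))

    def test_sinusoid_closed_form(self):
        # mean |A sin| over whole periods = 2A/pi per axis
        t = np.arange(200) / 100.0
        a = 0.3
        w = np.stack([a * np.sin(2 * np.pi * 2.0 * t)] * 3, axis=1)
        assert odba(w) == pytest.approx(3 * 2 * a / np.pi, rel=0.01)


class TestValidateBursts:
    def test_exact_length_kept(self, rng):
        long = make_long({"b1": rng.normal(size=(264, 3))})
        kept, dropped = validate_bursts(long, expected_n=264)
        assert dropped == []
        assert len(kept) == 264

    def test_underlength_dropped(self, rng):
        long = make_long({"b1": rng.normal(size=(249, 3)), "b2": rng.normal(size=(250, 3))})
        kept, dropped = validate_bursts(long, expected_n=250)
        assert dropped == ["b1"]
        assert set(kept["burst_id"]) == {"b2"}

    def test_overlength_truncated_with_warning(self, rng):
        long = make_long({"b1": rng.normal(size=(251, 3))})
        with pytest.warns(UserWarning, match="truncating"):
            kept, dropped = validate_bursts(long, expected_n=250)
        assert dropped == []
        assert len(kept) == 250


class TestFeaturize:
    def test_three_bursts_give_three_rows_of_25_predictors(self, rng):
        long = make_long({f"b{i}": rng.normal(size=(50, 3)) for i in range(3)})
        tab = featurize(long, expected_n=50)
        assert len(tab) == 3
        assert len(FEATURE_COLUMNS) == 25
        assert list(tab.columns[3:28]) == FEATURE_COLUMNS

    def test_zero_noise_immobile_burst_degenerates_cleanly(self):
        long = make_long({"b1": np.tile([0.0, 0.0, 1.0], (50, 1))})
        tab = featurize(long, expected_n=50)
        row = tab.iloc[0]
        for ax in "xyz":
            assert row[f"sd_{ax}"] == 0.0
            assert row[f"var_{ax}"] == 0.0
        assert row["odba"] == 0.0
        assert bool(row["missing"])  # icv/kurtosis undefined on constant axes

    def test_asd_is_the_sum_of_axis_sds(self, rng):
        long = make_long({f"b{i}": rng.normal(size=(40, 3)) for i in range(4)})
        tab = featurize(long, expected_n=40)
        assert np.allclose(tab["asd"], tab[["sd_x", "sd_y", "sd_z"]].sum(axis=1))

    def test_empty_input_gives_empty_table(self):
        empty = pd.DataFrame(
            columns=["individual_id", "burst_id", "timestamp", "sample_idx",
                     "ax_g", "ay_g", "az_g"]
        )
        tab = featurize(empty, expected_n=50)
        assert tab.empty
        assert set(FEATURE_COLUMNS) <= set(tab.columns)


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.floats(min_value=-2.0, max_value=2.0, allow_nan=False),
        min_size=8,
        max_size=40,
    ),
    seed=st.integers(0, 2**16),
)
def test_order_free_statistics_ignore_sample_order(data, seed):
    """Moments are permutation-invariant; the spectral weighted mean is an
    ordered-signal statistic and in general is not."""
    x = np.asarray(data)
    perm = np.random.default_rng(seed).permutation(len(x))
    a, b = per_axis_stats(x), per_axis_stats(x[perm])
    for key in ("mean", "sd", "var"):
        assert a[key] == pytest.approx(b[key], nan_ok=True)


def test_spectral_wmean_depends_on_sample_order():
    t = np.arange(100) / 100.0
    x = np.sin(2 * np.pi * 3.0 * t)
    shuffled = x[np.random.default_rng(1).permutation(100)]
    assert abs(spectral_wmean(x, 100.0) - spectral_wmean(shuffled, 100.0)) > 1.0
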