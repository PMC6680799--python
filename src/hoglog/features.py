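"""Burst validation and the 25-predictor feature set.

Each one-minute accelerometer burst (2.5 s or 2.64 s of triaxial data at
100 Hz) is summarised by 25 predictors: per axis, mean, standard deviation,
inverse coefficient of variation (mean/sd), variance, kurtosis, skewness and
the weighted mean of the autocorrelated power spectrum (21 values); across
axes, the static vector norm q, pitch, roll and overall dynamic body
acceleration ODBA (4 values).  The accumulated SD (aSD = sd_x + sd_y + sd_z)
is carried alongside as the activity proxy for the rhythm metrics; it is not
itself a model predictor.

Conventions (declared, since the field literature admits variants):

* sd and variance use the n-1 denominator;
* kurtosis is the raw standardized fourth moment (a normal sample gives ~3,
  not ~0); skewness the standardized third moment, both with biased central
  moments;
* pitch = atan2(s_x, sqrt(s_y^2 + s_z^2)), roll = atan2(s_y, s_z), in
  degrees, where s is the per-axis burst mean (x forward, z up);
* the static/dynamic split for ODBA uses the whole-burst mean — bursts are
  shorter than any usual running-mean window;
* a burst with fewer samples than expected on any axis is dropped; an
  over-length burst is truncated to the expected count with a warning.

Degenerate values (sd = 0 making icv/skewness/kurtosis undefined, |s| = 0
making pitch/roll undefined) become NaN plus a per-row missing flag rather
than infinities, keeping downstream model matrices finite.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")
PER_AXIS_STATS = ("mean", "sd", "icv", "var", "kurtosis", "skewness", "spectral_wmean")

#: The 25 predictor columns, in fixed order.
FEATURE_COLUMNS = [f"{stat}_{ax}" for ax in AXES for stat in PER_AXIS_STATS] + [
    "q",
    "pitch",
    "roll",
    "odba",
]


# ---------------------------------------------------------------------------
# single-burst operations
# ---------------------------------------------------------------------------

def per_axis_stats(x: np.ndarray) -> dict[str, float]:
    """Mean, sd, icv, variance, kurtosis and skewness of one axis."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("per-axis statistics require at least 2 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd > 0.0:
        icv = mean / sd
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        skew = float(stats.skew(x, bias=True))
    else:
        icv = kurt = skew = float("nan")
    return {
        "mean": mean,
        "sd": sd,
        "icv": icv,
        "var": sd**2,
        "kurtosis": kurt,
        "skewness": skew,
    }


def spectral_wmean(x: np.ndarray, hz: float) -> float:
    """Weighted mean frequency (Hz) of the autocorrelated power spectrum.

    The axis is mean-centred, autocorrelated (biased, normalized, circular),
    and the magnitude spectrum of the autocorrelation is used as the weight:
    sum(f * P(f)) / sum(P(f)) over positive frequencies, DC excluded.  An
    all-zero power spectrum (constant signal) returns 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("spectral_wmean requires at least 4 samples")
    xc = x - x.mean()
    power0 = np.abs(np.fft.rfft(xc)) ** 2
    if not np.any(power0 > 0.0):
        return 0.0
    acf = np.fft.irfft(power0, n=n) / n
    acf = acf / acf[0]
    p = np.abs(np.fft.rfft(acf))
    freqs = np.fft.rfftfreq(n, d=1.0 / hz)
    p = p[1:]
    freqs = freqs[1:]
    total = p.sum()
    if total <= 0.0:
        return 0.0
    return float(np.sum(freqs * p) / total)


def attitude(samples: np.ndarray) -> tuple[float, float, float]:
    """Static attitude of one burst: (q, pitch_deg, roll_deg).

    q is the Euclidean norm of the per-axis burst mean (in g); pitch and roll
    are derived from the same static vector.  A zero static vector leaves
    pitch/roll undefined (NaN).
    """
    samples = np.asarray(samples, dtype=float)
    s = samples.mean(axis=0)
    q = float(np.linalg.norm(s))
    if q == 0.0:
        return 0.0, float("nan"), float("nan")
    pitch = float(np.degrees(np.arctan2(s[0], np.hypot(s[1], s[2]))))
    roll = float(np.degrees(np.arctan2(s[1], s[2])))
    return q, pitch, roll


def odba(samples: np.ndarray) -> float:
    """Overall dynamic body acceleration of one burst (g).

    Static component = per-axis burst mean; ODBA is the mean over samples of
    the summed absolute dynamic (static-removed) acceleration.  Invariant
    under any constant offset, e.g. re-orienting gravity.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2:
        raise ValueError("odba requires at least 2 samples")
    dyn = samples - samples.mean(axis=0)
    return float(np.abs(dyn).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

def validate_bursts(
    bursts: pd.DataFrame, expected_n: int
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the completeness rule to a long-format burst table.

    Bursts with fewer than ``expected_n`` samples on any axis are dropped
    (their ids are returned and logged); over-length bursts are truncated to
    ``expected_n`` with a warning.  Validation never raises on data content.
    """
    counts = bursts.groupby("burst_id", sort=False)["sample_idx"].size()
    short = counts.index[counts < expected_n].tolist()
    if short:
        logger.info("dropping %d under-length bursts: %s", len(short), short[:10])
    over = counts.index[counts > expected_n]
    kept = bursts[~bursts["burst_id"].isin(short)]
    if len(over):
        warnings.warn(
            f"truncating {len(over)} over-length bursts to {expected_n} samples",
            stacklevel=2,
        )
        kept = kept[kept["sample_idx"] < expected_n]
    return kept.reset_index(drop=True), short


def _spectral_wmean_batch(X: np.ndarray, hz: float) -> np.ndarray:
    """Vectorized spectral_wmean over rows of X (n_bursts, n_samples)."""
    n = X.shape[1]
    xc = X - X.mean(axis=1, keepdims=True)
    power0 = np.abs(np.fft.rfft(xc, axis=1)) ** 2
    acf = np.fft.irfft(power0, n=n, axis=1) / n
    r0 = acf[:, :1].copy()
    ok = r0[:, 0] > 0.0
    r0[~ok] = 1.0
    acf = acf / r0
    p = np.abs(np.fft.rfft(acf, axis=1))[:, 1:]
    freqs = np.fft.rfftfreq(n, d=1.0 / hz)[1:]
    total = p.sum(axis=1)
    out = np.zeros(X.shape[0])
    nz = ok & (total > 0.0)
    out[nz] = (p[nz] * freqs).sum(axis=1) / total[nz]
    return out


def featurize(
    bursts: pd.DataFrame, expected_n: int, hz: float = 100.0
) -> pd.DataFrame:
    """Compute the feature table from a validated long-format burst table.

    One row per burst: identifiers, the 25 predictors (``FEATURE_COLUMNS``
    order), aSD, and a ``missing`` flag marking rows with any undefined
    predictor.  Flagged rows are kept — their aSD still feeds the rhythm
    metrics — but should be excluded from classifier training.
    """
    id_cols = ["individual_id", "burst_id", "timestamp"]
    if bursts.empty:
        return pd.DataFrame(
            columns=id_cols + FEATURE_COLUMNS + ["asd", "n_samples", "missing"]
        )
    bursts = bursts.sort_values(["burst_id", "sample_idx"], kind="stable")
    counts = bursts.groupby("burst_id", sort=False)["sample_idx"].size()
    if counts.nunique() != 1 or counts.iloc[0] != expected_n:
        raise ValueError(
            "featurize expects validated bursts of uniform length; "
            "run validate_bursts first"
        )
    ids = bursts.drop_duplicates("burst_id")[id_cols].reset_index(drop=True)
    n_bursts = len(ids)
    X = np.empty((n_bursts, expected_n, 3))
    for k, col in enumerate(("ax_g", "ay_g", "az_g")):
        X[:, :, k] = bursts[col].to_numpy().reshape(n_bursts, expected_n)

    out = ids.copy()
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        icv = np.where(sd > 0.0, mean / sd, np.nan)
    with warnings.catch_warnings():
        # constant axes trigger scipy's precision warning; they are flagged
        # as missing below, so the warning carries no information here
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = np.where(sd > 0.0, stats.kurtosis(X, axis=1, fisher=False, bias=True), np.nan)
        skew = np.where(sd > 0.0, stats.skew(X, axis=1, bias=True), np.nan)
    for k, ax in enumerate(AXES):
        out[f"mean_{ax}"] = mean[:, k]
        out[f"sd_{ax}"] = sd[:, k]
        out[f"icv_{ax}"] = icv[:, k]
        out[f"var_{ax}"] = sd[:, k] ** 2
        out[f"kurtosis_{ax}"] = kurt[:, k]
        out[f"skewness_{ax}"] = skew[:, k]
        out[f"spectral_wmean_{ax}"] = _spectral_wmean_batch(X[:, :, k], hz)

    q = np.linalg.norm(mean, axis=1)
    with np.errstate(invalid="ignore"):
        pitch = np.degrees(np.arctan2(mean[:, 0], np.hypot(mean[:, 1], mean[:, 2])))
        roll = np.degrees(np.arctan2(mean[:, 1], mean[:, 2]))
    pitch = np.where(q > 0.0, pitch, np.nan)
    roll = np.where(q > 0.0, roll, np.nan)
    out["q"] = q
    out["pitch"] = pitch
    out["roll"] = roll
    dyn = X - mean[:, None, :]
    out["odba"] = np.abs(dyn).sum(axis=2).mean(axis=1)
    out["asd"] = sd.sum(axis=1)
    out["n_samples"] = expected_n
    out["missing"] = out[FEATURE_COLUMNS].isna().any(axis=1)
    return out[id_cols + FEATURE_COLUMNS + ["asd", "n_samples", "missing"]]
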