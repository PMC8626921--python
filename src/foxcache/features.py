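"""Summary-statistic features of a 3-s tri-axial acceleration window.

Each window is reduced to 52 real-valued statistics spanning the
families conventionally used for accelerometry-based behaviour
classification: per-axis moments and extrema, dynamic-range statistics,
cross-axis association, and dynamic-body-acceleration summaries.

Concretely, per axis (sway, surge, heave; 13 each, 39 total): mean, SD,
skewness, kurtosis, min, max, range, mean absolute deviation, RMS,
mean-crossing count, 25th percentile, 75th percentile, mean absolute
first difference. Per axis pair (3 pairs, 2 each): Pearson correlation
and covariance. Whole-signal (7): ODBA mean/SD/max, VeDBA mean/SD, and
acceleration vector-magnitude mean/SD, where per sample
ODBA = sum_axes |a - axis mean| and VeDBA = sqrt(sum_axes (a - mean)^2).

Conventions (fixed so that an independent reference implementation can
reproduce every value exactly): SD, covariance and the moment-based
skewness/kurtosis use population normalisation (divide by n); kurtosis
is the raw standardized fourth moment m4/m2^2 (not excess); percentiles
use linear interpolation; a mean crossing is a change of the predicate
(x - mean) > 0 between consecutive samples; zero-variance axes report
correlation 0 rather than NaN so downstream classifiers always receive
finite inputs.
"""

from __future__ import annotations

import numpy as np

AXES = ("sway", "surge", "heave")
_PER_AXIS = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "min",
    "max",
    "range",
    "mad",
    "rms",
    "mean_crossings",
    "q25",
    "q75",
    "mean_abs_diff",
)
_PAIRS = (("sway", "surge"), ("sway", "heave"), ("surge", "heave"))
_GLOBAL = (
    "odba_mean",
    "odba_sd",
    "odba_max",
    "vedba_mean",
    "vedba_sd",
    "magnitude_mean",
    "magnitude_sd",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{axis}_{stat}" for axis in AXES for stat in _PER_AXIS
) + tuple(
    f"{a}_{b}_{stat}" for a, b in _PAIRS for stat in ("corr", "cov")
) + _GLOBAL

assert len(FEATURE_NAMES) == 52

N_FEATURES = len(FEATURE_NAMES)


def compute_feature_matrix(signals: np.ndarray) -> np.ndarray:
    """Feature matrix for a batch of windows.

    Parameters
    ----------
    signals
        Array of shape ``(n_windows, 3, n_samples)`` with axis order
        (sway, surge, heave), in g.

    Returns
    -------
    ``(n_windows, 52)`` float array, columns ordered as FEATURE_NAMES.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 3 or x.shape[1] != 3:
        raise ValueError("signals must have shape (n_windows, 3, n_samples)")
    if x.shape[2] < 2:
        raise ValueError("windows must contain at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")

    n = x.shape[2]
    mean = x.mean(axis=2)
    centered = x - mean[:, :, None]
    m2 = (centered**2).mean(axis=2)
    sd = np.sqrt(m2)
    # centring a constant axis leaves ~1-ulp residue; treat it as zero
    # variance so correlations/skewness stay at their degenerate values
    constant = sd <= 1e-12 * (np.abs(mean) + 1.0)
    sd = np.where(constant, 0.0, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        m3 = (centered**3).mean(axis=2)
        m4 = (centered**4).mean(axis=2)
        ok = ~constant
        skew = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2, 0.0)
    amin = x.min(axis=2)
    amax = x.max(axis=2)
    mad = np.abs(centered).mean(axis=2)
    rms = np.sqrt((x**2).mean(axis=2))
    positive = centered > 0
    crossings = (positive[:, :, 1:] != positive[:, :, :-1]).sum(axis=2).astype(float)
    q25 = np.percentile(x, 25, axis=2)
    q75 = np.percentile(x, 75, axis=2)
    madiff = np.abs(np.diff(x, axis=2)).mean(axis=2)

    per_axis = np.stack(
        [
            mean,
            sd,
            skew,
            kurt,
            amin,
            amax,
            amax - amin,
            mad,
            rms,
            crossings,
            q25,
            q75,
            madiff,
        ],
        axis=2,
    )  # (n_win, 3, 13)
    per_axis = per_axis.reshape(x.shape[0], -1)

    pair_cols = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        cov = (centered[:, a, :] * centered[:, b, :]).mean(axis=1)
        denom = sd[:, a] * sd[:, b]
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
        pair_cols.extend([corr, cov])
    pairs = np.stack(pair_cols, axis=1)

    odba = np.abs(centered).sum(axis=1)  # (n_win, n_samples)
    vedba = np.sqrt((centered**2).sum(axis=1))
    magnitude = np.sqrt((x**2).sum(axis=1))
    globals_ = np.stack(
        [
            odba.mean(axis=1),
            odba.std(axis=1),
            odba.max(axis=1),
            vedba.mean(axis=1),
            vedba.std(axis=1),
            magnitude.mean(axis=1),
            magnitude.std(axis=1),
        ],
        axis=1,
    )

    out = np.concatenate([per_axis, pairs, globals_], axis=1)
    assert out.shape[1] == N_FEATURES
    return out


def compute_features(sway: np.ndarray, surge: np.ndarray, heave: np.ndarray) -> np.ndarray:
    """52-statistic feature vector of one window (axes in g)."""
    sway, surge, heave = (np.asarray(a, dtype=float) for a in (sway, surge, heave))
    if not (sway.shape == surge.shape == heave.shape) or sway.ndim != 1:
        raise ValueError("axes must be equal-length 1-D arrays")
    return compute_feature_matrix(np.stack([sway, surge, heave])[None])[0]
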