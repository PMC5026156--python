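"""Test-retest reliability metrics.

Covers the agreement metrics for activation maps (pattern correlation,
R_QUANTITY, R_OVERLAP), one-way random-effects intraclass correlations in
single-session and k-session-average forms (with Spearman-Brown linking
the two), ROI cluster averaging, block-averaged response time courses and
their between-session correlation, paired t tests with Cohen's d for
paired observations, and the conventional qualitative bands
(poor / fair / good / excellent).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError

#: Qualitative interpretation bands for reliability coefficients
#: (Cicchetti-style): poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent.
RELIABILITY_BANDS = (
    (0.40, "poor"),
    (0.60, "fair"),
    (0.75, "good"),
    (np.inf, "excellent"),
)

#: Effect-size bands for Cohen's d: negligible < 0.20 <= small < 0.50 <=
#: medium < 0.80 <= large.
EFFECT_SIZE_BANDS = (
    (0.20, "negligible"),
    (0.50, "small"),
    (0.80, "medium"),
    (np.inf, "large"),
)


def r_quantity(a1: int, a2: int) -> float:
    """Reproducibility of the *quantity* of significant channels.

    R_QUANTITY = 1 - |A1 - A2| / (A1 + A2); NaN (reported as missing)
    when no channel is significant at either session.
    """
    a1, a2 = int(a1), int(a2)
    if a1 < 0 or a2 < 0:
        raise InputError("channel counts must be non-negative")
    if a1 + a2 == 0:
        return float("nan")
    return 1.0 - abs(a1 - a2) / (a1 + a2)


def r_overlap(a1: int, a2: int, a_overlap: int) -> float:
    """Reproducibility of the *location* of significant channels.

    R_OVERLAP = 2 * A_OVERLAP / (A1 + A2); NaN when A1 + A2 = 0.
    """
    a1, a2, a_overlap = int(a1), int(a2), int(a_overlap)
    if min(a1, a2, a_overlap) < 0:
        raise InputError("channel counts must be non-negative")
    if a_overlap > min(a1, a2):
        raise InputError(
            f"overlap count {a_overlap} exceeds min(A1, A2) = {min(a1, a2)}"
        )
    if a1 + a2 == 0:
        return float("nan")
    return 2.0 * a_overlap / (a1 + a2)


def overlap_counts(significant1, significant2) -> tuple:
    """(A1, A2, A_OVERLAP) from two collections of significant channels."""
    s1, s2 = set(significant1), set(significant2)
    return len(s1), len(s2), len(s1 & s2)


def pattern_correlation(map1, map2) -> float:
    """Pearson correlation between two per-channel t maps.

    NaN when either map has zero variance (undefined, reported missing).
    """
    x = np.asarray(map1, dtype=float)
    y = np.asarray(map2, dtype=float)
    if x.shape != y.shape:
        raise InputError("maps must share the channel set")
    if x.size < 3:
        raise InputError("need at least 3 channels for a pattern correlation")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


#: Alias: the same product-moment correlation applied over time samples of
#: block-averaged response time courses.
timecourse_correlation = pattern_correlation


@dataclass(frozen=True)
class ICCResult:
    """One-way random-effects ICCs with pre-clamp values retained.

    ``icc_single`` is the single-session reliability ICC(1) =
    (BMS - WMS) / (BMS + (k-1) WMS); ``icc_average`` the reliability of
    the k-session mean, ICC(k) = (BMS - WMS)/BMS. Negative estimates
    (sampling noise; no theoretical meaning) are clamped to 0 in the
    reported fields; the raw values are kept for identity checks.
    """

    icc_single: float
    icc_average: float
    icc_single_raw: float
    icc_average_raw: float
    bms: float
    wms: float
    n_subjects: int
    n_sessions: int


def icc_oneway(matrix) -> ICCResult:
    """One-way random-effects ICCs from a subjects x sessions matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InputError("need a (subjects >= 2) x (sessions >= 2) matrix")
    if np.any(np.isnan(X)):
        raise InputError("ICC input must have no missing cells")
    n, k = X.shape
    row_means = X.mean(axis=1)
    grand = X.mean()
    bms = k * np.sum((row_means - grand) ** 2) / (n - 1)
    wms = np.sum((X - row_means[:, None]) ** 2) / (n * (k - 1))
    denom_single = bms + (k - 1) * wms
    if denom_single == 0.0:
        single_raw = float("nan")
        avg_raw = float("nan")
    else:
        single_raw = (bms - wms) / denom_single
        with np.errstate(divide="ignore", invalid="ignore"):
            avg_raw = (bms - wms) / bms if bms > 0 else -np.inf
    return ICCResult(
        icc_single=float(max(single_raw, 0.0)) if np.isfinite(single_raw) else float("nan"),
        icc_average=float(max(avg_raw, 0.0)) if not np.isnan(avg_raw) else float("nan"),
        icc_single_raw=float(single_raw),
        icc_average_raw=float(avg_raw),
        bms=float(bms),
        wms=float(wms),
        n_subjects=n,
        n_sessions=k,
    )


def icc_average_from_single(icc_single: float, k: int = 2) -> float:
    """Spearman-Brown step-up: the ICC of a k-session average implied by a
    single-session ICC under the one-way random-effects model,
    ICC(k) = k*ICC(1) / (1 + (k-1)*ICC(1))."""
    if k < 1:
        raise InputError("k must be >= 1")
    return k * icc_single / (1.0 + (k - 1) * icc_single)


def cluster_amplitude(betas, roi_channels) -> np.ndarray:
    """Unweighted mean of member-channel betas (ROI cluster amplitude).

    ``betas`` has shape (observations, n_channels) with 1-based ROI
    channel numbers indexing the columns.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    idx = np.asarray(roi_channels, dtype=int) - 1
    if np.any(idx < 0) or np.any(idx >= betas.shape[1]):
        raise InputError(
            f"ROI channels {tuple(roi_channels)} outside the available 1..{betas.shape[1]}"
        )
    return betas[:, idx].mean(axis=1)


def block_average(series, fs: float, onsets, window_s=(-5.0, 40.0),
                  baseline_s=(-5.0, 0.0)):
    """Baseline-corrected average response epoch across stimulation blocks.

    Epochs of ``window_s`` (relative to onset) are extracted at each
    block onset, the mean over ``baseline_s`` is subtracted per epoch,
    and epochs are averaged. Epochs that would run outside the recording
    are excluded with a warning; if every epoch is excluded an
    ``InputError`` is raised.

    Returns ``(epoch_time, mean_epoch)``.
    """
    x = np.asarray(series, dtype=float).ravel()
    i_pre = int(round(window_s[0] * fs))
    i_post = int(round(window_s[1] * fs))
    if i_post <= i_pre:
        raise InputError("epoch window must have positive length")
    b0 = int(round(baseline_s[0] * fs)) - i_pre
    b1 = int(round(baseline_s[1] * fs)) - i_pre
    epochs = []
    for onset in onsets:
        i0 = int(round(onset * fs))
        lo, hi = i0 + i_pre, i0 + i_post
        if lo < 0 or hi > len(x):
            warnings.warn(
                f"epoch at onset {onset} s exceeds the recording bounds; excluded",
                stacklevel=2,
            )
            continue
        epoch = x[lo:hi].copy()
        if b1 > b0:
            epoch -= epoch[b0:b1].mean()
        epochs.append(epoch)
    if not epochs:
        raise InputError("all epochs fall outside the recording")
    epoch_time = np.arange(i_pre, i_post) / fs
    return epoch_time, np.mean(epochs, axis=0)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    d: float  # Cohen's d for paired observations, signed (session2 - session1)
    direction: str  # "+ve" if amplitude larger at session 2, else "-ve"


def paired_test(session1, session2) -> PairedTestResult:
    """Paired t test across subjects with Cohen's d for paired observations.

    d = mean(differences) / SD(differences) with differences taken as
    session2 - session1 (so a positive d means a stronger response at the
    second session). A zero-variance difference with non-zero mean is
    flagged with an infinite d; with zero mean, d = 0.
    """
    x1 = np.asarray(session1, dtype=float).ravel()
    x2 = np.asarray(session2, dtype=float).ravel()
    if x1.shape != x2.shape or x1.size < 2:
        raise InputError("need equal-length paired samples with n >= 2")
    diff = x2 - x1
    sd = diff.std(ddof=1)
    mean = diff.mean()
    direction = "+ve" if mean > 0 else "-ve"
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(t=0.0, p=1.0, d=0.0, direction="-ve")
        t = np.inf * np.sign(mean)
        return PairedTestResult(t=float(t), p=0.0, d=float(np.inf * np.sign(mean)),
                                direction=direction)
    n = diff.size
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(t=float(t), p=float(p), d=float(mean / sd),
                            direction=direction)


def _classify(value: float, bands) -> str:
    for upper, label in bands:
        if value < upper:
            return label
    return bands[-1][1]


def classify_reliability(value: float) -> str:
    """Qualitative label for a reliability coefficient in [-1, 1].

    Values below 0.40 (including all negatives) are "poor"; NaN inputs
    (undefined metrics) return "n/a".
    """
    if np.isnan(value):
        return "n/a"
    if value > 1.0 or value < -1.0:
        raise InputError(f"reliability coefficient {value} outside [-1, 1]")
    return _classify(value, RELIABILITY_BANDS)


def classify_effect_size(d: float) -> str:
    """Qualitative label for |Cohen's d|."""
    if np.isnan(d):
        return "n/a"
    return _classify(abs(d), EFFECT_SIZE_BANDS)
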