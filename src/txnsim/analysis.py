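"""Summary statistics of transcription and network trajectories.

Implements the trajectory measures used throughout the package: intervals
between transcript completions, microburst statistics (two or more RNAs
completed within a window much shorter than the mean initiation interval),
the coefficient of variation as noise measure, the initial transient of a
protein series, deterministic 1-D 2-means binarization, the 3-tuple Shannon
entropy of the binarized repressilator proteins (natural log), and a
crossing-based oscillation-period estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "MicroburstStats",
    "AnalysisResult",
    "completion_intervals",
    "microburst_stats",
    "coefficient_of_variation",
    "initial_transient",
    "kmeans_binarize",
    "tuple_entropy",
    "estimate_period",
]

#: Default microburst window, seconds; must stay below the ~40 s mean
#: open-complex delay for the episode definition to be meaningful.
MICROBURST_WINDOW = 5.0


@dataclass(frozen=True)
class MicroburstStats:
    """Microburst summary of a completion-time sequence.

    An *episode* is a maximal run of consecutive completions whose
    successive gaps are all shorter than the window and which contains at
    least two completions.  ``fraction_fast_intervals`` is the fraction of
    all gaps shorter than the window; ``largest_burst_size`` is the largest
    number of completions in one episode (1 when no episode exists).
    """

    episode_count: int
    fraction_fast_intervals: float
    largest_burst_size: int
    window: float = MICROBURST_WINDOW


@dataclass(frozen=True)
class AnalysisResult:
    cv: float | None = None
    transient: float | None = None
    entropy: float | None = None
    period: float | None = None
    microbursts: MicroburstStats | None = None


def completion_intervals(completion_times) -> np.ndarray:
    """First-order differences of the sorted completion times (seconds)."""
    t = np.sort(np.asarray(completion_times, dtype=float))
    if t.size < 2:
        return np.empty(0)
    return np.diff(t)


def microburst_stats(completion_times, window: float = MICROBURST_WINDOW) -> MicroburstStats:
    """Count microburst episodes among transcript completion times."""
    if window <= 0:
        raise ValueError("window must be positive")
    if window >= 40.0:
        warnings.warn(
            "microburst window is not smaller than the mean open-complex "
            "delay; episodes lose their meaning",
            stacklevel=2,
        )
    gaps = completion_intervals(completion_times)
    if gaps.size == 0:
        return MicroburstStats(0, 0.0, 1 if len(completion_times) else 0, window)
    fast = gaps < window
    episodes = 0
    largest = 1
    run = 1
    for f in fast:
        if f:
            run += 1
        else:
            if run >= 2:
                episodes += 1
                largest = max(largest, run)
            run = 1
    if run >= 2:
        episodes += 1
        largest = max(largest, run)
    return MicroburstStats(episodes, float(fast.mean()), largest, window)


def coefficient_of_variation(series) -> float:
    """Population standard deviation over the mean of the sampled series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    m = x.mean()
    if m == 0:
        raise ValueError("zero-mean series: CV undefined")
    return float(x.std() / m)


def initial_transient(series, sample_dt: float, t0: float = 0.0) -> float:
    """Time at which the series first reaches its whole-series mean.

    The response-speed measure of a gene switched on at ``t0``: the first
    sample at or above the mean level over the full simulated window.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    idx = np.nonzero(x >= x.mean())[0]
    if idx.size == 0:  # pragma: no cover - impossible for finite series
        raise ValueError("series never reaches its own mean")
    return t0 + float(idx[0]) * sample_dt


def kmeans_binarize(series) -> np.ndarray:
    """Deterministic 1-D 2-means binarization (label 1 = upper cluster).

    Lloyd iterations start from the (min, max) centroids, so the result is
    reproducible and invariant to positive affine rescaling.  A constant
    series yields all zeros with a warning.
    """
    x = np.asarray(series, dtype=float).reshape(-1, 1)
    if x.size < 2 or np.ptp(x) == 0:
        warnings.warn("constant series: binarization is all zeros", stacklevel=2)
        return np.zeros(x.size, dtype=int)
    km = KMeans(
        n_clusters=2,
        init=np.array([[x.min()], [x.max()]]),
        n_init=1,
        max_iter=300,
    ).fit(x)
    labels = km.labels_
    if km.cluster_centers_[0, 0] > km.cluster_centers_[1, 0]:
        labels = 1 - labels
    return labels.astype(int)


def tuple_entropy(b1, b2, b3) -> float:
    """Shannon entropy (nats) of the joint 3-tuple binary state frequencies.

    With three binarized series there are eight joint states; the entropy of
    their empirical distribution is 0 for a frozen state and ln 8 for the
    uniform case.  For a healthy oscillator with three anti-phased square
    waves, six of the eight states dominate roughly equally.
    """
    b1, b2, b3 = (np.asarray(b, dtype=int) for b in (b1, b2, b3))
    if not (b1.shape == b2.shape == b3.shape) or b1.ndim != 1:
        raise ValueError("the three series must be 1-D and equal length")
    if b1.size == 0:
        raise ValueError("empty series")
    state = b1 * 4 + b2 * 2 + b3
    counts = np.bincount(state, minlength=8)
    return float(stats.entropy(counts))


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")


def estimate_period(
    series, sample_dt: float, smooth_window: int = 5
) -> float:
    """Mean oscillation period from upward midrange crossings, seconds.

    The series is smoothed with a ``smooth_window``-sample moving average
    (shorter than a quarter period at the default 100 s sampling) and the
    mean interval between successive upward crossings of the smoothed
    midrange is returned.  ``series`` may be a single trace or a sequence of
    traces (e.g. the three repressilator proteins), in which case the
    per-trace estimates are averaged.

    Raises ``ValueError`` when fewer than two crossings exist (no period
    detectable).
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        return float(
            np.mean([estimate_period(row, sample_dt, smooth_window) for row in arr])
        )
    x = _smooth(arr, smooth_window)
    if x.size < 3 or np.ptp(x) == 0:
        raise ValueError("no period detectable")
    mid = 0.5 * (x.min() + x.max())
    above = x >= mid
    up = np.nonzero(~above[:-1] & above[1:])[0]
    if up.size < 2:
        raise ValueError("no period detectable")
    return float(np.mean(np.diff(up)) * sample_dt)
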