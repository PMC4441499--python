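"""Surface-EMG screening and burst-onset measurement.

The rectified trace is summarized in 100 ms bins, each the mean of a 300 ms
moving-average window centred on the bin (truncated at the trace edges).
The pre-stimulus portion defines a baseline threshold (mean + 2 SD of the
rectified baseline samples).  A trial shows "significant EMG activity" when
a post-stimulus bin exceeds the threshold AND its raw rectified samples
differ from baseline by a two-sample t-test; covert-condition trials that
screen positive are discarded upstream.  On active Go trials the burst
onset is the threshold crossing of a short (25 ms) moving average of the
rectified trace, searched from the start of the first suprathreshold bin
and refined by linear interpolation to ms resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidArgumentError
from .synth import EmgTrace


@dataclass
class EmgEnvelope:
    bins: np.ndarray          # one value per 100 ms epoch, >= 0
    bin_centers_ms: np.ndarray
    baseline_mean: float
    baseline_sd: float
    threshold: float          # baseline_mean + 2 * baseline_sd
    fs: float
    window: tuple[float, float]
    rectified: np.ndarray     # |signal|, kept for the t-test and onset search

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + 1000.0 / self.fs * np.arange(len(self.rectified))


def envelope(trace: EmgTrace, bin_ms: float = 100.0,
             smooth_ms: float = 300.0) -> EmgEnvelope:
    """Binned moving-average envelope plus the baseline threshold."""
    t0, t1 = trace.window
    if t1 - t0 < bin_ms:
        raise InvalidArgumentError("trace shorter than one bin")
    rect = np.abs(np.asarray(trace.samples, dtype=float))
    times = t0 + 1000.0 / trace.fs * np.arange(rect.size)
    n_bins = int(round((t1 - t0) / bin_ms))
    centers = t0 + bin_ms * (np.arange(n_bins) + 0.5)
    half = smooth_ms / 2.0
    bins = np.empty(n_bins)
    for i, c in enumerate(centers):
        sel = (times >= c - half) & (times < c + half)  # truncated at edges
        bins[i] = rect[sel].mean()
    base = rect[times < 0.0]
    if base.size == 0:
        raise InvalidArgumentError("no baseline portion before 0 ms")
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    return EmgEnvelope(bins, centers, mu, sd, mu + 2.0 * sd,
                       trace.fs, trace.window, rect)


def baseline_threshold(env: EmgEnvelope) -> float:
    """Mean + 2 SD of the rectified baseline samples."""
    return env.threshold


def screen_trial(env: EmgEnvelope, alpha: float = 0.01) -> bool:
    """Flag a trial as showing significant post-stimulus EMG activity.

    Requires both a post-stimulus bin above the baseline threshold and a
    two-sample t-test (suprathreshold-bin samples vs baseline samples)
    significant at ``alpha``.  With degenerate variance the threshold rule
    alone decides.
    """
    post = env.bin_centers_ms > 0
    if not np.any(post):
        raise InvalidArgumentError("no post-stimulus bins")
    above = post & (env.bins > env.threshold)
    if not np.any(above):
        return False
    times = env.times
    base = env.rectified[times < 0.0]
    sel = np.zeros(times.size, dtype=bool)
    for c in env.bin_centers_ms[above]:
        sel |= (times >= c - 50.0) & (times < c + 50.0)
    active = env.rectified[sel]
    if base.std(ddof=1) == 0 and active.std(ddof=1) == 0:
        return True  # threshold-only fallback
    _, p = sps.ttest_ind(active, base, equal_var=False)
    return bool(p < alpha)


def go_onset(env: EmgEnvelope, refine_ms: float = 25.0,
             alpha: float = 0.01) -> float | None:
    """Burst-onset latency (ms re target onset) on an active trial.

    Returns None when the trial screens inactive or the refined envelope
    never crosses the threshold.
    """
    if not screen_trial(env, alpha):
        return None
    post = env.bin_centers_ms > 0
    above = post & (env.bins > env.threshold)
    first_bin_start = float(env.bin_centers_ms[above][0] - 50.0)
    # short centred moving average for sample-level refinement
    n_win = max(1, int(round(refine_ms / 1000.0 * env.fs)))
    kernel = np.ones(n_win) / n_win
    smooth = np.convolve(env.rectified, kernel, mode="same")
    times = env.times
    idx = np.nonzero(times >= first_bin_start)[0]
    seg = smooth[idx]
    over = seg > env.threshold
    if not np.any(over):
        return None
    j = int(np.argmax(over))
    if j == 0:
        return float(times[idx[0]])
    t_prev, t_cur = times[idx[j - 1]], times[idx[j]]
    v_prev, v_cur = seg[j - 1], seg[j]
    frac = (env.threshold - v_prev) / (v_cur - v_prev)
    return float(t_prev + frac * (t_cur - t_prev))
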