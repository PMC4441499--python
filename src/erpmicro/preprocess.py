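"""From continuous recordings to artifact-screened, average-referenced ERPs.

The chain mirrors standard evoked-potential practice: zero-phase band-pass
(1-30 Hz) with a 50 Hz notch, re-reference to the common average, epoching
around target onsets, amplitude-based artifact rejection (65 uV), a
minimum-trial rule per subject and condition (40 artifact-free trials), and
per-subject / group averaging.  Bad channels are rebuilt by spherical-spline
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .containers import ContinuousRecording, EpochSet, Erp, n_samples_for
from .errors import EmptyAverageError, InvalidArgumentError

# ---------------------------------------------------------------------------
# filtering and referencing
# ---------------------------------------------------------------------------


def bandpass(rec: ContinuousRecording, low: float = 1.0, high: float = 30.0,
             notch: float | None = 50.0, order: int = 2,
             notch_width: float = 2.0) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass plus optional notch.

    ``order`` is the one-pass Butterworth order; forward-backward filtering
    doubles the effective order and cancels phase distortion, which matters
    for latency measures.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise InvalidArgumentError(f"cutoffs must satisfy 0 < {low} < {high} < {nyq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None and notch < nyq:
        b, a = signal.iirnotch(notch, notch / notch_width, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return replace(rec, data=out)


def average_reference(x):
    """Re-reference to the common average (per-sample channel mean removed)."""
    if isinstance(x, Erp):
        if x.data.shape[0] < 2:
            raise InvalidArgumentError("average reference needs >= 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=0, keepdims=True))
    if isinstance(x, EpochSet):
        if x.data.shape[1] < 2:
            raise InvalidArgumentError("average reference needs >= 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=1, keepdims=True))
    if isinstance(x, ContinuousRecording):
        if x.data.shape[0] < 2:
            raise InvalidArgumentError("average reference needs >= 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=0, keepdims=True))
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[0] < 2:
        raise InvalidArgumentError("average reference needs >= 2 channels")
    return arr - arr.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# epoching and screening
# ---------------------------------------------------------------------------


def extract_epochs(rec: ContinuousRecording, codes,
                   window: tuple[float, float] = (-200.0, 700.0),
                   condition: str = "") -> EpochSet:
    """Cut one epoch per matching event; the event sample is t = 0.

    Events too close to a recording edge are kept in the set but flagged
    (``kept=False``, reason "edge") rather than silently dropped.
    """
    codes = {codes} if isinstance(codes, str) else set(codes)
    n_samp = n_samples_for(window, rec.fs)
    pre = int(round(-window[0] / 1000.0 * rec.fs))
    n_chan, n_total = rec.data.shape
    trials, kept, reasons = [], [], []
    for sample, code in rec.events:
        if code not in codes:
            continue
        start = sample - pre
        if start < 0 or start + n_samp > n_total:
            trials.append(np.zeros((n_chan, n_samp)))
            kept.append(False)
            reasons.append("edge")
        else:
            trials.append(rec.data[:, start : start + n_samp])
            kept.append(True)
            reasons.append("")
    data = np.stack(trials) if trials else np.empty((0, n_chan, n_samp))
    return EpochSet(data, rec.fs, window, condition,
                    np.asarray(kept, dtype=bool), reasons)


def reject_artifacts(ep: EpochSet, threshold: float = 65.0) -> EpochSet:
    """Flag trials with any |sample| strictly above ``threshold`` uV."""
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    if ep.n_trials == 0:
        return ep
    bad = np.abs(ep.data).max(axis=(1, 2)) > threshold
    kept = ep.kept & ~bad
    reasons = [
        "amplitude" if (b and k) else r
        for b, k, r in zip(bad, ep.kept, ep.reject_reason)
    ]
    return replace(ep, kept=kept, reject_reason=reasons)


@dataclass
class SubjectDecision:
    subject: str
    kept: bool
    counts: dict[str, int]
    minimum: int

    def __str__(self):  # goes to the pipeline log
        verdict = "kept" if self.kept else "discarded"
        return f"subject {self.subject}: {verdict} (min {self.minimum}, counts {self.counts})"


def enforce_min_trials(epochs_by_condition: dict[str, EpochSet],
                       minimum: int = 40, subject: str = "") -> SubjectDecision:
    """Discard a subject if any condition has fewer kept trials than ``minimum``."""
    counts = {c: ep.n_kept for c, ep in epochs_by_condition.items()}
    ok = all(n >= minimum for n in counts.values())
    return SubjectDecision(subject, ok, counts, minimum)


# ---------------------------------------------------------------------------
# spherical-spline channel interpolation
# ---------------------------------------------------------------------------


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 20) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** m * (n + 1.0) ** m)
    P = np.stack([eval_legendre(k, cosang) for k in n], axis=-1)
    return (P * coef).sum(axis=-1) / (4.0 * np.pi)


def interpolate_channels(x, bad: list[int], montage=None, m: int = 4,
                         n_terms: int = 20, reg: float = 1e-5):
    """Rebuild bad channels by spherical-spline interpolation (stiffness m).

    The spline is fitted on the good channels' unit-sphere positions and
    evaluated at the bad ones; good channels pass through unchanged.
    """
    if not bad:
        return x
    mon = montage if montage is not None else getattr(x, "montage", None)
    if mon is None:
        raise InvalidArgumentError("montage required for interpolation")
    bad = sorted(set(bad))
    good = [i for i in range(mon.n_channels) if i not in bad]
    if len(good) < 4:
        raise InvalidArgumentError("need at least 4 good channels")
    pos = mon.positions
    G = _spline_g(pos[good] @ pos[good].T, m, n_terms)
    G = G + reg * np.eye(len(good))
    Gb = _spline_g(pos[bad] @ np.asarray(pos[good]).T, m, n_terms)
    # solve [G 1; 1' 0][c; c0] = [v; 0] for every time sample at once
    n_good = len(good)
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0

    def _fix(mat2d):  # (channels, samples)
        v = mat2d[good]
        rhs = np.vstack([v, np.zeros((1, v.shape[1]))])
        sol = np.linalg.solve(A, rhs)
        c, c0 = sol[:n_good], sol[n_good]
        out = mat2d.copy()
        out[bad] = Gb @ c + c0
        return out

    if isinstance(x, Erp):
        return replace(x, data=_fix(x.data))
    if isinstance(x, EpochSet):
        fixed = np.stack([_fix(tr) for tr in x.data]) if x.n_trials else x.data
        return replace(x, data=fixed)
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    return _fix(arr)


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------


def average_trials(ep: EpochSet, subject: str = "") -> Erp:
    """Arithmetic mean over kept trials."""
    if ep.n_kept == 0:
        raise EmptyAverageError("no kept trials to average")
    data = ep.data[ep.kept].mean(axis=0)
    return Erp(data, ep.fs, ep.window, n_trials=ep.n_kept,
               condition=ep.condition, subject=subject)


def group_average(erps: list[Erp]) -> Erp:
    """Unweighted per-sample mean across subject ERPs."""
    if not erps:
        raise EmptyAverageError("no ERPs to average")
    ref = erps[0]
    for e in erps[1:]:
        if e.data.shape != ref.data.shape or e.fs != ref.fs or e.window != ref.window:
            raise InvalidArgumentError("ERPs must share montage, fs and window")
    data = np.mean([e.data for e in erps], axis=0)
    return Erp(data, ref.fs, ref.window, n_trials=len(erps),
               condition=ref.condition, subject="group",
               montage=ref.montage)
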