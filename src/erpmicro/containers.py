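"""In-memory containers for continuous, epoched and averaged EEG."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError, ShapeError
from .montage import Montage


def n_samples_for(window: tuple[float, float], fs: float) -> int:
    """Sample count for a half-open [tmin, tmax) ms window at fs Hz."""
    tmin, tmax = window
    return int(round((tmax - tmin) / 1000.0 * fs))


@dataclass
class ContinuousRecording:
    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    montage: Montage | None = None
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        for sample, _code in self.events:
            if not (0 <= sample < self.data.shape[1]):
                raise InvalidArgumentError(f"event sample {sample} outside recording")


@dataclass
class EpochSet:
    data: np.ndarray  # (n_trials, n_channels, n_samples), uV
    fs: float
    window: tuple[float, float]  # ms, half-open [tmin, tmax)
    condition: str = ""
    kept: np.ndarray | None = None  # bool per trial
    reject_reason: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ShapeError("epoch data must be (trials, channels, samples)")
        if self.data.shape[2] != n_samples_for(self.window, self.fs):
            raise ShapeError("window length x fs inconsistent with sample count")
        if self.kept is None:
            self.kept = np.ones(self.data.shape[0], dtype=bool)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = [""] * self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + 1000.0 / self.fs * np.arange(self.data.shape[2])


@dataclass
class Erp:
    """One averaged evoked response: channels x time, with its epoch window."""

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    window: tuple[float, float]  # ms, half-open
    n_trials: int = 1
    condition: str = ""
    subject: str = ""
    montage: Montage | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != n_samples_for(self.window, self.fs):
            raise ShapeError(
                f"{self.data.shape[1]} samples inconsistent with window "
                f"{self.window} at {self.fs} Hz"
            )
        if self.n_trials < 1:
            raise InvalidArgumentError("n_trials must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + 1000.0 / self.fs * np.arange(self.data.shape[1])

    def crop(self, tmin: float, tmax: float) -> "Erp":
        """Restrict to the half-open [tmin, tmax) ms sub-window."""
        sel = (self.times >= tmin) & (self.times < tmax)
        if not np.any(sel):
            raise InvalidArgumentError("empty crop window")
        t0 = float(self.times[sel][0])
        n = int(sel.sum())
        return replace(self, data=self.data[:, sel],
                       window=(t0, t0 + n * 1000.0 / self.fs))
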