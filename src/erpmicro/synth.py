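"""Synthetic inputs with known ground truth.

The study this pipeline targets deposited no recordings, so every input is
emulated: multi-subject average-referenced ERPs built as hidden sequences of
template scalp topographies (each the forward projection of a dipole in the
spherical head model), cued-CPT trial schedules, and surface-EMG traces with
a planted burst onset.  All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Erp, n_samples_for
from .errors import (DegenerateConfigurationError, InvalidArgumentError,
                     SequencingError, ShapeError)
from .inverse import SourceGrid, build_grid, leadfield
from .montage import Montage, gen_montage, standard_montage_110  # noqa: F401

# ---------------------------------------------------------------------------
# stimulus geometry
# ---------------------------------------------------------------------------


def visual_angle(extent_mm: float, distance_cm: float) -> float:
    """Visual angle (degrees) subtended by a stimulus of ``extent_mm`` at
    ``distance_cm`` viewing distance: 2*arctan(extent/2 / distance)."""
    if extent_mm <= 0 or distance_cm <= 0:
        raise InvalidArgumentError("extent and distance must be positive")
    return float(np.degrees(2.0 * np.arctan2(extent_mm / 2.0, distance_cm * 10.0)))


# ---------------------------------------------------------------------------
# templates from dipoles
# ---------------------------------------------------------------------------


@dataclass
class DipoleSpec:
    position_mm: np.ndarray
    moment: np.ndarray  # unit orientation x amplitude


def gen_templates(k: int, montage: Montage, grid: SourceGrid | None = None,
                  seed: int = 0, max_corr: float = 0.9,
                  max_tries: int = 1000):
    """``k`` decorrelated template topographies, each a forward-projected dipole.

    Returns (maps, dipoles): maps is (k, n_channels), each average-referenced
    and unit-normed; all pairwise |spatial correlations| < ``max_corr``.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    grid = grid or build_grid(300)
    lf = leadfield(montage, grid)
    rng = np.random.default_rng(seed)
    radii = np.linalg.norm(grid.points, axis=1)
    candidates = np.nonzero(radii >= 0.4 * radii.max())[0]  # cortical-ish shell
    maps, dipoles = [], []
    tries = 0
    while len(maps) < k:
        tries += 1
        if tries > max_tries:
            raise DegenerateConfigurationError(
                f"could not draw {k} maps with pairwise |r| < {max_corr}"
            )
        idx = int(rng.choice(candidates))
        mom = rng.normal(size=3)
        mom /= np.linalg.norm(mom)
        v = lf.gain[:, 3 * idx : 3 * idx + 3] @ mom
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue
        v /= norm
        # maps are centered and unit-normed, so the dot product is Pearson r
        if any(abs(float(v @ m)) >= max_corr for m in maps):
            continue
        maps.append(v)
        dipoles.append(DipoleSpec(grid.points[idx].copy(), mom))
    return np.asarray(maps), dipoles


# ---------------------------------------------------------------------------
# ground truth and ERP datasets
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Hidden microstate structure behind a synthetic ERP dataset.

    ``label_timeline`` maps each sample of each condition to a template
    index (-1 = baseline, no evoked signal).  ``gfp_profile`` carries the
    within-segment strength modulation (half-sine bumps).
    """

    label_timeline: np.ndarray  # (n_conditions, n_samples) int
    templates: np.ndarray       # (k, n_channels) unit-normed, centered
    dipoles: list = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    fs: float = 500.0
    window: tuple[float, float] = (-200.0, 700.0)
    gfp_amplitude: float = 5.0  # uV, peak of each half-sine bump
    gfp_floor: float = 0.3      # fraction of the peak kept at segment edges
    noise_sd: float = 1.0       # uV, per-channel sensor noise
    scale_sigma: float = 0.1    # lognormal sd of subject amplitude scales
    jitter_ms: float = 10.0     # max |latency jitter| per subject

    def __post_init__(self):
        self.label_timeline = np.atleast_2d(np.asarray(self.label_timeline, dtype=int))
        if self.label_timeline.max() >= len(self.templates):
            raise InvalidArgumentError("timeline refers to a missing template")
        if not self.conditions:
            self.conditions = [f"cond{i+1}" for i in range(len(self.label_timeline))]

    @property
    def gfp_profile(self) -> np.ndarray:
        """(n_conditions, n_samples) half-sine strength profile, 0 at baseline."""
        out = np.zeros_like(self.label_timeline, dtype=float)
        for c, labels in enumerate(self.label_timeline):
            for start, stop, lab in iter_runs(labels):
                if lab < 0:
                    continue
                ph = (np.arange(start, stop) - start + 0.5) / (stop - start)
                bump = np.sin(np.pi * ph)
                out[c, start:stop] = self.gfp_amplitude * (
                    self.gfp_floor + (1 - self.gfp_floor) * bump
                )
        return out


def iter_runs(labels: np.ndarray):
    """Yield (start, stop, label) for maximal constant runs (stop exclusive)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return
    edges = np.nonzero(np.diff(labels))[0] + 1
    bounds = np.concatenate([[0], edges, [labels.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield int(a), int(b), int(labels[a])


def make_ground_truth(templates: np.ndarray, dipoles=None,
                      condition_sequences: list[list[int]] | None = None,
                      fs: float = 500.0, window: tuple[float, float] = (-200.0, 700.0),
                      **kwargs) -> GroundTruth:
    """Lay out template sequences over the post-stimulus period.

    ``condition_sequences`` lists, per condition, the template indices visited
    in order; the 0-700 ms period is split evenly among them.  Baseline
    samples are labeled -1.
    """
    k = len(templates)
    if condition_sequences is None:
        condition_sequences = [list(range(k))]
    n_samp = n_samples_for(window, fs)
    n_base = int(round(-window[0] / 1000.0 * fs))
    timeline = np.full((len(condition_sequences), n_samp), -1, dtype=int)
    for c, seq in enumerate(condition_sequences):
        edges = np.linspace(n_base, n_samp, len(seq) + 1).round().astype(int)
        for s, lab in enumerate(seq):
            timeline[c, edges[s]:edges[s + 1]] = lab
    return GroundTruth(timeline, np.asarray(templates), dipoles or [],
                       fs=fs, window=window, **kwargs)


def gen_erp_dataset(truth: GroundTruth, n_subjects: int = 15, seed: int = 0):
    """Per-subject, per-condition ERPs from the hidden microstate sequence.

    ERP(t) = gfp_profile(t) x template(label(t)) x subject_scale + white
    Gaussian sensor noise, re-referenced to the common average.  Subject
    effects: multiplicative amplitude scale ~ lognormal(0, scale_sigma) and a
    uniform latency jitter within +-jitter_ms (applied by shifting the label
    timeline).  Returns (erps, effects) where erps[subject][condition] is an
    :class:`Erp` and effects records the per-subject scale and jitter.
    """
    n_samp = n_samples_for(truth.window, truth.fs)
    if truth.label_timeline.shape[1] != n_samp:
        raise ShapeError("ground-truth timeline does not span the window at fs")
    rng = np.random.default_rng(seed)
    scales = np.exp(rng.normal(0.0, truth.scale_sigma, size=n_subjects))
    jit_samples = np.round(
        rng.uniform(-truth.jitter_ms, truth.jitter_ms, size=n_subjects)
        * truth.fs / 1000.0
    ).astype(int)
    gfp = truth.gfp_profile
    n_chan = truth.templates.shape[1]
    erps = []
    for s in range(n_subjects):
        per_cond = {}
        for c, cond in enumerate(truth.conditions):
            labels = _shift_hold(truth.label_timeline[c], jit_samples[s])
            prof = _shift_hold(gfp[c], jit_samples[s])
            sig = np.zeros((n_chan, n_samp))
            active = labels >= 0
            # templates are unit-L2; rescale so gfp_profile is the signal's
            # GFP in uV and SNR = gfp_amplitude / noise_sd
            sig[:, active] = (truth.templates[labels[active]].T
                              * prof[active] * np.sqrt(n_chan))
            sig *= scales[s]
            if truth.noise_sd > 0:
                sig = sig + rng.normal(0.0, truth.noise_sd, size=sig.shape)
            sig -= sig.mean(axis=0, keepdims=True)
            per_cond[cond] = Erp(sig, truth.fs, truth.window, n_trials=1,
                                 condition=cond, subject=f"S{s+1:02d}")
        erps.append(per_cond)
    effects = pd.DataFrame({
        "subject": [f"S{s+1:02d}" for s in range(n_subjects)],
        "scale": scales,
        "jitter_samples": jit_samples,
    })
    return erps, effects


def _shift_hold(arr: np.ndarray, shift: int) -> np.ndarray:
    """Shift right by ``shift`` samples, holding the edge value."""
    if shift == 0:
        return arr.copy()
    out = np.empty_like(arr)
    if shift > 0:
        out[shift:] = arr[:-shift]
        out[:shift] = arr[0]
    else:
        out[:shift] = arr[-shift:]
        out[shift:] = arr[-1]
    return out


# ---------------------------------------------------------------------------
# cued-CPT trial schedule
# ---------------------------------------------------------------------------

DEFAULT_LETTERS = list("ABCDEFGHJL") + ["O", "X"]


@dataclass
class ParadigmSpec:
    n_go_type: int = 80
    n_nogo_type: int = 80
    n_distractors: int = 240
    stim_dur_ms: float = 200.0
    isi_range_ms: tuple[float, float] = (1650.0, 2000.0)
    letters: list[str] = field(default_factory=lambda: list(DEFAULT_LETTERS))
    cue: str = "O"
    go_target: str = "X"

    def __post_init__(self):
        if min(self.n_go_type, self.n_nogo_type, self.n_distractors) < 0:
            raise InvalidArgumentError("trial counts must be >= 0")
        if self.isi_range_ms[0] > self.isi_range_ms[1]:
            raise InvalidArgumentError("ISI range low must be <= high")
        others = [l for l in self.letters if l not in (self.cue, self.go_target)]
        if (self.n_nogo_type or self.n_distractors) and len(others) < 2:
            raise InvalidArgumentError("alphabet too small for the no-repeat rule")


def gen_cpt_sequence(spec: ParadigmSpec | None = None, seed: int = 0,
                     max_tries: int = 200) -> pd.DataFrame:
    """Randomized cued-CPT stimulus table.

    Events are cue-target pairs (cue immediately precedes every target) and
    single distractor letters; the same letter never appears twice in a row.
    Columns: index, letter, class (cue/go_target/nogo_target/distractor),
    onset_ms, isi_ms.
    """
    spec = spec or ParadigmSpec()
    rng = np.random.default_rng(seed)
    others = [l for l in spec.letters if l not in (spec.cue, spec.go_target)]
    units = (["go"] * spec.n_go_type + ["nogo"] * spec.n_nogo_type
             + ["d"] * spec.n_distractors)
    for _ in range(max_tries):
        order = rng.permutation(len(units))
        seq: list[tuple[str, str]] = []
        ok = True
        for u in (units[i] for i in order):
            prev = seq[-1][0] if seq else None
            if u == "go":
                if prev == spec.cue:
                    ok = False
                    break
                seq.append((spec.cue, "cue"))
                seq.append((spec.go_target, "go_target"))
            elif u == "nogo":
                if prev == spec.cue:
                    ok = False
                    break
                seq.append((spec.cue, "cue"))
                choices = [l for l in others if l != spec.cue]
                seq.append((str(rng.choice(choices)), "nogo_target"))
            else:
                choices = [l for l in others if l != prev]
                if not choices:
                    ok = False
                    break
                seq.append((str(rng.choice(choices)), "distractor"))
        if ok:
            break
    else:
        raise SequencingError("could not satisfy sequencing constraints")
    isis = rng.uniform(*spec.isi_range_ms, size=len(seq))
    onsets = np.concatenate([[0.0], np.cumsum(spec.stim_dur_ms + isis)[:-1]])
    return pd.DataFrame({
        "index": np.arange(len(seq)),
        "letter": [s[0] for s in seq],
        "class": [s[1] for s in seq],
        "onset_ms": onsets,
        "isi_ms": isis,
    })


# ---------------------------------------------------------------------------
# EMG traces
# ---------------------------------------------------------------------------


@dataclass
class EmgTrace:
    samples: np.ndarray  # uV
    fs: float
    window: tuple[float, float]
    trial_id: int = 0
    condition: str = ""
    true_onset_ms: float | None = None

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + 1000.0 / self.fs * np.arange(len(self.samples))


def gen_emg(onset_ms: float | None = 415.0, burst_amp: float = 10.0,
            noise_sd: float = 1.0, fs: float = 500.0,
            window: tuple[float, float] = (-200.0, 700.0), seed: int = 0,
            burst_freq: float = 80.0) -> EmgTrace:
    """Surface-EMG trace: Gaussian noise plus a planted sinusoidal burst.

    ``onset_ms=None`` or ``burst_amp=0`` gives a pure-noise (inactive) trial.
    """
    n_samp = n_samples_for(window, fs)
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, size=n_samp) if noise_sd > 0 else np.zeros(n_samp)
    if onset_ms is not None and burst_amp > 0:
        if not (window[0] <= onset_ms < window[1]):
            raise InvalidArgumentError("onset must lie inside the window")
        t = window[0] + 1000.0 / fs * np.arange(n_samp)
        after = t >= onset_ms
        phase = 2 * np.pi * burst_freq * (t[after] - onset_ms) / 1000.0
        x[after] += burst_amp * np.sin(phase)
        true_onset = float(onset_ms)
    else:
        true_onset = None
    return EmgTrace(x, fs, window, true_onset_ms=true_onset)
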