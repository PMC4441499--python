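"""Single-subject competitive back-fitting of group template maps.

Each time point of a subject's ERP is labeled with the candidate template it
correlates best with (signed spatial correlation, ties to the lowest
template id); "map presence" is the total labeled duration per map,
condition and window, the dependent variable of the repeated-measures
ANOVAs.  No duration constraint is applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Erp
from .errors import IncompleteDesignError, InvalidArgumentError
from .microstates import _center_norm


@dataclass
class FitWindow:
    start_ms: float
    end_ms: float
    candidates: list[int]  # template ids competing in this window
    name: str = ""

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise InvalidArgumentError("window start must precede end")
        if not self.candidates:
            raise InvalidArgumentError("candidate set must be non-empty")
        if not self.name:
            self.name = f"{self.start_ms:g}-{self.end_ms:g}ms"


def label_samples(maps, templates, candidates=None) -> np.ndarray:
    """Per-sample argmax of signed spatial correlation against templates.

    ``maps``: (n_channels, n_samples) or (n_samples, n_channels) with
    channels matching ``templates``.  Zero-variance samples get label -1
    ("unassigned").  Ties resolve to the lowest template id.
    """
    templates = np.asarray(templates, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2 and maps.shape[0] == templates.shape[1]:
        maps = maps.T
    # sorted so argmax's first-occurrence rule == lowest template id on ties
    cand = (np.arange(len(templates)) if candidates is None
            else np.sort(np.asarray(candidates)))
    Xc = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    U = _center_norm(maps)
    T = _center_norm(templates[cand])
    corr = U @ T.T  # (n_samples, n_candidates)
    # argmax returns the first (lowest candidate id) on exact ties
    labels = cand[np.argmax(corr, axis=1)]
    labels[norms < 1e-15] = -1
    return labels


def fit_subject(erp: Erp, window: FitWindow, templates: np.ndarray):
    """Back-fit candidate templates within one time window.

    Returns (labels, presence): per-sample labels over the window's samples
    (-1 = unassigned, excluded from sums) and a dict template id ->
    presence in ms (label count x 1000/fs).
    """
    times = erp.times
    sel = (times >= window.start_ms) & (times < window.end_ms)
    if not np.any(sel):
        raise InvalidArgumentError("ERP does not cover the fitting window")
    labels = label_samples(erp.data[:, sel], templates, window.candidates)
    ms_per_sample = 1000.0 / erp.fs
    presence = {
        int(t): float(np.sum(labels == t) * ms_per_sample) for t in window.candidates
    }
    return labels, presence


def presence_table(erps: list[dict[str, Erp]], windows: list[FitWindow],
                   templates: np.ndarray) -> pd.DataFrame:
    """Long-format map-presence table over subjects x conditions x windows.

    ``erps[s][condition]`` is subject s's ERP.  Raises if any subject lacks
    a condition (incomplete within-subject design).
    """
    conditions = sorted({c for per in erps for c in per})
    rows = []
    for s, per_cond in enumerate(erps):
        missing = [c for c in conditions if c not in per_cond]
        if missing:
            raise IncompleteDesignError(f"subject {s} lacks conditions {missing}")
        for cond in conditions:
            erp = per_cond[cond]
            for w in windows:
                _, presence = fit_subject(erp, w, templates)
                for tid, ms in presence.items():
                    rows.append({
                        "subject": erp.subject or f"S{s+1:02d}",
                        "condition": cond,
                        "window": w.name,
                        "template": tid,
                        "presence_ms": ms,
                    })
    return pd.DataFrame(rows)
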