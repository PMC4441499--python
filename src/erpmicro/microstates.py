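"""Topographic microstate segmentation of group-averaged ERPs.

The scalp potential field of an evoked response moves through a small number
of quasi-stable configurations.  This module summarizes a set of
condition ERPs by k template topographies and a per-sample labeling, using
Atomize-and-Agglomerate Hierarchical Clustering (AAHC): every sample starts
as its own cluster; the cluster contributing least to the global explained
variance (GEV) is repeatedly dissolved and its members reassigned to the
best-correlating surviving cluster.  Model order is chosen by a
Krzanowski-Lai dispersion criterion, and a minimum-duration rule removes
spuriously short segments.  Clustering is polarity-sensitive (signed
spatial correlation), the evoked-potential convention.

The public estimator, :class:`MicrostateSegmentation`, follows the
scikit-learn fit/predict protocol; :func:`aahc`, :func:`segment` and friends
are functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import Erp
from .errors import InvalidArgumentError, UndefinedCorrelationError
from .synth import iter_runs

# ---------------------------------------------------------------------------
# elementary topographic measures
# ---------------------------------------------------------------------------


def gfp(erp) -> np.ndarray:
    """Global field power: per-sample RMS across average-referenced channels."""
    data = erp.data if isinstance(erp, Erp) else np.atleast_2d(np.asarray(erp, float))
    mean = data.mean(axis=0, keepdims=True)
    if np.abs(mean).max() > 1e-6:
        warnings.warn("input not average-referenced; re-referencing", stacklevel=2)
        data = data - mean
    return np.sqrt((data**2).mean(axis=0))


def spatial_correlation(a, b) -> float:
    """Signed Pearson correlation of two scalp maps across channels.

    Strength-independent: invariant to positive rescaling of either map;
    a polarity flip gives -r.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InvalidArgumentError("maps must share the channel set")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-15 or nb < 1e-15:
        raise UndefinedCorrelationError("zero-variance map")
    return float(a @ b / (na * nb))


def _center_norm(X: np.ndarray) -> np.ndarray:
    """Row-wise center (channel mean) and L2-normalize; zero rows stay zero."""
    Xc = X - X.mean(axis=1, keepdims=True)
    n = np.linalg.norm(Xc, axis=1, keepdims=True)
    n[n < 1e-15] = 1.0
    return Xc / n


def gev(maps: np.ndarray, gfp_vals: np.ndarray, templates: np.ndarray,
        labels: np.ndarray) -> float:
    """Global explained variance of a labeling.

    GEV = sum_t (GFP(t) * r(map_t, template(label_t)))^2 / sum_t GFP(t)^2.
    """
    labels = np.asarray(labels)
    if labels.max(initial=-1) >= len(templates):
        raise KeyError("label refers to a missing template")
    U = _center_norm(np.asarray(maps, dtype=float))
    T = _center_norm(np.asarray(templates, dtype=float))
    r = np.einsum("tc,tc->t", U, T[labels])
    denom = float(np.sum(gfp_vals**2))
    if denom == 0:
        return 0.0
    return float(np.sum((gfp_vals * r) ** 2) / denom)


# ---------------------------------------------------------------------------
# AAHC
# ---------------------------------------------------------------------------


def _aahc_path(X: np.ndarray, k_min: int, k_keep: set[int]):
    """Run AAHC from singletons down to ``k_min`` clusters.

    X: (n_samples, n_channels) raw maps.  Returns {k: (templates, labels)}
    for every k in ``k_keep`` plus k_min.  Deterministic: ties break toward
    the lowest cluster index.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=1, keepdims=True)
    g = np.sqrt((Xc**2).mean(axis=1))  # per-sample GFP
    U = _center_norm(X)  # normalized maps for correlations

    labels = np.arange(n)
    # centroid = unit-normed mean of member maps (raw maps)
    centroids = _center_norm(X.copy())
    alive = np.ones(n, dtype=bool)
    sums = X.copy()  # running raw sums per cluster
    out = {}
    n_alive = n
    while n_alive > k_min:
        live = np.nonzero(alive)[0]
        # GEV contribution of each cluster
        r = np.einsum("tc,tc->t", U, centroids[labels])
        contrib = np.bincount(labels, weights=(g * r) ** 2, minlength=n)
        worst = live[np.argmin(contrib[live])]
        members = np.nonzero(labels == worst)[0]
        alive[worst] = False
        n_alive -= 1
        live = np.nonzero(alive)[0]
        # reassign freed maps to the best-correlating surviving cluster
        c = U[members] @ centroids[live].T
        best = live[np.argmax(c, axis=1)]
        labels[members] = best
        # update raw sums and centroids of receiving clusters
        for cl in np.unique(best):
            idx = np.nonzero(labels == cl)[0]
            sums[cl] = X[idx].sum(axis=0)
            centroids[cl] = _center_norm(sums[cl][None, :])[0]
        if n_alive in k_keep or n_alive == k_min:
            live_sorted = np.sort(np.nonzero(alive)[0])
            remap = {int(old): i for i, old in enumerate(live_sorted)}
            out[n_alive] = (
                centroids[live_sorted].copy(),
                np.array([remap[int(l)] for l in labels]),
            )
    if n <= k_min and not out:
        out[n] = (_center_norm(X.copy()), np.arange(n))
    return out


def aahc(X: np.ndarray, k: int):
    """AAHC clustering to exactly ``k`` templates.

    X: (n_samples, n_channels).  Returns (templates (k, n_channels) unit-
    normed, labels (n_samples,)).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not 1 <= k <= X.shape[0]:
        raise InvalidArgumentError("k must satisfy 1 <= k <= n_samples")
    res = _aahc_path(X, k, {k})
    return res[k]


# ---------------------------------------------------------------------------
# duration constraint
# ---------------------------------------------------------------------------


def enforce_duration(labels: np.ndarray, maps: np.ndarray,
                     templates: np.ndarray, min_samples: int = 10) -> np.ndarray:
    """Absorb label runs shorter than ``min_samples``.

    Each sample of a short interior run is relabeled to whichever flanking
    segment's template correlates better with that sample's map (ties to the
    lower template id).  Runs touching the first or last sample are exempt:
    the epoch window truncates them.  Iterates until no short interior run
    remains.
    """
    labels = np.asarray(labels).copy()
    n = labels.size
    if n < min_samples:
        return labels
    U = _center_norm(np.asarray(maps, dtype=float))
    T = _center_norm(np.asarray(templates, dtype=float))
    for _ in range(n):  # convergence bound; each pass removes >= 1 run
        runs = list(iter_runs(labels))
        short = [
            (a, b, l) for a, b, l in runs
            if (b - a) < min_samples and a > 0 and b < n
        ]
        if not short:
            break
        short.sort(key=lambda r: (r[1] - r[0], r[0]))
        a, b, _lab = short[0]
        left_lab = labels[a - 1]
        right_lab = labels[b]
        for t in range(a, b):
            rl = float(U[t] @ T[left_lab])
            rr = float(U[t] @ T[right_lab])
            if rl > rr or (rl == rr and left_lab <= right_lab):
                labels[t] = left_lab
            else:
                labels[t] = right_lab
    return labels


# ---------------------------------------------------------------------------
# Krzanowski-Lai model-order selection
# ---------------------------------------------------------------------------


@dataclass
class ClusterQuality:
    k: int
    w: float       # mean within-cluster topographic dissimilarity (1 - r)
    gev_k: float


def kl_select(quality: list[ClusterQuality], n_channels: int,
              gev_fallback: float = 0.9) -> int:
    """Krzanowski-Lai choice of the cluster count.

    DIFF(k) = W(k-1)*(k-1)^(2/p) - W(k)*k^(2/p) with p the channel count;
    KL(k) = |DIFF(k)| / |DIFF(k+1)|, evaluated where the dispersion curve is
    locally convex.  If no k qualifies (featureless curve), falls back to
    the smallest k whose GEV reaches ``gev_fallback``.
    """
    if len(quality) < 3:
        raise InvalidArgumentError("need quality for at least 3 consecutive k")
    quality = sorted(quality, key=lambda q: q.k)
    ks = [q.k for q in quality]
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise InvalidArgumentError("k range must be contiguous")
    W = np.array([q.w for q in quality])
    p = float(n_channels)

    def diff(i):  # i indexes quality; needs i-1
        return W[i - 1] * ks[i - 1] ** (2 / p) - W[i] * ks[i] ** (2 / p)

    scores = {}
    for i in range(1, len(ks) - 1):
        convex = W[i - 1] - 2 * W[i] + W[i + 1] > 0
        d_next = diff(i + 1)
        if not convex or abs(d_next) < 1e-15:
            continue
        scores[ks[i]] = abs(diff(i)) / abs(d_next)
    if not scores:
        for q in quality:
            if q.gev_k >= gev_fallback:
                return q.k
        return ks[-1]
    best = max(scores.values())
    return min(k for k, v in scores.items() if v == best)


# ---------------------------------------------------------------------------
# estimator and full segmentation
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    templates: np.ndarray                 # (k, n_channels)
    labels: dict[str, np.ndarray]         # per-condition sample labels
    segments: pd.DataFrame                # condition, template, onset/offset ms
    gev: float
    k: int
    quality: list[ClusterQuality] = field(default_factory=list)

    def labels_from_segments(self) -> dict[str, np.ndarray]:
        """Rebuild label arrays from the segments table (consistency check)."""
        out = {}
        for cond, arr in self.labels.items():
            sub = self.segments[self.segments.condition == cond]
            rebuilt = np.full(arr.size, -1, dtype=int)
            for _, row in sub.iterrows():
                a, b = int(row.onset_sample), int(row.offset_sample)
                rebuilt[a:b] = int(row.template)
            out[cond] = rebuilt
        return out


class MicrostateSegmentation(BaseEstimator):
    """AAHC microstate segmentation with KL model-order selection.

    Parameters
    ----------
    k_min, k_max : inclusive range of cluster counts explored.  If
        ``k_min == k_max`` the count is fixed and KL selection is skipped.
    min_duration : minimum segment length in samples (10 samples = 20 ms at
        500 Hz); short interior segments are absorbed into their flanks.
    gev_fallback : GEV level used when the KL curve is featureless.

    Fitted attributes: ``templates_``, ``labels_`` (per condition),
    ``segments_``, ``gev_``, ``k_``, ``quality_``.
    """

    def __init__(self, k_min: int = 2, k_max: int = 8, min_duration: int = 10,
                 gev_fallback: float = 0.9):
        self.k_min = k_min
        self.k_max = k_max
        self.min_duration = min_duration
        self.gev_fallback = gev_fallback

    # -- scikit-learn API ---------------------------------------------------

    def fit(self, erps, y=None):
        """Cluster one or several condition ERPs jointly.

        ``erps``: an :class:`Erp`, a list of them, or a dict name -> Erp.
        All must share channel count, fs and window.
        """
        conds = self._as_dict(erps)
        ref = next(iter(conds.values()))
        for e in conds.values():
            if e.data.shape != ref.data.shape or e.fs != ref.fs or e.window != ref.window:
                raise InvalidArgumentError("condition ERPs must share shape, fs, window")
        names = list(conds)
        X = np.concatenate([conds[c].data.T for c in names], axis=0)
        g = gfp(np.concatenate([conds[c].data for c in names], axis=1))
        n_samp = ref.data.shape[1]
        n_chan = ref.data.shape[0]

        k_lo = max(1, int(self.k_min))
        k_hi = min(int(self.k_max), X.shape[0])
        if k_lo > k_hi:
            raise InvalidArgumentError("empty k range")
        # KL needs W on [k_lo-1, k_hi+1] when a choice is to be made
        select = k_hi > k_lo
        keep = set(range(max(1, k_lo - 1), k_hi + 2)) if select else {k_lo}
        path = _aahc_path(X, min(keep), keep)

        U = _center_norm(X)
        quality = []
        for k in sorted(path):
            tk, lk = path[k]
            r = np.einsum("tc,tc->t", U, _center_norm(tk)[lk])
            quality.append(ClusterQuality(k, float(np.mean(1.0 - r)),
                                          gev(X, g, tk, lk)))
        if select:
            k_star = kl_select(quality, n_chan, self.gev_fallback)
            k_star = int(np.clip(k_star, k_lo, k_hi))
        else:
            k_star = k_lo
        templates, labels_all = path[k_star]

        labels = {}
        for i, c in enumerate(names):
            lab = labels_all[i * n_samp : (i + 1) * n_samp]
            labels[c] = enforce_duration(lab, conds[c].data.T, templates,
                                         self.min_duration)
        final = np.concatenate([labels[c] for c in names])

        self.templates_ = templates
        self.labels_ = labels
        self.k_ = k_star
        self.gev_ = gev(X, g, templates, final)
        self.quality_ = [q for q in quality if k_lo <= q.k <= k_hi]
        self.segments_ = self._segments_table(conds, labels)
        return self

    def predict(self, erp) -> np.ndarray:
        """Label each sample of an ERP by its best-correlating template."""
        from .fitting import label_samples

        return label_samples(erp.data if isinstance(erp, Erp) else erp,
                             self.templates_)

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _as_dict(erps) -> dict[str, Erp]:
        if isinstance(erps, Erp):
            return {erps.condition or "cond1": erps}
        if isinstance(erps, dict):
            return dict(erps)
        return {e.condition or f"cond{i+1}": e for i, e in enumerate(erps)}

    @staticmethod
    def _segments_table(conds: dict[str, Erp], labels: dict[str, np.ndarray]):
        rows = []
        for c, lab in labels.items():
            times = conds[c].times
            dt = 1000.0 / conds[c].fs
            for a, b, l in iter_runs(lab):
                rows.append({
                    "condition": c, "template": int(l),
                    "onset_ms": float(times[a]),
                    "offset_ms": float(times[b - 1] + dt),
                    "onset_sample": a, "offset_sample": b,
                })
        return pd.DataFrame(rows)

    def result_(self) -> SegmentationResult:
        return SegmentationResult(self.templates_, self.labels_, self.segments_,
                                  self.gev_, self.k_, self.quality_)


def segment(erps_by_condition, k_range: tuple[int, int] = (2, 8),
            min_samples: int = 10) -> SegmentationResult:
    """One clustering across concatenated conditions; per-condition timelines."""
    est = MicrostateSegmentation(k_range[0], k_range[1], min_samples)
    est.fit(erps_by_condition)
    return est.result_()
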