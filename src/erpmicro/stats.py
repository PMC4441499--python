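"""Behavioural scoring, repeated-measures ANOVA and voxel-wise source statistics.

Covers the statistical layer of the pipeline: omission/commission error
rates, summative movement-imagery questionnaire scores, two-way
within-subject ANOVA on map presence (Condition x Map) with planned
comparisons, and voxel-wise paired t maps over solution points with a
contiguity (cluster-extent) threshold.  Degrees of freedom are reported
uncorrected (no sphericity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .errors import (IncompleteDesignError, InvalidArgumentError,
                     UndefinedRateError)

# ---------------------------------------------------------------------------
# behavioural measures
# ---------------------------------------------------------------------------


def error_rates(trials: pd.DataFrame, go_class: str = "go_target",
                nogo_class: str = "nogo_target",
                response_col: str = "responded") -> tuple[float, float]:
    """Omission and commission percentages from a trial log.

    Omission % = Go trials without a response / Go trials x 100;
    commission % = NoGo trials with a response / NoGo trials x 100.
    """
    go = trials[trials["class"] == go_class]
    nogo = trials[trials["class"] == nogo_class]
    if len(go) == 0 or len(nogo) == 0:
        raise UndefinedRateError("need at least one trial of each class")
    omission = 100.0 * float((~go[response_col].astype(bool)).sum()) / len(go)
    commission = 100.0 * float(nogo[response_col].astype(bool).sum()) / len(nogo)
    return omission, commission


def vmiq_score(ratings) -> int:
    """Summative score of one 24-item imagery-vividness scale (each 1-5).

    Per-perspective range 24-120; lower = more vivid imagery.
    """
    ratings = np.asarray(ratings)
    if ratings.shape != (24,):
        raise InvalidArgumentError("exactly 24 item ratings required")
    if np.any((ratings < 1) | (ratings > 5)) or not np.issubdtype(ratings.dtype, np.integer):
        raise InvalidArgumentError("ratings must be integers in 1..5")
    return int(ratings.sum())


def vmiq_total(other_score: int, self_score: int) -> int:
    """Total = external (Other) + internal (Self) perspective scores."""
    return int(other_score) + int(self_score)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA on map presence
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    effect: str
    df1: int
    df2: int
    F: float
    p: float


def _check_balanced(presence: pd.DataFrame, subject: str, factors: list[str]):
    counts = presence.groupby([subject, *factors]).size()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise IncompleteDesignError("design must be complete and balanced")
    per_subj = presence.groupby(subject).size()
    if per_subj.nunique() != 1:
        raise IncompleteDesignError("unequal cell counts across subjects")


def rm_anova2(presence: pd.DataFrame, value: str = "presence_ms",
              subject: str = "subject", condition: str = "condition",
              map_col: str = "template") -> list[AnovaResult]:
    """Two-way within-subject ANOVA (Condition x Map) on map presence.

    Standard sums-of-squares decomposition with uncorrected degrees of
    freedom: df1 = (a-1), (b-1), (a-1)(b-1); df2 = df1 x (n-1).
    """
    _check_balanced(presence, subject, [condition, map_col])
    import warnings as _warnings

    with _warnings.catch_warnings():
        # single-level factors make statsmodels emit 0/0 for that row;
        # those rows are dropped below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = AnovaRM(presence, depvar=value, subject=subject,
                      within=[condition, map_col]).fit()
    tbl = res.anova_table.dropna(subset=["F Value"])
    name_map = {
        condition: "Condition",
        map_col: "Map",
        f"{condition}:{map_col}": "Condition x Map",
    }
    out = []
    for row_name, row in tbl.iterrows():
        out.append(AnovaResult(
            effect=name_map.get(row_name, row_name),
            df1=int(round(row["Num DF"])),
            df2=int(round(row["Den DF"])),
            F=float(row["F Value"]),
            p=float(row["Pr > F"]),
        ))
    return out


def planned_comparison(presence: pd.DataFrame, template: int,
                       condition_pair: tuple[str, str],
                       value: str = "presence_ms", subject: str = "subject",
                       condition: str = "condition",
                       map_col: str = "template") -> AnovaResult:
    """Within-subject contrast of one map's presence between two conditions.

    One-way repeated-measures F with df = (1, n-1); algebraically the square
    of the paired t on the same data.
    """
    a, b = condition_pair
    sub = presence[presence[map_col] == template]
    pa = sub[sub[condition] == a].set_index(subject)[value]
    pb = sub[sub[condition] == b].set_index(subject)[value]
    common = pa.index.intersection(pb.index)
    if len(common) < 2:
        raise InvalidArgumentError("need at least 2 subjects with both conditions")
    if len(common) < len(pa.index.union(pb.index)):
        raise IncompleteDesignError("both conditions required for every subject")
    x = np.column_stack([pa.loc[common].to_numpy(float),
                         pb.loc[common].to_numpy(float)])
    n = x.shape[0]
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = 2 * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = 1, n - 1
    ms_err = ss_err / df2
    if ms_err > 0:
        F = float(ss_cond / ms_err)
    else:
        # degenerate error variance: identical data -> no effect at all
        F = 0.0 if ss_cond <= 1e-12 else np.inf
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(f"map {template}: {a} vs {b}", df1, df2, F, p)


def anova_results_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# voxel-wise paired t with cluster-extent threshold
# ---------------------------------------------------------------------------


@dataclass
class StatMap:
    t: np.ndarray          # per-voxel paired t (NaN where undefined)
    p: np.ndarray          # two-tailed probabilities
    mask: np.ndarray       # significant after threshold (+ clustering)
    clusters: list[list[int]] = field(default_factory=list)
    t_crit: float = 0.0
    df: int = 0
    excluded: list[int] = field(default_factory=list)  # zero-variance voxels


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical t (t_crit(14) at alpha .05 rounds to 2.14)."""
    return float(sps.t.ppf(1.0 - alpha / 2.0, df))


def voxelwise_paired_t(a: np.ndarray, b: np.ndarray,
                       alpha: float = 0.05) -> StatMap:
    """Paired t per solution point; positive t means A > B.

    Voxels whose paired differences have zero variance are excluded (t and
    p set to NaN) and listed in ``excluded``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("conditions must have identical subjects x voxels")
    n = a.shape[0]
    if n < 3:
        raise InvalidArgumentError("need at least 3 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var] = np.nan
    df = n - 1
    p = 2.0 * sps.t.sf(np.abs(t), df)
    tc = t_critical(df, alpha)
    mask = np.zeros(t.shape, dtype=bool)
    valid = ~np.isnan(t)
    mask[valid] = np.abs(t[valid]) > tc
    return StatMap(t, p, mask, [], tc, df, np.nonzero(zero_var)[0].tolist())


def cluster_filter(stat: StatMap, adjacency: dict[int, list[int]],
                   min_cluster: int = 10) -> StatMap:
    """Drop suprathreshold components smaller than ``min_cluster`` voxels.

    Connected components are computed separately for positive and negative
    t voxels over the supplied grid adjacency (face neighbors by default in
    the pipeline — the most conservative contiguity).
    """
    mask = stat.mask.copy()
    clusters: list[list[int]] = []
    for sign in (+1, -1):
        with np.errstate(invalid="ignore"):
            in_set = stat.mask & (np.sign(np.nan_to_num(stat.t)) == sign)
        seen = np.zeros_like(in_set)
        for start in np.nonzero(in_set)[0]:
            if seen[start]:
                continue
            comp = [int(start)]
            seen[start] = True
            frontier = [int(start)]
            while frontier:
                v = frontier.pop()
                for w in adjacency.get(v, []):
                    if in_set[w] and not seen[w]:
                        seen[w] = True
                        comp.append(int(w))
                        frontier.append(int(w))
            if len(comp) >= min_cluster:
                clusters.append(sorted(comp))
            else:
                mask[comp] = False
    clusters.sort(key=lambda c: c[0])
    return StatMap(stat.t, stat.p, mask, clusters, stat.t_crit, stat.df,
                   list(stat.excluded))


def statmap_frame(stat: StatMap, points: np.ndarray) -> pd.DataFrame:
    """Delimited voxel table: index, coordinates (mm), t, p, cluster id."""
    cluster_id = np.full(stat.t.shape, -1, dtype=int)
    for ci, comp in enumerate(stat.clusters):
        cluster_id[comp] = ci
    return pd.DataFrame({
        "index": np.arange(len(stat.t)),
        "x_mm": points[:, 0], "y_mm": points[:, 1], "z_mm": points[:, 2],
        "t": stat.t, "p": stat.p,
        "significant": stat.mask.astype(int),
        "cluster": cluster_id,
    })
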