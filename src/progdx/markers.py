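"""Marker statistics: rank tests, FDR, the two-cohort progressive filter,
and the mRMR / MCC species-panel selection.

The central operation is :func:`progressive_filter`.  A feature is called a
progressive marker when, in *each* of two discovery cohorts, a Kruskal-Wallis
test across the three collapsed stage groups (control, advanced adenoma,
CRC) is significant at Benjamini-Hochberg FDR < 0.05 *and* the group medians
change by more than 1.5-fold at each consecutive transition (control -> AA
and AA -> CRC), in the same direction in both cohorts.  Medians are
stabilized with a pseudocount so zero medians still yield defined ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .profiles import CohortProfile
from .stages import DISCOVERY_GROUP_ORDER, Stage, collapse_stage

PSEUDOCOUNT = 1e-10


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration of the permutation distribution when the pooled
    sample size is at most 12 and there are no ties, otherwise the normal
    approximation with tie correction and continuity correction.

    Returns the Mann-Whitney U statistic of ``x`` and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square, k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all values tied: no evidence against the null
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MarkerStats:
    """Per-feature progressive-filter statistics for one cohort."""

    feature_id: str
    cohort_id: str
    h: float
    p: float
    q: float
    medians: dict[str, float]  # group name -> raw median
    folds: tuple[float, float]  # pseudocount-stabilized NC->AA, AA->CRC ratios
    direction: str  # "up" | "down" | "none"


@dataclass
class ProgressiveMarkerSet:
    """Features passing the two-cohort monotone filter."""

    markers: dict[str, str]  # feature id -> direction
    stats: list[MarkerStats]
    fdr_threshold: float = 0.05
    fold_threshold: float = 1.5
    pseudocount: float = PSEUDOCOUNT

    @property
    def feature_ids(self) -> list[str]:
        return list(self.markers)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": s.feature_id,
                "cohort": s.cohort_id,
                "H": s.h,
                "p": s.p,
                "q": s.q,
                "median_NC": s.medians["NC"],
                "median_AA": s.medians["AA"],
                "median_CRC": s.medians["CRC"],
                "fold1": s.folds[0],
                "fold2": s.folds[1],
                "direction": s.direction,
            }
            for s in self.stats
        ]
        return pd.DataFrame(rows)


def _stage_groups(metadata: pd.DataFrame) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {g: [] for g in DISCOVERY_GROUP_ORDER}
    for sid, stage in zip(metadata["sample_id"], metadata["stage"]):
        g = collapse_stage(stage)
        if g is not None:
            groups[g].append(sid)
    return groups


def _cohort_stats(
    profile: CohortProfile,
    metadata: pd.DataFrame,
    fold_threshold: float,
    pseudocount: float,
) -> list[MarkerStats]:
    groups = _stage_groups(metadata)
    for g, sids in groups.items():
        if not sids:
            raise ValueError(
                f"cohort {profile.cohort_id!r} has no samples in stage group {g}"
            )
    arrays = {g: profile.data.loc[sids].to_numpy() for g, sids in groups.items()}
    n_feat = len(profile.feature_ids)
    hs = np.empty(n_feat)
    ps = np.empty(n_feat)
    medians = {g: np.median(a, axis=0) for g, a in arrays.items()}
    for j in range(n_feat):
        hs[j], ps[j] = kruskal_wallis([arrays[g][:, j] for g in DISCOVERY_GROUP_ORDER])
    qs = bh_fdr(ps)

    out: list[MarkerStats] = []
    for j, fid in enumerate(profile.feature_ids):
        m = {g: float(medians[g][j]) for g in DISCOVERY_GROUP_ORDER}
        fold1 = (m["AA"] + pseudocount) / (m["NC"] + pseudocount)
        fold2 = (m["CRC"] + pseudocount) / (m["AA"] + pseudocount)
        if fold1 > fold_threshold and fold2 > fold_threshold:
            direction = "up"
        elif fold1 < 1.0 / fold_threshold and fold2 < 1.0 / fold_threshold:
            direction = "down"
        else:
            direction = "none"
        out.append(
            MarkerStats(fid, profile.cohort_id, float(hs[j]), float(ps[j]), float(qs[j]), m, (fold1, fold2), direction)
        )
    return out


def progressive_filter(
    cohort1: tuple[CohortProfile, pd.DataFrame],
    cohort2: tuple[CohortProfile, pd.DataFrame],
    fdr_threshold: float = 0.05,
    fold_threshold: float = 1.5,
    pseudocount: float = PSEUDOCOUNT,
) -> ProgressiveMarkerSet:
    """Two-cohort progressive-marker filter.

    Retains a feature iff in each cohort its Kruskal-Wallis BH q-value is
    below ``fdr_threshold`` and its stabilized group medians move strictly
    monotonically by more than ``fold_threshold`` per transition, in the
    same direction in both cohorts.
    """
    p1, m1 = cohort1
    p2, m2 = cohort2
    if list(p1.feature_ids) != list(p2.feature_ids):
        raise ValueError("cohorts must share an identical feature space")
    stats1 = _cohort_stats(p1, m1, fold_threshold, pseudocount)
    stats2 = _cohort_stats(p2, m2, fold_threshold, pseudocount)
    markers: dict[str, str] = {}
    for s1, s2 in zip(stats1, stats2):
        if (
            s1.q < fdr_threshold
            and s2.q < fdr_threshold
            and s1.direction != "none"
            and s1.direction == s2.direction
        ):
            markers[s1.feature_id] = s1.direction
    kept = set(markers)
    kept_stats = [s for s in stats1 + stats2 if s.feature_id in kept]
    return ProgressiveMarkerSet(markers, kept_stats, fdr_threshold, fold_threshold, pseudocount)


# ---------------------------------------------------------------------------
# Species-panel selection: Wilcoxon prefilter -> mRMR -> CV-MCC panel
# ---------------------------------------------------------------------------


def wilcoxon_prefilter(profile: CohortProfile, labels: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Features whose two-group Wilcoxon rank-sum p-value is <= alpha."""
    labels = np.asarray(labels)
    kept = []
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("prefilter needs exactly two classes")
    a = profile.values[labels == classes[0]]
    b = profile.values[labels == classes[1]]
    for j, fid in enumerate(profile.feature_ids):
        _, p = wilcoxon_rank_sum(a[:, j], b[:, j])
        if p <= alpha:
            kept.append(fid)
    return kept


def _discretize_tertiles(column: np.ndarray) -> np.ndarray:
    qs = np.quantile(column, [1 / 3, 2 / 3])
    return np.digitize(column, qs)


def mrmr_rank(profile: CohortProfile, labels, top_k: int) -> list[str]:
    """Greedy max-relevance-min-redundancy feature ranking (MID variant).

    Mutual information is computed on tertile-discretized abundances; at
    each step the feature maximizing relevance minus mean redundancy with
    the already-selected set is appended.  Ties resolve to the earliest
    feature in input column order, so the ranking is deterministic.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need two classes for mRMR")
    n_feat = len(profile.feature_ids)
    if top_k > n_feat:
        raise ValueError(f"top_k={top_k} exceeds {n_feat} features")
    disc = np.column_stack([_discretize_tertiles(profile.values[:, j]) for j in range(n_feat)])
    relevance = np.array([mutual_info_score(labels, disc[:, j]) for j in range(n_feat)])

    selected: list[int] = []
    redundancy_sum = np.zeros(n_feat)
    remaining = list(range(n_feat))
    while len(selected) < top_k:
        if selected:
            scores = relevance[remaining] - redundancy_sum[remaining] / len(selected)
        else:
            scores = relevance[remaining]
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            redundancy_sum[j] += mutual_info_score(disc[:, best], disc[:, j])
    return [profile.feature_ids[j] for j in selected]


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


@dataclass
class SpeciesPanelParams:
    prefilter_alpha: float = 0.05
    mrmr_top_k: int = 100
    panel_size: int | None = 25
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prefilter_alpha < 1:
            raise ValueError("prefilter_alpha must be in (0, 1)")
        if self.panel_size is not None and self.panel_size > self.mrmr_top_k:
            raise ValueError("panel_size cannot exceed mrmr_top_k")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SpeciesPanel:
    feature_ids: list[str]
    mcc_curve: list[float] = field(repr=False)
    params: SpeciesPanelParams = field(default_factory=SpeciesPanelParams)


def _cv_mcc(x: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for train, test in skf.split(x, y):
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        tp += int(np.sum((pred == 1) & (y[test] == 1)))
        fp += int(np.sum((pred == 1) & (y[test] == 0)))
        tn += int(np.sum((pred == 0) & (y[test] == 0)))
        fn += int(np.sum((pred == 0) & (y[test] == 1)))
    return mcc(tp, fp, tn, fn)


def mcc_panel_select(
    ranked: list[str], profile: CohortProfile, labels, params: SpeciesPanelParams | None = None
) -> SpeciesPanel:
    """Choose a marker panel by cross-validated MCC over ranking prefixes.

    Each nested prefix of the mRMR ranking is scored by the pooled
    cross-validated MCC of a linear maximum-margin classifier on
    ln(abundance + pseudocount) features.  With ``panel_size`` set (the
    default, 25) the fixed-size prefix is returned alongside the full MCC
    curve; with ``panel_size=None`` the prefix with maximal MCC wins.
    """
    params = params or SpeciesPanelParams()
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain exactly two classes")
    sub = profile.restrict(ranked)
    x_all = np.log(sub.values + PSEUDOCOUNT)
    max_prefix = len(ranked) if params.panel_size is None else min(len(ranked), max(params.panel_size, 1))
    curve: list[float] = []
    for k in range(1, max_prefix + 1):
        curve.append(_cv_mcc(x_all[:, :k], labels, params.cv_folds, params.seed))
    if params.panel_size is not None:
        chosen = ranked[: min(params.panel_size, len(ranked))]
    else:
        chosen = ranked[: int(np.argmax(curve)) + 1]
    return SpeciesPanel(chosen, curve, params)
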