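"""Diagnostic-performance evaluation: confusion metrics, ROC/AUC with
bootstrap confidence intervals, and Spearman clinical correlations.

Sensitivity and specificity are reported as count-backed percentages
rounded half-up to one decimal — e.g. 119 detected of 167 cases prints as
71.3% (119/167) — so the percentage can always be re-derived exactly from
the stored counts.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _round_half_up_1dp(value: float) -> float:
    return float(decimal.Decimal(repr(value)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity_pct: float
    specificity_pct: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    mcc: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity_pct": self.sensitivity_pct,
            "sensitivity_fraction": f"{self.tp}/{self.tp + self.fn}",
            "specificity_pct": self.specificity_pct,
            "specificity_fraction": f"{self.tn}/{self.tn + self.fp}",
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "mcc": self.mcc,
        }


def confusion(calls, truth) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) from binary calls against binary truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    if calls.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    return tp, fp, tn, fn


def sensitivity_specificity(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
    """Percentages (one decimal, half-up) from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("sensitivity/specificity undefined for an empty class")
    sens = _round_half_up_1dp(100.0 * tp / (tp + fn))
    spec = _round_half_up_1dp(100.0 * tn / (tn + fp))
    return sens, spec


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC as pairwise concordance (ties count half).

    AUC equals P(score_case > score_control) + 0.5 * P(tie), computed via
    the rank (Mann-Whitney) identity so ties are handled exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for ROC analysis")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    # collapse threshold ties to the last index of each distinct score
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_scores.size - 1]
    curve = pd.DataFrame(
        {
            "threshold": sorted_scores[distinct],
            "tpr": tps[distinct] / n_pos,
            "fpr": fps[distinct] / n_neg,
        }
    )
    curve = pd.concat(
        [pd.DataFrame({"threshold": [np.inf], "tpr": [0.0], "fpr": [0.0]}), curve],
        ignore_index=True,
    )
    return curve, float(auc)


def bootstrap_auc_ci(
    scores, labels, reps: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile-bootstrap confidence interval for the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    if reps < 100:
        warnings.warn("fewer than 100 bootstrap replicates; interval is unstable")
    rng = np.random.default_rng(seed)
    pos = scores[labels]
    neg = scores[~labels]
    aucs = np.empty(reps)
    for r in range(reps):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        ranks = stats.rankdata(np.concatenate([bp, bn]))
        aucs[r] = (ranks[: bp.size].sum() - bp.size * (bp.size + 1) / 2) / (bp.size * bn.size)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(low), float(high)


def evaluate_calls(calls, truth, scores=None, ci_seed: int = 0, ci_reps: int = 2000) -> EvaluationResult:
    """Full evaluation: confusion counts, percentages, optional AUC + CI."""
    tp, fp, tn, fn = confusion(calls, truth)
    sens, spec = sensitivity_specificity(tp, fp, tn, fn)
    auc = ci = mcc_val = None
    if scores is not None:
        _, auc = roc_auc(scores, truth)
        truth_arr = np.asarray(truth, dtype=bool)
        if truth_arr.sum() >= 2 and (~truth_arr).sum() >= 2:
            ci = bootstrap_auc_ci(scores, truth, reps=ci_reps, seed=ci_seed)
    from .markers import mcc as _mcc

    mcc_val = _mcc(tp, fp, tn, fn)
    return EvaluationResult(tp, fp, tn, fn, sens, spec, auc, ci, mcc_val)


def spearman_clinical_correlation(
    abundances: pd.DataFrame, clinical: pd.DataFrame, min_samples: int = 3
) -> pd.DataFrame:
    """Spearman rho between each marker and each clinical covariate.

    For each covariate, samples whose value is missing (NA) are dropped
    from that covariate's column only; covariates with fewer than
    ``min_samples`` remaining observations are reported as NaN.
    """
    shared = abundances.index.intersection(clinical.index)
    if shared.empty:
        raise ValueError("no shared sample ids between abundances and clinical table")
    abund = abundances.loc[shared]
    clin = clinical.loc[shared]
    out = pd.DataFrame(index=abund.columns, columns=clin.columns, dtype=float)
    for cov in clin.columns:
        values = pd.to_numeric(clin[cov], errors="coerce")
        mask = values.notna()
        if mask.sum() < min_samples:
            out[cov] = np.nan
            continue
        v = values[mask].to_numpy()
        for marker in abund.columns:
            rho, _ = stats.spearmanr(abund.loc[mask, marker].to_numpy(), v)
            out.loc[marker, cov] = rho
    return out
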