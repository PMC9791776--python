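"""Fecal immunochemical test (FIT) binarization and FIT + index combination.

Quantitative fecal hemoglobin is binarized at the manufacturer positivity
threshold of 20 ug/g dry stool (equivalently 100 ng/mL of buffer); only
values strictly greater than the threshold are positive.  The published
combination scores are affine in the binary FIT result and one CRC effect
index:

    score1 = 23.710037 + 4.082365 * FIT + 0.147425 * CEI1   (cutoff 28.55)
    score2 = -0.87127 + 21.769347 * FIT + 0.332905 * CEI2   (cutoff 22.75)

with a positive call when the score exceeds the cutoff.  The coefficient
magnitudes are only plausible for a 0/1 FIT covariate, which is the
convention here; :func:`combined_score` accepts a continuous value via
``fit_binary`` only when explicitly allowed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .effect_index import NEGATIVE_TARGET, POSITIVE_TARGET, choose_cutoff


@dataclass(frozen=True)
class FitConfig:
    positivity_threshold: float = 20.0  # ug hemoglobin / g dry stool

    def __post_init__(self) -> None:
        if self.positivity_threshold <= 0:
            raise ValueError("positivity threshold must be positive")


@dataclass
class CombinedScoreModel:
    name: str
    intercept: float
    fit_coef: float
    index_coef: float
    index_name: str
    cutoff: float


def binarize_fit(value: float, config: FitConfig | None = None) -> int:
    """1 iff the FIT value strictly exceeds the positivity threshold."""
    config = config or FitConfig()
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError("missing FIT value")
    if value < 0:
        raise ValueError(f"negative FIT value {value}")
    return int(value > config.positivity_threshold)


def published_models() -> dict[str, CombinedScoreModel]:
    """The two published FIT + index combination models with their cutoffs."""
    return {
        "score1": CombinedScoreModel("score1", 23.710037, 4.082365, 0.147425, "CEI1", 28.55),
        "score2": CombinedScoreModel("score2", -0.87127, 21.769347, 0.332905, "CEI2", 22.75),
    }


def combined_score(
    fit_binary: int, index_value: float, model: CombinedScoreModel
) -> tuple[float, bool]:
    """Evaluate a combination model; positive call iff score > cutoff."""
    if fit_binary not in (0, 1):
        raise ValueError("fit_binary must be 0 or 1")
    score = model.intercept + model.fit_coef * fit_binary + model.index_coef * index_value
    return float(score), bool(score > model.cutoff)


def refit_combined(
    fit_binaries,
    index_values,
    labels,
    name: str = "refit",
    index_name: str = "index",
    target_specificity: float = 0.90,
) -> CombinedScoreModel:
    """Refit combination coefficients on new data.

    Reuses the dichotomy convention: least squares of 1/50 targets on
    [1, FIT, index], then a specificity-first cutoff.
    """
    fit_binaries = np.asarray(fit_binaries, dtype=float)
    index_values = np.asarray(index_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes required to refit")
    y = np.where(labels, POSITIVE_TARGET, NEGATIVE_TARGET)
    design = np.column_stack([np.ones_like(fit_binaries), fit_binaries, index_values])
    if np.ptp(fit_binaries) == 0 and np.ptp(index_values) == 0:
        import warnings

        warnings.warn("constant predictors; refit is intercept-only")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    scores = design @ coef
    cutoff = choose_cutoff(scores, labels, target_specificity)
    return CombinedScoreModel(name, float(coef[0]), float(coef[1]), float(coef[2]), index_name, float(cutoff))
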