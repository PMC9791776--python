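"""Effect-index diagnosis models over progressive marker abundances.

An effect index is a linear score over log-transformed marker abundances,

    index(sample) = sum_i c_i * ( ln(abun_i + 1e-10) + 23.026 ) + b,

trained by "dichotomy" iterative least squares: the negative class starts
at target score 1 and the positive class at 50, a (minimum-norm) least
squares fit maps transformed abundances to those targets, and samples the
fit already places on the correct side of the class midpoint (25.5) adopt
their fitted value as the new target ("good scores") before refitting.
Iteration stops once the training Youden index stops improving.

The constant 23.026 is the rounded negative log of the pseudocount
(-ln(1e-10) = 23.02585...), so a feature absent from a sample contributes
almost exactly zero to the score.

Four canonical indexes ladder up the adenoma-carcinoma sequence — AEI1
(advanced adenoma and above vs control), AEI2 (high-grade dysplasia and
above), CEI1 (any CRC), CEI2 (stage III/IV CRC) — plus a Progressive
Disease Index (PDI) fitted to ordinal targets over all six stages with a
reference warning line at 75.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import CohortProfile
from .stages import Stage

EPSILON = 1e-10
LOG_OFFSET = 23.026
CLASS_MIDPOINT = 25.5  # midpoint of the 1 / 50 dichotomy targets
NEGATIVE_TARGET = 1.0
POSITIVE_TARGET = 50.0

#: Ordinal PDI targets per stage; the warning line at 75 falls between the
#: stage I/II and stage III/IV cancer targets.
PDI_TARGETS: dict[Stage, float] = {
    Stage.NC: 1.0,
    Stage.MP: 20.0,
    Stage.AA_LGD: 40.0,
    Stage.AA_HGD: 60.0,
    Stage.CRC_I_II: 80.0,
    Stage.CRC_III_IV: 100.0,
}
PDI_WARNING_LINE = 75.0


@dataclass(frozen=True)
class IndexDefinition:
    """Which stages form the positive (target 50) and negative (target 1)
    classes of one index; all other stages are excluded from training."""

    name: str
    positive_stages: frozenset[Stage]
    negative_stages: frozenset[Stage]

    def __post_init__(self) -> None:
        if self.positive_stages & self.negative_stages:
            raise ValueError("positive and negative stages overlap")
        if not self.positive_stages or not self.negative_stages:
            raise ValueError("both classes must be non-empty")


INDEX_DEFINITIONS: dict[str, IndexDefinition] = {
    # negative class is always the control group; the positive class walks
    # up the severity ladder
    "AEI1": IndexDefinition(
        "AEI1",
        frozenset({Stage.AA_LGD, Stage.AA_HGD, Stage.CRC_I_II, Stage.CRC_III_IV}),
        frozenset({Stage.NC}),
    ),
    "AEI2": IndexDefinition(
        "AEI2",
        frozenset({Stage.AA_HGD, Stage.CRC_I_II, Stage.CRC_III_IV}),
        frozenset({Stage.NC}),
    ),
    "CEI1": IndexDefinition(
        "CEI1", frozenset({Stage.CRC_I_II, Stage.CRC_III_IV}), frozenset({Stage.NC})
    ),
    "CEI2": IndexDefinition("CEI2", frozenset({Stage.CRC_III_IV}), frozenset({Stage.NC})),
}


@dataclass
class TrainingOptions:
    tolerance: float = 0.005  # minimum Youden improvement to keep iterating
    max_iterations: int = 20
    solver: str = "min-norm"  # or "ridge"
    ridge_lambda: float = 1.0
    target_specificity: float = 0.90

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.solver not in ("min-norm", "ridge"):
            raise ValueError("solver must be 'min-norm' or 'ridge'")


@dataclass
class EffectIndexModel:
    definition: IndexDefinition
    feature_ids: list[str]
    coefficients: np.ndarray = field(repr=False)
    intercept: float
    cutoff: float
    pseudocount: float = EPSILON
    offset: float = LOG_OFFSET
    trace: list[dict] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.feature_ids),):
            raise ValueError("one coefficient per feature required")

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.definition.name,
                "positive_stages": sorted(s.name for s in self.definition.positive_stages),
                "negative_stages": sorted(s.name for s in self.definition.negative_stages),
                "feature_ids": self.feature_ids,
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "cutoff": self.cutoff,
                "pseudocount": self.pseudocount,
                "offset": self.offset,
                "trace": self.trace,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "EffectIndexModel":
        obj = json.loads(text)
        definition = IndexDefinition(
            obj["name"],
            frozenset(Stage.parse(s) for s in obj["positive_stages"]),
            frozenset(Stage.parse(s) for s in obj["negative_stages"]),
        )
        return cls(
            definition,
            list(obj["feature_ids"]),
            np.asarray(obj["coefficients"], dtype=float),
            float(obj["intercept"]),
            float(obj["cutoff"]),
            float(obj["pseudocount"]),
            float(obj["offset"]),
            list(obj["trace"]),
        )


def transform_abundance(a, pseudocount: float = EPSILON, offset: float = LOG_OFFSET):
    """ln(abundance + pseudocount) + offset, elementwise; rejects negatives."""
    a = np.asarray(a, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    return np.log(a + pseudocount) + offset


def initial_targets(metadata: pd.DataFrame, definition: IndexDefinition) -> pd.Series:
    """Dichotomy targets (1 / 50) over the samples a definition includes.

    Samples in neither class (intermediate stages) are omitted entirely.
    """
    targets: dict[str, float] = {}
    for sid, stage_name in zip(metadata["sample_id"], metadata["stage"]):
        stage = Stage.parse(stage_name)
        if stage in definition.positive_stages:
            targets[sid] = POSITIVE_TARGET
        elif stage in definition.negative_stages:
            targets[sid] = NEGATIVE_TARGET
    series = pd.Series(targets, name="target", dtype=float)
    if not (series == POSITIVE_TARGET).any():
        raise ValueError(f"{definition.name}: no samples in the positive class")
    if not (series == NEGATIVE_TARGET).any():
        raise ValueError(f"{definition.name}: no samples in the negative class")
    return series


def _solve_least_squares(
    x: np.ndarray, y: np.ndarray, options: TrainingOptions
) -> tuple[np.ndarray, float]:
    """Least squares of y on [1, x]; minimum-norm coefficients when p >= n.

    Centering both sides makes the coefficient block the minimum-norm
    solution and zeroes the coefficient of any constant column.
    """
    y_mean = float(y.mean())
    varying = ~(x == x[0]).all(axis=0)  # constant columns get coefficient 0
    if not varying.any():
        warnings.warn("all features constant; fitting intercept-only model")
        return np.zeros(x.shape[1]), y_mean
    xv = x[:, varying]
    x_mean = xv.mean(axis=0)
    xc = xv - x_mean
    yc = y - y_mean
    if options.solver == "ridge":
        lam = options.ridge_lambda
        sub = np.linalg.solve(xc.T @ xc + lam * np.eye(xc.shape[1]), xc.T @ yc)
    else:
        sub, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    coef = np.zeros(x.shape[1])
    coef[varying] = sub
    intercept = y_mean - float(sub @ x_mean)
    return coef, intercept


def youden_index(scores: np.ndarray, positive: np.ndarray) -> float:
    """Max over thresholds of sensitivity + specificity - 1 (call: score > t)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    best = 0.0
    thresholds = np.unique(scores)
    # candidate cutoffs just below each observed score, plus above the max
    for t in np.concatenate([thresholds - 1e-12, [thresholds[-1]]]):
        calls = scores > t
        sens = np.mean(calls[positive]) if positive.any() else 0.0
        spec = np.mean(~calls[~positive]) if (~positive).any() else 0.0
        best = max(best, float(sens + spec - 1.0))
    return best


def fit_effect_index(
    profile: CohortProfile,
    metadata: pd.DataFrame,
    definition: IndexDefinition,
    options: TrainingOptions | None = None,
) -> EffectIndexModel:
    """Train one effect index by dichotomy-target iterative least squares.

    Each accepted iteration must improve the training Youden index by at
    least ``options.tolerance``; the best iterate is kept.  Targets of
    correctly-classified samples are replaced by their fitted scores
    clipped to [1, 50]; misclassified samples revert to 1 / 50.
    """
    options = options or TrainingOptions()
    targets = initial_targets(metadata, definition)
    sample_ids = list(targets.index)
    if len(sample_ids) < 4:
        raise ValueError("need at least 2 samples per class to train")
    x = transform_abundance(profile.data.loc[sample_ids].to_numpy())
    y = targets.to_numpy(copy=True)
    positive = y == POSITIVE_TARGET

    best: tuple[float, np.ndarray, float] | None = None  # youden, coef, intercept
    trace: list[dict] = []
    for iteration in range(options.max_iterations):
        coef, intercept = _solve_least_squares(x, y, options)
        fitted = x @ coef + intercept
        youden = youden_index(fitted, positive)
        improved = best is None or youden > best[0] + options.tolerance
        if best is None or youden > best[0]:
            best = (youden, coef, intercept)
        correct = np.where(positive, fitted > CLASS_MIDPOINT, fitted < CLASS_MIDPOINT)
        n_relabelled = int(correct.sum())
        trace.append(
            {"iteration": iteration, "youden": float(youden), "relabelled": n_relabelled}
        )
        if not improved and iteration > 0:
            break
        # good scores replace the 1/50 targets; the rest reset
        y = np.where(
            correct,
            np.clip(fitted, NEGATIVE_TARGET, POSITIVE_TARGET),
            np.where(positive, POSITIVE_TARGET, NEGATIVE_TARGET),
        )

    _, coef, intercept = best
    final_scores = x @ coef + intercept
    cutoff = choose_cutoff(final_scores, positive, options.target_specificity)
    return EffectIndexModel(
        definition, list(profile.feature_ids), coef, float(intercept), float(cutoff), trace=trace
    )


def score_samples(model: EffectIndexModel, profile: CohortProfile) -> pd.Series:
    """Apply a fitted index to a profile; missing model features are an error."""
    sub = profile.restrict(model.feature_ids)
    x = np.log(sub.values + model.pseudocount) + model.offset
    scores = x @ model.coefficients + model.intercept
    return pd.Series(scores, index=sub.sample_ids, name=model.definition.name)


def choose_cutoff(scores, positive, target_specificity: float = 0.90) -> float:
    """Smallest observed-score cutoff with specificity >= target.

    Calls are positive when score > cutoff, so specificity at cutoff c is
    the fraction of negatives with score <= c.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or (~positive).all():
        raise ValueError("both classes required to choose a cutoff")
    negatives = np.sort(scores[~positive])
    n = negatives.size
    for c in np.unique(negatives):
        if np.searchsorted(negatives, c, side="right") / n >= target_specificity:
            return float(c)
    warnings.warn("target specificity unachievable; cutoff set above all scores")
    return float(scores.max() + EPSILON)


def progressive_disease_index(
    profile: CohortProfile,
    metadata: pd.DataFrame,
    options: TrainingOptions | None = None,
    warning_line: float = PDI_WARNING_LINE,
) -> tuple[EffectIndexModel, pd.Series, float]:
    """Fit the Progressive Disease Index to ordinal six-stage targets.

    A single least-squares fit maps transformed abundances to targets that
    rise with stage severity (1, 20, 40, 60, 80, 100); scores are emitted
    together with the configurable warning line (default 75).
    """
    options = options or TrainingOptions()
    stages = [Stage.parse(s) for s in metadata["stage"]]
    sample_ids = list(metadata["sample_id"])
    y = np.array([PDI_TARGETS[s] for s in stages])
    x = transform_abundance(profile.data.loc[sample_ids].to_numpy())
    coef, intercept = _solve_least_squares(x, y, options)
    definition = IndexDefinition(
        "PDI",
        frozenset({Stage.CRC_I_II, Stage.CRC_III_IV}),
        frozenset({Stage.NC}),
    )
    model = EffectIndexModel(
        definition,
        list(profile.feature_ids),
        coef,
        float(intercept),
        cutoff=float(warning_line),
        trace=[{"iteration": 0, "targets": "ordinal"}],
    )
    scores = pd.Series(x @ coef + intercept, index=sample_ids, name="PDI")
    return model, scores, warning_line
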