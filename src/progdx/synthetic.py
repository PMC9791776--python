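"""Synthetic multi-stage, multi-cohort stool-metagenome cohorts.

Emulates the data structure of a two-discovery-cohort study of the
adenoma-carcinoma sequence: compositional, zero-inflated gene/species
abundance profiles over six ordered disease stages, with a planted subset
of features whose group medians rise (or fall) by a configurable fold per
stage transition in every cohort, per-cohort batch effects, and fecal
hemoglobin (FIT) values that increase with disease severity.

The abundance model draws per-feature log-normal intensities with Bernoulli
zero-inflation and then closes each sample to relative abundance.  Stage
effects are applied on the log scale before closure, so planted up-markers
have their population medians multiplied by ``exp(per_step_log_fold)`` at
each control -> advanced adenoma -> CRC transition.  Randomness is routed
through per-(cohort, feature) substreams of one global seed, so the draws
for existing features do not change when features are added.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CohortProfile
from .stages import Stage

#: Stage positions along the control -> AA -> CRC progression axis, in units
#: of "filter steps".  The collapsed AA group sits one step above control and
#: the collapsed CRC group two steps above, so planted medians move by the
#: configured fold at each transition the progressive filter tests; the
#: fractional offsets grade the six-level severity for the disease index.
STAGE_EFFECT_STEPS: dict[Stage, float] = {
    Stage.NC: 0.0,
    Stage.MP: 0.5,
    Stage.AA_LGD: 1.0,
    Stage.AA_HGD: 1.25,
    Stage.CRC_I_II: 2.0,
    Stage.CRC_III_IV: 2.25,
}

#: Default per-cohort group sizes (a 1:10 scale-down of an 871-sample study
#: with 390 controls, 67 multiple polyps, 167 advanced adenomas of which 106
#: high-grade, 128 stage I/II and 87 stage III/IV cancers).
DEFAULT_GROUP_SIZES: dict[Stage, int] = {
    Stage.NC: 39,
    Stage.MP: 7,
    Stage.AA_LGD: 17,
    Stage.AA_HGD: 11,
    Stage.CRC_I_II: 13,
    Stage.CRC_III_IV: 9,
}

#: Default per-stage FIT mean/sd in ug hemoglobin per g dry stool.  Chosen so
#: that, against the 20 ug/g positivity threshold, controls are rarely
#: positive while most advanced cancers are — the qualitative behaviour of
#: quantitative FIT in screening populations.
DEFAULT_FIT_PARAMS: dict[Stage, tuple[float, float]] = {
    Stage.NC: (5.0, 8.0),
    Stage.MP: (8.0, 10.0),
    Stage.AA_LGD: (12.0, 15.0),
    Stage.AA_HGD: (15.0, 18.0),
    Stage.CRC_I_II: (80.0, 60.0),
    Stage.CRC_III_IV: (120.0, 80.0),
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort (shared by both cohorts of a study).

    Parameters
    ----------
    group_sizes
        Samples per stage, per cohort.
    n_features
        Total number of features in the profile.
    n_progressive_up, n_progressive_down
        How many features carry a planted monotone increase / decrease.
    per_step_log_fold
        Natural-log shift of planted medians per progression step; the
        default ln(2) doubles (halves) the median at each transition.
        Planted markers meant to survive the 1.5-fold filter need a value
        above ln(1.5).
    zero_inflation
        Probability that any single measurement is zeroed (dropout).
    dispersion
        Log-normal sd of per-measurement biological + technical noise.
    cohort_batch_sd
        Sd of the per-cohort, per-feature log-scale batch offset.
    fit_params
        Per-stage (mean, sd) of FIT in ug/g.
    """

    group_sizes: dict[Stage, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_features: int = 2000
    n_progressive_up: int = 10
    n_progressive_down: int = 10
    per_step_log_fold: float = float(np.log(2.0))
    zero_inflation: float = 0.3
    dispersion: float = 1.0
    cohort_batch_sd: float = 0.3
    fit_params: dict[Stage, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FIT_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = {Stage.parse(k): int(v) for k, v in self.group_sizes.items()}
        self.fit_params = {Stage.parse(k): tuple(v) for k, v in self.fit_params.items()}
        if not self.group_sizes:
            raise ValueError("group_sizes must not be empty")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.n_progressive_up < 0 or self.n_progressive_down < 0:
            raise ValueError("planted marker counts must be >= 0")
        if self.n_progressive_up + self.n_progressive_down > self.n_features:
            raise ValueError("more planted markers than features")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.cohort_batch_sd < 0:
            raise ValueError("cohort_batch_sd must be >= 0")
        for stage, (mean, sd) in self.fit_params.items():
            if mean < 0 or sd < 0:
                raise ValueError(f"fit_params for {stage.name} must be non-negative")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study: planted marker ids + directions."""

    directions: dict[str, str]  # feature id -> "up" | "down"
    stages: dict[str, str]  # sample id -> stage name
    seed: int

    @property
    def progressive_feature_ids(self) -> list[str]:
        return list(self.directions)

    def to_json(self) -> str:
        return json.dumps(
            {"directions": self.directions, "stages": self.stages, "seed": self.seed},
            indent=2,
            sort_keys=True,
        )


def _feature_rng(seed: int, cohort_id: str, feature_index: int, purpose: int) -> np.random.Generator:
    # crc32 keeps the substream a pure function of the cohort *string*
    # (python's hash() is salted per process).
    key = (zlib.crc32(cohort_id.encode()), purpose, feature_index)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _planted_directions(spec: SyntheticSpec) -> dict[str, str]:
    # Planted markers occupy the first up+down feature indices; baselines are
    # drawn per feature index so the assignment is stable across cohorts.
    directions: dict[str, str] = {}
    for j in range(spec.n_progressive_up):
        directions[f"feat_{j:05d}"] = "up"
    for j in range(spec.n_progressive_up, spec.n_progressive_up + spec.n_progressive_down):
        directions[f"feat_{j:05d}"] = "down"
    return directions


def generate_cohort(
    spec: SyntheticSpec, cohort_id: str, level: str = "gene"
) -> tuple[CohortProfile, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: closed abundance profile, metadata, truth.

    Output is a pure function of ``(spec, cohort_id)``.
    """
    if not cohort_id:
        raise ValueError("cohort_id must be non-empty")
    n = spec.n_samples
    if n == 0:
        raise ValueError("group_sizes sum to zero samples")

    stages_per_sample: list[Stage] = []
    for stage in Stage:
        stages_per_sample.extend([stage] * spec.group_sizes.get(stage, 0))
    sample_ids = [f"{cohort_id}_s{i:04d}" for i in range(n)]
    steps = np.array([STAGE_EFFECT_STEPS[s] for s in stages_per_sample])

    directions = _planted_directions(spec)
    feature_ids = [f"feat_{j:05d}" for j in range(spec.n_features)]

    intensities = np.empty((n, spec.n_features))
    for j, fid in enumerate(feature_ids):
        # Baseline log-intensity is a cohort-independent function of the
        # feature index, so both cohorts share the same abundance structure.
        # Planted markers start low-to-mid abundance: disease-associated
        # genes are not dominant community members, and a small baseline
        # share keeps closure-induced saturation from eroding their fold.
        base_rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0, j)))
        if fid in directions:
            mu = base_rng.normal(-3.0, 1.0)
        else:
            mu = base_rng.normal(0.0, 2.0)
        rng = _feature_rng(spec.seed, cohort_id, j, purpose=1)
        batch = rng.normal(0.0, spec.cohort_batch_sd) if spec.cohort_batch_sd > 0 else 0.0
        sign = {"up": 1.0, "down": -1.0}.get(directions.get(fid, ""), 0.0)
        log_mean = mu + batch + sign * spec.per_step_log_fold * steps
        noise = rng.normal(0.0, spec.dispersion, size=n)
        keep = rng.random(n) >= spec.zero_inflation
        intensities[:, j] = np.exp(log_mean + noise) * keep

    # guard against an all-dropout sample: re-seat the most abundant feature
    row_sums = intensities.sum(axis=1)
    for i in np.nonzero(row_sums == 0)[0]:
        intensities[i, 0] = 1.0
        row_sums[i] = 1.0
    abundances = intensities / row_sums[:, None]

    profile = CohortProfile(
        pd.DataFrame(abundances, index=sample_ids, columns=feature_ids),
        level=level,
        cohort_id=cohort_id,
    )
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "stage": [s.name for s in stages_per_sample],
            "cohort": cohort_id,
        }
    ).set_index("sample_id", drop=False)
    metadata["fit_ug_g"] = generate_fit_values(metadata, spec.fit_params, seed=spec.seed)
    demo_rng = _feature_rng(spec.seed, cohort_id, 0, purpose=3)
    metadata["age"] = np.round(demo_rng.normal(60.0, 10.0, size=n), 1)
    metadata["sex"] = np.where(demo_rng.random(n) < 0.5, "F", "M")

    truth = SyntheticTruth(
        directions=directions,
        stages={sid: s.name for sid, s in zip(sample_ids, stages_per_sample)},
        seed=spec.seed,
    )
    return profile, metadata, truth


def generate_fit_values(
    metadata: pd.DataFrame, fit_params: dict[Stage, tuple[float, float]], seed: int
) -> np.ndarray:
    """Per-sample FIT (ug hemoglobin / g dry stool), truncated-normal per stage.

    Values are non-negative and their expectation rises with stage severity
    under the default parameters; only the binarized value (>20 ug/g) enters
    downstream scoring.
    """
    if metadata["stage"].isna().any():
        raise ValueError("every sample needs a stage label to draw FIT values")
    params = {Stage.parse(k): tuple(v) for k, v in fit_params.items()}
    cohorts = metadata["cohort"].astype(str) if "cohort" in metadata else pd.Series("", index=metadata.index)
    values = np.empty(len(metadata))
    for i, (stage_name, cohort) in enumerate(zip(metadata["stage"], cohorts)):
        stage = Stage.parse(stage_name)
        if stage not in params:
            raise ValueError(f"no fit_params for stage {stage.name}")
        mean, sd = params[stage]
        if mean < 0:
            raise ValueError(f"negative FIT mean configured for {stage.name}")
        rng = _feature_rng(seed, str(cohort), i, purpose=2)
        if sd == 0:
            values[i] = mean
        else:
            a = (0.0 - mean) / sd
            values[i] = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)
    return values


def generate_two_cohort_study(
    spec: SyntheticSpec, cohort_ids: tuple[str, str] = ("discovery1", "discovery2"), level: str = "gene"
) -> tuple[tuple[CohortProfile, pd.DataFrame], tuple[CohortProfile, pd.DataFrame], SyntheticTruth]:
    """Two cohorts with independent noise/batch but one shared planted truth."""
    (p1, m1, t1) = generate_cohort(spec, cohort_ids[0], level=level)
    (p2, m2, t2) = generate_cohort(spec, cohort_ids[1], level=level)
    assert t1.directions == t2.directions
    truth = SyntheticTruth(
        directions=t1.directions,
        stages={**t1.stages, **t2.stages},
        seed=spec.seed,
    )
    return (p1, m1), (p2, m2), truth
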