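"""End-to-end orchestration: simulate -> discover -> train -> combine -> evaluate.

The pipeline mirrors a two-discovery-cohort study design: progressive
markers are discovered on two cohorts, effect indexes are trained on the
pooled discovery samples, and performance is measured on an independent
validation cohort (simulated with the same spec when running synthetically).
Every artifact is a TSV or JSON file stamped with the config hash and
package version, and a run is a pure function of (config, seed): re-running
the same config writes byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effect_index import (
    INDEX_DEFINITIONS,
    TrainingOptions,
    fit_effect_index,
    progressive_disease_index,
    score_samples,
)
from .evaluation import evaluate_calls
from .fit_integration import FitConfig, binarize_fit, refit_combined
from .markers import (
    SpeciesPanelParams,
    mcc_panel_select,
    mrmr_rank,
    progressive_filter,
    wilcoxon_prefilter,
)
from .profiles import (
    CohortProfile,
    read_abundance_table,
    read_metadata,
    write_abundance_table,
    write_metadata,
)
from .stages import Stage, collapse_stage
from .synthetic import SyntheticSpec, generate_cohort

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    synthetic: dict | None = None  # SyntheticSpec kwargs; None = load from paths
    cohort1_profile: str | None = None
    cohort1_metadata: str | None = None
    cohort2_profile: str | None = None
    cohort2_metadata: str | None = None
    validation_profile: str | None = None
    validation_metadata: str | None = None
    orientation: str = "samples_by_features"
    fdr_threshold: float = 0.05
    fold_threshold: float = 1.5
    panel: dict = dataclasses.field(default_factory=dict)  # SpeciesPanelParams kwargs
    training: dict = dataclasses.field(default_factory=dict)  # TrainingOptions kwargs
    fit_threshold: float = 20.0
    ci_reps: int = 500
    run_species_panel: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def canonical(self) -> str:
        # out_dir is where artifacts land, not what they are: keep the hash
        # path-independent so relocated runs stay comparable
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return json.dumps(fields, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.digest(), "version": __version__}


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _synthetic_spec(config: PipelineConfig) -> SyntheticSpec:
    kwargs = dict(config.synthetic or {})
    kwargs.setdefault("seed", config.seed)
    if "group_sizes" in kwargs:
        kwargs["group_sizes"] = {Stage.parse(k): v for k, v in kwargs["group_sizes"].items()}
    try:
        return SyntheticSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid synthetic spec: {exc}") from None


def _load_cohort(profile_path, metadata_path, orientation, cohort_id) -> tuple[CohortProfile, pd.DataFrame]:
    if not profile_path or not metadata_path:
        raise ConfigError(f"missing profile/metadata path for {cohort_id}")
    for p in (profile_path, metadata_path):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    profile = read_abundance_table(profile_path, orientation, cohort_id=cohort_id)
    metadata = read_metadata(metadata_path)
    missing = set(profile.sample_ids) - set(metadata["sample_id"])
    if missing:
        raise DataError(f"samples without metadata: {sorted(missing)[:5]}")
    return profile, metadata.loc[profile.sample_ids]


def _get_cohorts(config: PipelineConfig, out: Path):
    """Three (profile, metadata) pairs: discovery 1+2 and validation."""
    if config.synthetic is not None:
        spec = _synthetic_spec(config)
        cohorts = {}
        for cid in ("discovery1", "discovery2", "validation"):
            profile, metadata, truth = generate_cohort(spec, cid)
            cohorts[cid] = (profile, metadata)
            write_abundance_table(profile, out / f"{cid}_profile.tsv")
            write_metadata(metadata, out / f"{cid}_metadata.tsv")
            if cid == "discovery1":
                (out / "truth.json").write_text(truth.to_json() + "\n")
        return cohorts["discovery1"], cohorts["discovery2"], cohorts["validation"]
    c1 = _load_cohort(config.cohort1_profile, config.cohort1_metadata, config.orientation, "discovery1")
    c2 = _load_cohort(config.cohort2_profile, config.cohort2_metadata, config.orientation, "discovery2")
    if config.validation_profile:
        cv = _load_cohort(config.validation_profile, config.validation_metadata, config.orientation, "validation")
    else:
        cv = None
    return c1, c2, cv


def run_discovery(config: PipelineConfig) -> dict:
    """Discover progressive markers (and the species panel) on two cohorts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort1, cohort2, _ = _get_cohorts(config, out)

    marker_set = progressive_filter(
        cohort1, cohort2, fdr_threshold=config.fdr_threshold, fold_threshold=config.fold_threshold
    )
    marker_set.to_frame().to_csv(out / "progressive_markers.tsv", sep="\t", index=False)

    # auditable funnel: how many features pass each clause in each cohort
    funnel = {}
    for label, (profile, metadata) in (("cohort1", cohort1), ("cohort2", cohort2)):
        from .markers import _cohort_stats

        st = _cohort_stats(profile, metadata, config.fold_threshold, marker_set.pseudocount)
        funnel[label] = {
            "n_features": len(st),
            "q_pass": sum(s.q < config.fdr_threshold for s in st),
            "fold_pass": sum(s.direction != "none" for s in st),
            "both_pass": sum(s.q < config.fdr_threshold and s.direction != "none" for s in st),
        }
    funnel["retained"] = len(marker_set.markers)

    artifacts = {
        **_provenance(config),
        "markers": marker_set.markers,
        "params": {
            "fdr_threshold": marker_set.fdr_threshold,
            "fold_threshold": marker_set.fold_threshold,
            "pseudocount": marker_set.pseudocount,
        },
        "funnel": funnel,
    }

    if config.run_species_panel:
        profile1, metadata1 = cohort1
        groups = metadata1["stage"].map(lambda s: collapse_stage(s))
        mask = groups.isin(["NC", "AA"]).to_numpy()
        labels = (groups[mask] == "AA").astype(int).to_numpy()
        sub = CohortProfile(profile1.data.loc[mask], profile1.level, profile1.cohort_id)
        panel_params = SpeciesPanelParams(**config.panel) if config.panel else SpeciesPanelParams(seed=config.seed)
        candidates = wilcoxon_prefilter(sub, labels, panel_params.prefilter_alpha)
        if len(candidates) >= 2:
            top_k = min(panel_params.mrmr_top_k, len(candidates))
            ranked = mrmr_rank(sub.restrict(candidates), labels, top_k)
            if panel_params.panel_size is not None and panel_params.panel_size > top_k:
                panel_params = dataclasses.replace(panel_params, panel_size=top_k)
            panel = mcc_panel_select(ranked, sub, labels, panel_params)
            pd.DataFrame({"feature_id": panel.feature_ids}).to_csv(out / "species_panel.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"prefix": np.arange(1, len(panel.mcc_curve) + 1), "cv_mcc": panel.mcc_curve}
            ).to_csv(out / "panel_mcc_curve.tsv", sep="\t", index=False)
            artifacts["species_panel"] = panel.feature_ids
        else:
            artifacts["species_panel"] = []

    _write_json(out / "discovery.json", artifacts)
    return artifacts


def run_diagnosis(config: PipelineConfig) -> dict:
    """Train the effect indexes on pooled discovery samples, evaluate on the
    validation cohort, and combine CRC indexes with binarized FIT."""
    out = Path(config.out_dir)
    discovery_path = out / "discovery.json"
    if not discovery_path.exists():
        run_discovery(config)
    marker_ids = list(json.loads(discovery_path.read_text())["markers"])
    if not marker_ids:
        raise DataError("no progressive markers discovered; cannot train indexes")

    cohort1, cohort2, validation = _get_cohorts(config, out)
    train_profile = CohortProfile(
        pd.concat([cohort1[0].data, cohort2[0].data])[marker_ids], cohort1[0].level, "training"
    )
    train_meta = pd.concat([cohort1[1], cohort2[1]])
    options = TrainingOptions(**config.training) if config.training else TrainingOptions()

    report: dict = {**_provenance(config), "indexes": {}, "combined": {}}
    index_scores_val: dict[str, pd.Series] = {}
    trained_models: dict[str, object] = {}
    fit_cfg = FitConfig(config.fit_threshold)

    for name, definition in INDEX_DEFINITIONS.items():
        try:
            model = fit_effect_index(train_profile, train_meta, definition, options)
        except ValueError as exc:
            warnings.warn(f"skipping {name}: {exc}")
            report["indexes"][name] = {"skipped": str(exc)}
            continue
        trained_models[name] = model
        (out / f"model_{name}.json").write_text(model.to_json() + "\n")
        if validation is not None:
            vprofile, vmeta = validation
            scores = score_samples(model, vprofile.restrict(marker_ids))
            index_scores_val[name] = scores
            stage_series = vmeta.set_index("sample_id")["stage"]
            included = [
                sid
                for sid in scores.index
                if Stage.parse(stage_series[sid]) in (definition.positive_stages | definition.negative_stages)
            ]
            truth = np.array(
                [Stage.parse(stage_series[sid]) in definition.positive_stages for sid in included]
            )
            s = scores.loc[included].to_numpy()
            calls = s > model.cutoff
            result = evaluate_calls(calls, truth, scores=s, ci_seed=config.seed, ci_reps=config.ci_reps)
            report["indexes"][name] = result.to_dict()
            scores.rename("score").to_frame().assign(index=name).to_csv(
                out / f"scores_{name}.tsv", sep="\t", index_label="sample_id"
            )

    # Progressive Disease Index over all six stages
    pdi_model, pdi_train_scores, warning_line = progressive_disease_index(train_profile, train_meta, options)
    (out / "model_PDI.json").write_text(pdi_model.to_json() + "\n")
    if validation is not None:
        vprofile, vmeta = validation
        pdi_scores = score_samples(pdi_model, vprofile.restrict(marker_ids))
        pdi_scores.rename("score").to_frame().to_csv(out / "scores_PDI.tsv", sep="\t", index_label="sample_id")
        stage_series = vmeta.set_index("sample_id")["stage"]
        medians = {
            stage.name: float(np.median([pdi_scores[s] for s in pdi_scores.index if stage_series[s] == stage.name]))
            for stage in Stage
            if (stage_series == stage.name).any()
        }
        report["pdi"] = {"warning_line": warning_line, "stage_medians": medians}

    # FIT combination for the CRC indexes, trained on discovery FIT + scores
    if validation is not None and "fit_ug_g" in train_meta.columns and not train_meta["fit_ug_g"].isna().all():
        vprofile, vmeta = validation
        stage_series = vmeta.set_index("sample_id")["stage"]
        for combo, index_name in (("score1", "CEI1"), ("score2", "CEI2")):
            if index_name not in index_scores_val:
                continue
            definition = INDEX_DEFINITIONS[index_name]
            model = trained_models[index_name]
            train_scores = score_samples(model, train_profile)
            tmeta = train_meta.set_index("sample_id")
            included = [
                sid for sid in train_scores.index
                if Stage.parse(tmeta.loc[sid, "stage"]) in (definition.positive_stages | definition.negative_stages)
            ]
            fit_bin = np.array([binarize_fit(float(tmeta.loc[sid, "fit_ug_g"]), fit_cfg) for sid in included])
            labels = np.array([Stage.parse(tmeta.loc[sid, "stage"]) in definition.positive_stages for sid in included])
            cmodel = refit_combined(fit_bin, train_scores.loc[included].to_numpy(), labels,
                                    name=combo, index_name=index_name)
            vincluded = [
                sid for sid in index_scores_val[index_name].index
                if Stage.parse(stage_series[sid]) in (definition.positive_stages | definition.negative_stages)
            ]
            vm = vmeta.set_index("sample_id")
            vfit = np.array([binarize_fit(float(vm.loc[sid, "fit_ug_g"]), fit_cfg) for sid in vincluded])
            vidx = index_scores_val[index_name].loc[vincluded].to_numpy()
            vscores = cmodel.intercept + cmodel.fit_coef * vfit + cmodel.index_coef * vidx
            vtruth = np.array([Stage.parse(stage_series[sid]) in definition.positive_stages for sid in vincluded])
            result = evaluate_calls(vscores > cmodel.cutoff, vtruth, scores=vscores,
                                    ci_seed=config.seed, ci_reps=config.ci_reps)
            report["combined"][combo] = {
                "model": dataclasses.asdict(cmodel),
                **result.to_dict(),
            }

    _write_json(out / "report.json", report)
    return report


def run_report(artifact_dir) -> str:
    """Render the evaluation report as a plain-text table."""
    out = Path(artifact_dir)
    report_path = out / "report.json"
    missing = [p.name for p in (report_path,) if not p.exists()]
    if missing:
        raise DataError(f"missing artifacts in {out}: {missing}")
    report = json.loads(report_path.read_text())
    lines = [
        f"progdx report (config {report.get('config_hash', '?')}, version {report.get('version', '?')})",
        f"{'variable':<18}{'AUC':>8}{'95% CI':>18}{'sensitivity':>20}{'specificity':>20}",
    ]

    def fmt_row(name: str, entry: dict) -> str:
        if "skipped" in entry:
            return f"{name:<18}  skipped: {entry['skipped']}"
        ci = entry.get("auc_ci")
        ci_txt = f"{ci[0]:.3f}-{ci[1]:.3f}" if ci else "-"
        auc = f"{entry['auc']:.3f}" if entry.get("auc") is not None else "-"
        sens = f"{entry['sensitivity_pct']}% ({entry['sensitivity_fraction']})"
        spec = f"{entry['specificity_pct']}% ({entry['specificity_fraction']})"
        return f"{name:<18}{auc:>8}{ci_txt:>18}{sens:>20}{spec:>20}"

    for name, entry in report.get("indexes", {}).items():
        lines.append(fmt_row(name, entry))
    for name, entry in report.get("combined", {}).items():
        lines.append(fmt_row(name + "+FIT", entry))
    if "pdi" in report:
        stage_medians = report["pdi"]["stage_medians"]
        ordered = [s.name for s in Stage if s.name in stage_medians]
        med = ", ".join(f"{k}={stage_medians[k]:.1f}" for k in ordered)
        lines.append(f"PDI warning line {report['pdi']['warning_line']}; stage medians: {med}")
    return "\n".join(lines)
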