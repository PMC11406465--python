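"""End-to-end orchestration: simulate -> score -> analyze -> voxelwise.

A single YAML-expressible configuration (validated by pydantic) drives the
four stages, writes versioned outputs per stage, and records provenance
(config hash, seeds, package version) in a machine-readable JSON run
report.  Every source of randomness takes an explicit seed derived from
the config, so two runs of the same config produce identical numeric
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import InterofatError
from .intero import score_subject
from .metacog import ConfidenceCountTable, fit_meta_dprime
from .regression import (
    DEFAULT_COVARIATES,
    dichotomize,
    group_comparison_table,
    logistic_model_table,
)
from .synthetic import (
    CohortParams,
    EffectFieldSpec,
    simulate_cohort,
    simulate_skeleton_maps,
    write_ground_truth,
    write_trial_tables,
)
from .voxelwise import (
    extract_cluster_means,
    interaction_design,
    permutation_inference,
    write_skeleton_set,
    write_volume,
)

logger = logging.getLogger(__name__)


class CohortConfig(BaseModel):
    n_subjects: int = 36
    beta_intercept: float = 0.8
    beta_insight_high: float = float(np.log(0.29))
    p_high_insight: float = 0.5


class EffectFieldConfig(BaseModel):
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    skeleton_fraction: float = 0.15
    gamma_fatigue: float = 0.04
    gamma_insight: float = 0.0
    gamma_interaction: float = -0.12
    noise_sd: float = 0.05
    smoothing_fwhm_vox: float = 2.0
    modalities: list[str] = Field(default_factory=lambda: ["FA"])


class AnalysisConfig(BaseModel):
    fatigue_cutoff: str | float = "median"
    alpha_screen: float = 0.25
    covariates: list[str] = Field(default_factory=lambda: list(DEFAULT_COVARIATES))


class VoxelwiseConfig(BaseModel):
    n_perm: int = 200
    behavioural_variable: str = "htt_insight_r"
    covariates: list[str] = Field(default_factory=list)
    tfce_E: float = 1.0
    tfce_H: float = 2.0
    connectivity: int = 26
    alpha: float = 0.05
    tail: str = "pos"


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; the seed is mandatory."""

    seed: int
    cohort: CohortConfig = CohortConfig()
    effect_field: EffectFieldConfig = EffectFieldConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    voxelwise: VoxelwiseConfig = VoxelwiseConfig()

    @field_validator("seed")
    @classmethod
    def _seed_bounds(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("cohort", "maps", "voxelwise")
    return {n: int(s.generate_state(1)[0] % 2**31) for n, s in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, returning (and writing) the machine-readable report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "interofat_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
    }

    try:
        cohort, maps_by_mod, region = _stage_simulate(config, seeds, out_dir, report)
        scores = _stage_score(cohort, out_dir, report)
        cohort_scored = cohort.merge(scores, on="subject_id")
        _stage_analyze(config, cohort_scored, out_dir, report)
        _stage_voxelwise(config, seeds, cohort_scored, maps_by_mod, region, out_dir, report)
    except InterofatError as exc:
        stage = report.get("failed_stage", "unknown")
        raise InterofatError(f"pipeline halted in stage {stage!r}: {exc}") from exc

    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_simulate(config: RunConfig, seeds, out_dir: Path, report: dict):
    report["failed_stage"] = "simulate"
    stage_dir = out_dir / "simulate"
    cp = CohortParams(
        n_subjects=config.cohort.n_subjects,
        beta_intercept=config.cohort.beta_intercept,
        beta_insight_high=config.cohort.beta_insight_high,
        p_high_insight=config.cohort.p_high_insight,
        seed=seeds["cohort"],
    )
    cohort = simulate_cohort(cp)
    paths = write_trial_tables(cohort, stage_dir)

    maps_by_mod = {}
    region = None
    for modality in config.effect_field.modalities:
        spec = EffectFieldSpec(
            grid_shape=tuple(config.effect_field.grid_shape),
            skeleton_fraction=config.effect_field.skeleton_fraction,
            gamma_fatigue=config.effect_field.gamma_fatigue,
            gamma_insight=config.effect_field.gamma_insight,
            gamma_interaction=config.effect_field.gamma_interaction,
            noise_sd=config.effect_field.noise_sd,
            smoothing_fwhm_vox=config.effect_field.smoothing_fwhm_vox,
            modality=modality,
        )
        maps, mask, region = simulate_skeleton_maps(cohort, spec, seed=seeds["maps"])
        map_paths, mask_path = write_skeleton_set(maps, stage_dir / f"maps_{modality}")
        maps_by_mod[modality] = maps
        write_ground_truth(spec, region, cp, stage_dir / f"ground_truth_{modality}.json")
    report["stages"]["simulate"] = {
        "n_subjects": len(cohort),
        "outputs": {k: str(v) for k, v in paths.items()},
        "n_effect_voxels": int(region.sum()) if region is not None else 0,
    }
    return cohort, maps_by_mod, region


def _stage_score(cohort: pd.DataFrame, out_dir: Path, report: dict) -> pd.DataFrame:
    report["failed_stage"] = "score"
    rows = []
    for _, row in cohort.iterrows():
        s = score_subject(row["htt_trials"], row["hdt_trials"])
        rec = {
            "subject_id": row["subject_id"],
            "htt_accuracy": s.htt_accuracy,
            "htt_insight_r": s.htt_insight_r,
            "hdt_accuracy": s.hdt_accuracy,
            "hdt_insight_auc": s.hdt_insight_auc,
            "htt_insight_low_trial": s.htt_insight_low_trial,
        }
        for task in ("visual", "memory"):
            tab = ConfidenceCountTable.from_trials(row[f"metacog_trials_{task}"])
            fit = fit_meta_dprime(tab)
            rec[f"d_prime_{task}"] = fit.d_prime
            rec[f"meta_d_prime_{task}"] = fit.meta_d_prime
            rec[f"metacog_efficiency_{task}"] = fit.efficiency
            rec[f"metacog_converged_{task}"] = fit.converged
        rows.append(rec)
    scores = pd.DataFrame(rows)
    path = out_dir / "scores.csv"
    scores.to_csv(path, index=False)
    report["stages"]["score"] = {"n_subjects": len(scores), "output": str(path)}
    return scores


def _stage_analyze(config: RunConfig, cohort: pd.DataFrame, out_dir: Path, report: dict) -> None:
    report["failed_stage"] = "analyze"
    stage_dir = out_dir / "analyze"
    stage_dir.mkdir(parents=True, exist_ok=True)

    y, cutoff = dichotomize(cohort["mfis_cog"], config.analysis.fatigue_cutoff)
    cohort = cohort.assign(high_fatigue_observed=y)

    table1 = group_comparison_table(
        cohort,
        "high_fatigue_observed",
        ["age_years", "education_years", "edss", "disease_duration_years",
         "hads_a", "hads_d", "ess", "sex", "dmt_class"],
    )
    table1.to_csv(stage_dir / "group_comparisons.csv", index=False)

    predictors = {}
    for name in ("htt_insight_r", "htt_accuracy", "hdt_insight_auc", "hdt_accuracy",
                 "metacog_efficiency_visual", "metacog_efficiency_memory"):
        labels, cut = dichotomize(cohort[name], "median")
        predictors[name] = labels
    pred_df = pd.DataFrame(predictors, index=cohort.index)
    cov_df = cohort[list(config.analysis.covariates)]
    if "sex" in cov_df.columns and cov_df["sex"].dtype == object:
        cov_df = cov_df.assign(sex=(cov_df["sex"] == "F").astype(float))
    table2 = logistic_model_table(y, pred_df, cov_df, config.analysis.alpha_screen)
    table2.to_csv(stage_dir / "logistic_models.csv", index=False)

    lines = [f"High cognitive fatigue cutoff: {cutoff:g} "
             f"({int(np.nansum(y))} high / {int(np.nansum(1 - y))} mild)", ""]
    for _, r in table2.iterrows():
        lines.append(
            f"{r['predictor']}: unadjusted OR {r['or_unadjusted']:.2f} "
            f"[{r['ci_low_unadjusted']:.2f}, {r['ci_high_unadjusted']:.2f}] p={r['p_unadjusted']:.3f}; "
            f"adjusted OR {r['or_adjusted']:.2f} "
            f"[{r['ci_low_adjusted']:.2f}, {r['ci_high_adjusted']:.2f}] p={r['p_adjusted']:.3f}"
        )
    (stage_dir / "report.txt").write_text("\n".join(lines) + "\n")
    report["stages"]["analyze"] = {
        "fatigue_cutoff": cutoff,
        "n_high_fatigue": int(np.nansum(y)),
        "outputs": [str(stage_dir / p) for p in
                    ("group_comparisons.csv", "logistic_models.csv", "report.txt")],
    }


def _stage_voxelwise(
    config: RunConfig, seeds, cohort: pd.DataFrame, maps_by_mod, region, out_dir: Path, report: dict
) -> None:
    report["failed_stage"] = "voxelwise"
    stage_dir = out_dir / "voxelwise"
    stage_dir.mkdir(parents=True, exist_ok=True)
    vw = config.voxelwise
    stage_report = {}
    for modality, maps in maps_by_mod.items():
        design = interaction_design(
            cohort, vw.behavioural_variable, covariates=vw.covariates
        )
        res = permutation_inference(
            maps, design, "interaction",
            n_perm=vw.n_perm, seed=seeds["voxelwise"],
            tail=vw.tail, alpha=vw.alpha,
            E=vw.tfce_E, H=vw.tfce_H, connectivity=vw.connectivity,
        )
        vx = maps[0].voxel_size_mm
        write_volume(res.t_map, stage_dir / f"{modality}_tstat.nii", vx)
        write_volume(res.tfce_map, stage_dir / f"{modality}_tfce.nii", vx)
        write_volume(res.fwe_p_map, stage_dir / f"{modality}_fwe_p.nii", vx)
        write_volume(res.significance_mask.astype(float), stage_dir / f"{modality}_sig.nii", vx)

        n_sig = int(res.significance_mask.sum())
        entry = {"n_significant_voxels": n_sig, "n_permutations": res.n_permutations,
                 "min_fwe_p": float(res.fwe_p_map[maps[0].mask].min())}
        if n_sig:
            means = extract_cluster_means(maps, res.significance_mask)
            means = means.merge(
                cohort[["subject_id", "mfis_cog", vw.behavioural_variable]], on="subject_id"
            )
            labels, _ = dichotomize(means[vw.behavioural_variable], "median")
            means["insight_level"] = labels
            means.to_csv(stage_dir / f"{modality}_cluster_means.csv", index=False)
            _interaction_plot(means, modality, stage_dir / f"{modality}_interaction.png")
            slopes = {}
            for lvl, grp in means.groupby("insight_level"):
                if grp["mfis_cog"].nunique() > 1:
                    slopes[f"slope_insight_{int(lvl)}"] = float(
                        np.polyfit(grp["mfis_cog"], grp["cluster_mean"], 1)[0]
                    )
            entry["fatigue_slopes_by_insight"] = slopes
        stage_report[modality] = entry
    report["stages"]["voxelwise"] = stage_report
    report.pop("failed_stage", None)


def _interaction_plot(means: pd.DataFrame, modality: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lvl, grp in means.groupby("insight_level"):
        label = "high insight" if lvl == 1 else "low insight"
        ax.scatter(grp["mfis_cog"], grp["cluster_mean"], label=label, alpha=0.8)
        if grp["mfis_cog"].nunique() > 1:
            coef = np.polyfit(grp["mfis_cog"], grp["cluster_mean"], 1)
            xs = np.linspace(grp["mfis_cog"].min(), grp["mfis_cog"].max(), 10)
            ax.plot(xs, np.polyval(coef, xs))
    ax.set_xlabel("MFIS-Cog")
    ax.set_ylabel(f"mean {modality} in significant voxels")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
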