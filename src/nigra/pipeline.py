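"""End-to-end orchestration: phantom -> ESNV / R2* / Ki -> statistics -> report.

One YAML config drives the whole run. The stage order mirrors the
analysis chartflow of a multimodal PD imaging study: generate (or load)
the cohort, flip maps so the clinically most affected side is on the
left, quantify each modality, then run the five voxelwise analysis
families —

1. group effect on R2* (PD > HC), small-volume corrected over the
   bilateral lateral/medial SN masks;
2. group effect on Ki (HC > PD), corrected over the bilateral
   anterior/posterior putamen masks;
3. group x ESNV-skewness interaction on R2* (SN masks);
4. group x ESNV-skewness interaction on Ki (putamen masks);
5. group x lateral-SN-R2* interaction on Ki (putamen masks);

— plus the ROI-level statistics (skewness mixed model, demographics,
clinical correlations, triple interaction) and a ground-truth recovery
table. A master seed spawns per-stage child seeds deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from nigra import nm_esnv, pet_patlak, phantom, r2star, roi_stats, voxel_stats
from nigra.volumes import ImageVolume, flip_lateralized, gaussian_smooth

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

ANALYSIS_DEFAULTS = {
    "atlas_threshold_au": 4.0,
    "t_star_min": 30.0,
    "fwhm_mm": 4.0,
    "alpha": 0.05,
    "n_perm": 500,
    "background_stat": "median",
    "skewness_estimator": "G1",
    "smooth_maps": True,
}


@dataclass
class PipelineConfig:
    phantom: phantom.PhantomConfig
    seed: int
    atlas_threshold_au: float = 4.0
    t_star_min: float = 30.0
    fwhm_mm: float = 4.0
    alpha: float = 0.05
    n_perm: int = 500
    background_stat: str = "median"
    skewness_estimator: str = "G1"
    smooth_maps: bool = True
    output_dir: str | None = None


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse and schema-check a pipeline config, filling defaults.

    Accepts a YAML path or an already-parsed mapping. All problems are
    collected and reported in a single ValueError.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    known_top = {"phantom", "analysis", "seed", "output_dir"}
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown top-level key {key!r}")
    seed = raw.get("seed")
    if seed is None:
        errors.append("missing required key 'seed'")
    elif not isinstance(seed, int):
        errors.append("'seed' must be an integer")

    analysis = dict(ANALYSIS_DEFAULTS)
    user_analysis = raw.get("analysis") or {}
    for key, value in user_analysis.items():
        if key not in ANALYSIS_DEFAULTS:
            errors.append(f"unknown analysis key {key!r}")
        else:
            analysis[key] = value
    if not (0.0 < float(analysis["alpha"]) < 1.0):
        errors.append("alpha must lie in (0, 1)")
    if analysis["background_stat"] not in ("median", "mean"):
        errors.append("background_stat must be 'median' or 'mean'")
    if analysis["skewness_estimator"] not in ("g1", "G1"):
        errors.append("skewness_estimator must be 'g1' or 'G1'")
    if int(analysis["n_perm"]) < 100:
        errors.append("n_perm must be >= 100")

    ph_raw = raw.get("phantom") or {}
    ph_cfg = None
    try:
        eff = phantom.EffectSpec(**(ph_raw.pop("effects", None) or {}))
        noise = phantom.NoiseSpec(**(ph_raw.pop("noise", None) or {}))
        known = {f.name for f in dataclasses.fields(phantom.PhantomConfig)}
        for key in ph_raw:
            if key not in known:
                errors.append(f"unknown phantom key {key!r}")
        ph_kwargs = {k: v for k, v in ph_raw.items() if k in known}
        for tup_key in ("grid_shape", "te_list", "s0_levels", "cref_rates_per_min", "pd_severity_range"):
            if tup_key in ph_kwargs:
                ph_kwargs[tup_key] = tuple(ph_kwargs[tup_key])
        if "frame_schedule" in ph_kwargs:
            ph_kwargs["frame_schedule"] = tuple(
                (int(c), float(d)) for c, d in ph_kwargs["frame_schedule"]
            )
        ph_kwargs["seed"] = seed if isinstance(seed, int) else 0
        ph_cfg = phantom.PhantomConfig(effects=eff, noise=noise, **ph_kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"phantom section: {exc}")

    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return PipelineConfig(
        phantom=ph_cfg,
        seed=int(seed),
        output_dir=raw.get("output_dir"),
        **{k: type(ANALYSIS_DEFAULTS[k])(v) for k, v in analysis.items()},
    )


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/failed/skipped
    esnv_table: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    lmm: roi_stats.MixedModelResult | None = None
    demographics: dict = field(default_factory=dict)
    clinical: pd.DataFrame | None = None
    triple_interaction: dict | None = None
    recovery: pd.DataFrame | None = None
    sign_summary: dict[str, bool] = field(default_factory=dict)
    config_fingerprint: str = ""
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _fingerprint(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "phantom": dataclasses.asdict(config.phantom),
            "analysis": {
                k: getattr(config, k) for k in ANALYSIS_DEFAULTS
            },
            "seed": config.seed,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _pooled_masks(rois) -> dict[str, np.ndarray]:
    return {
        "sn_lateral_bilateral": rois.union(["sn_lateral_left", "sn_lateral_right"]),
        "sn_medial_bilateral": rois.union(["sn_medial_left", "sn_medial_right"]),
        "putamen_anterior_bilateral": rois.union(
            ["putamen_anterior_left", "putamen_anterior_right"]
        ),
        "putamen_posterior_bilateral": rois.union(
            ["putamen_posterior_left", "putamen_posterior_right"]
        ),
    }


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> RunReport:
    """Execute every stage; on a stage failure, mark it and skip downstream."""
    report = RunReport(config_fingerprint=_fingerprint(config))
    out = Path(output_dir or config.output_dir) if (output_dir or config.output_dir) else None
    rng_seeds = np.random.SeedSequence(config.seed).spawn(8)

    # ---- stage: phantom cohort -------------------------------------------
    try:
        dataset = phantom.generate_cohort(config.phantom)
        atlas = dataset.atlas
        rois = atlas.rois
        pooled = _pooled_masks(rois)
        report.stages["phantom"] = "ok"
    except Exception as exc:  # pragma: no cover - config errors surface here
        report.stages["phantom"] = "failed"
        report.errors["phantom"] = str(exc)
        _finish(report, out)
        return report

    subjects_df = phantom.subject_table(dataset.subjects)
    side = dict(zip(subjects_df["subject_id"], subjects_df["most_affected_side"]))

    # ---- stage: quantification (flip + ESNV + R2* + Ki) ------------------
    try:
        sched = config.phantom.schedule()
        nm_flipped: dict[str, ImageVolume] = {}
        r2_maps: list[ImageVolume] = []
        ki_maps: list[ImageVolume] = []
        occ = rois["occipital"]
        brain = atlas.brain_mask
        for rec in dataset.subjects:
            sub = dataset.data[rec.subject_id]
            nm_flipped[rec.subject_id] = flip_lateralized(sub.nm, side[rec.subject_id])
            if len(sub.multiecho) > 1:
                series = [
                    r2star.MultiEchoSeries(vol, te, label=label)
                    for label, te, vol in sub.multiecho
                ]
                fitted = r2star.fit_r2star_estatics(series, mask=brain)
            else:
                label, te, vol = sub.multiecho[0]
                fitted = r2star.fit_r2star_loglinear(
                    r2star.MultiEchoSeries(vol, te, label=label), mask=brain
                )
            r2_map = flip_lateralized(fitted.r2star, side[rec.subject_id])
            ki_res = pet_patlak.ki_map(sub.pet, occ, sched, config.t_star_min, brain)
            ki = flip_lateralized(ki_res.ki, side[rec.subject_id])
            if config.smooth_maps and config.fwhm_mm > 0:
                r2_map = gaussian_smooth(r2_map, config.fwhm_mm, mask=brain)
                ki = gaussian_smooth(ki, config.fwhm_mm, mask=brain)
            r2_maps.append(r2_map)
            ki_maps.append(ki)
        esnv_df = nm_esnv.esnv_table(
            nm_flipped,
            rois,
            background_stat=config.background_stat,
            estimator=config.skewness_estimator,
        )
        report.esnv_table = esnv_df
        report.stages["quantification"] = "ok"
    except Exception as exc:
        report.stages["quantification"] = "failed"
        report.errors["quantification"] = str(exc)
        _finish(report, out)
        return report

    # per-subject scalar covariates
    wide = esnv_df.pivot(index="subject_id", columns="roi", values="skewness")
    wide = wide.loc[subjects_df["subject_id"]]
    skew_lat = wide["sn_lateral_bilateral"].to_numpy()
    skew_bilat = wide["sn_bilateral"].to_numpy()
    lat_mask = pooled["sn_lateral_bilateral"]
    r2_lat_median = np.array([np.median(m.data[lat_mask]) for m in r2_maps])

    # ---- stage: voxelwise families ---------------------------------------
    peaks_rows = []
    sign = {}
    try:
        families = [
            ("group_R2s_PDgtHC", r2_maps, "group_effect", None,
             {"PD": 1.0, "HC": -1.0}, "greater",
             ["sn_lateral_bilateral", "sn_medial_bilateral"]),
            ("group_Ki_HCgtPD", ki_maps, "group_effect", None,
             {"HC": 1.0, "PD": -1.0}, "greater",
             ["putamen_anterior_bilateral", "putamen_posterior_bilateral"]),
            ("groupXskew_on_R2s", r2_maps, "group_by_covariate", skew_lat,
             {"skew_PD": 1.0, "skew_HC": -1.0}, "two",
             ["sn_lateral_bilateral", "sn_medial_bilateral"]),
            ("groupXskew_on_Ki", ki_maps, "group_by_covariate", skew_bilat,
             {"skew_PD": 1.0, "skew_HC": -1.0}, "two",
             ["putamen_anterior_bilateral", "putamen_posterior_bilateral"]),
            ("groupXR2s_on_Ki", ki_maps, "group_by_covariate", r2_lat_median,
             {"r2lat_PD": 1.0, "r2lat_HC": -1.0}, "two",
             ["putamen_anterior_bilateral", "putamen_posterior_bilateral"]),
        ]
        for i, (name, maps, scheme, cov, weights, tail, mask_names) in enumerate(families):
            if scheme == "group_by_covariate":
                cov_label = list(weights)[0].rsplit("_", 1)[0]
                sdf = subjects_df.assign(**{cov_label: cov})
                design = voxel_stats.build_design(sdf, covariate=cov_label, scheme=scheme)
            else:
                design = voxel_stats.build_design(subjects_df, scheme=scheme)
            contrast = design.contrast(weights, tail=tail, description=name)
            svc = voxel_stats.small_volume_correct(
                maps,
                design,
                contrast,
                {m: pooled[m] for m in mask_names},
                n_perm=config.n_perm,
                seed=np.random.default_rng(rng_seeds[2 + i % 6]),
            )
            for mask_name, res in svc.items():
                peaks_rows.append(
                    {
                        "contrast": name,
                        "mask": mask_name,
                        "x_mm": res.peak_world_mm[0],
                        "y_mm": res.peak_world_mm[1],
                        "z_mm": res.peak_world_mm[2],
                        "t": res.peak_t,
                        "Z": res.peak_z,
                        "p_mask": res.p_mask,
                        "p_corr": res.p_corrected,
                    }
                )
            # record slope/effect signs in the ground-truth target masks
            if name == "group_R2s_PDgtHC":
                fitg = voxel_stats.fit_glm(maps, design, pooled["sn_lateral_bilateral"])
                sign["r2star_up_lateral_sn_pd"] = bool(
                    (contrast.weights @ fitg.beta).mean() > 0
                )
            if name == "group_Ki_HCgtPD":
                fitg = voxel_stats.fit_glm(maps, design, pooled["putamen_posterior_bilateral"])
                sign["ki_down_pd"] = bool((contrast.weights @ fitg.beta).mean() > 0)
            if name == "groupXskew_on_Ki":
                fitg = voxel_stats.fit_glm(maps, design, pooled["putamen_anterior_bilateral"])
                pd_slope = fitg.beta[design.columns.index("skew_PD")]
                sign["ki_skew_positive_coupling_pd"] = bool(pd_slope.mean() > 0)
            if name == "groupXR2s_on_Ki":
                fitg = voxel_stats.fit_glm(maps, design, pooled["putamen_posterior_bilateral"])
                pd_slope = fitg.beta[design.columns.index("r2lat_PD")]
                sign["ki_r2star_negative_coupling_pd"] = bool(pd_slope.mean() < 0)
        report.peaks = pd.DataFrame(peaks_rows)
        report.stages["voxelwise"] = "ok"
    except Exception as exc:
        report.stages["voxelwise"] = "failed"
        report.errors["voxelwise"] = str(exc)

    # ---- stage: ROI statistics -------------------------------------------
    try:
        long = esnv_df[esnv_df["roi"].isin(nm_esnv.SN_TIERS)].merge(
            subjects_df[["subject_id", "group", "age", "sex"]], on="subject_id"
        )
        report.lmm = roi_stats.fit_lmm_skewness(long)
        sign["skewness_down_pd"] = report.lmm.ls_means["PD"] < report.lmm.ls_means["HC"]

        sex_counts = pd.crosstab(subjects_df["group"], subjects_df["sex"])
        chi2, dfc, pc = roi_stats.pearson_chi_square(sex_counts.to_numpy())
        ages = subjects_df.groupby("group")["age"]
        t_age, df_age, p_age = roi_stats.two_sample_t(
            x=subjects_df.loc[subjects_df.group == "PD", "age"],
            y=subjects_df.loc[subjects_df.group == "HC", "age"],
        )
        report.demographics = {
            "sex_chi2": chi2, "sex_df": dfc, "sex_p": pc,
            "age_t": t_age, "age_df": df_age, "age_p": p_age,
        }

        pd_rows = subjects_df[subjects_df.group == "PD"].reset_index(drop=True)
        pd_skew = wide.loc[pd_rows["subject_id"], "sn_bilateral"].to_numpy()
        report.clinical = roi_stats.clinical_correlations(pd_skew, pd_rows)

        tri_rows = []
        sid_order = subjects_df["subject_id"].tolist()
        for j, sid in enumerate(sid_order):
            for roi_label, mask_name in (
                ("anterior", "putamen_anterior_bilateral"),
                ("posterior", "putamen_posterior_bilateral"),
            ):
                tri_rows.append(
                    {
                        "subject_id": sid,
                        "group": subjects_df.loc[j, "group"],
                        "roi": roi_label,
                        "ki": float(np.mean(ki_maps[j].data[pooled[mask_name]])),
                        "r2star_lat": float(r2_lat_median[j]),
                    }
                )
        report.triple_interaction = {
            k: v for k, v in roi_stats.roi_triple_interaction(pd.DataFrame(tri_rows)).items()
            if k != "model"
        }
        report.stages["roi_stats"] = "ok"
    except Exception as exc:
        report.stages["roi_stats"] = "failed"
        report.errors["roi_stats"] = str(exc)

    # ---- stage: ground-truth recovery ------------------------------------
    try:
        gt = dataset.ground_truth.set_index("subject_id").loc[subjects_df["subject_id"]]
        is_pd = subjects_df["group"].to_numpy() == "PD"

        def group_delta(values: np.ndarray, pd_minus_hc: bool = True) -> float:
            d = float(values[is_pd].mean() - values[~is_pd].mean())
            return d if pd_minus_hc else -d

        lat_left = rois["sn_lateral_left"]
        r2_lat_left = np.array([m.data[lat_left].mean() for m in r2_maps])
        ki_post = np.array(
            [np.nanmean(m.data[pooled["putamen_posterior_bilateral"]]) for m in ki_maps]
        )
        ki_ant = np.array(
            [np.nanmean(m.data[pooled["putamen_anterior_bilateral"]]) for m in ki_maps]
        )
        skew = wide.loc[subjects_df["subject_id"], "sn_bilateral"].to_numpy()
        report.recovery = pd.DataFrame(
            [
                {
                    "quantity": "r2star_lateral_delta_s-1",
                    "estimated": group_delta(r2_lat_left),
                    "true": group_delta(gt["true_r2star_lat"].to_numpy()),
                },
                {
                    "quantity": "ki_posterior_delta_min-1",
                    "estimated": group_delta(ki_post, pd_minus_hc=False),
                    "true": group_delta(gt["true_ki_post"].to_numpy(), pd_minus_hc=False),
                },
                {
                    "quantity": "ki_anterior_delta_min-1",
                    "estimated": group_delta(ki_ant, pd_minus_hc=False),
                    "true": group_delta(gt["true_ki_ant"].to_numpy(), pd_minus_hc=False),
                },
                {
                    "quantity": "skewness_gap",
                    "estimated": group_delta(skew),
                    "true": group_delta(gt["true_skew_sn"].to_numpy()),
                },
            ]
        )
        report.sign_summary = sign
        report.stages["recovery"] = "ok"
    except Exception as exc:
        report.stages["recovery"] = "failed"
        report.errors["recovery"] = str(exc)

    _finish(report, out)
    return report


def _finish(report: RunReport, out: Path | None) -> None:
    if out is None:
        return
    out.mkdir(parents=True, exist_ok=True)
    if report.esnv_table is not None:
        report.esnv_table.to_csv(out / "esnv.tsv", sep="\t", index=False)
    if report.peaks is not None:
        report.peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    if report.recovery is not None:
        report.recovery.to_csv(out / "recovery.tsv", sep="\t", index=False)
    if report.clinical is not None:
        report.clinical.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)
    lines = ["# Pipeline run report", "", f"Config fingerprint: `{report.config_fingerprint}`", ""]
    lines.append("## Stages")
    for stage, status in report.stages.items():
        lines.append(f"- {stage}: {status}")
    if report.errors:
        lines.append("")
        lines.append("## Errors")
        for stage, msg in report.errors.items():
            lines.append(f"- {stage}: {msg}")
    if report.demographics:
        d = report.demographics
        lines += [
            "",
            "## Demographics",
            f"- sex chi-square: {d['sex_chi2']:.4f} (df {d['sex_df']}, p = {d['sex_p']:.4f})",
            f"- age t test: t({d['age_df']:.0f}) = {d['age_t']:.2f}, p = {d['age_p']:.2f}",
        ]
    if report.lmm is not None:
        lines += [
            "",
            "## ESNV skewness mixed model",
            f"- LS-means: PD {report.lmm.ls_means['PD']:.3f}, HC {report.lmm.ls_means['HC']:.3f}",
            f"- group contrast: t({report.lmm.group_contrast_df}) = "
            f"{report.lmm.group_contrast_t:.2f}, Tukey p = {report.lmm.group_contrast_p_tukey:.4f}",
        ]
    if report.sign_summary:
        lines += ["", "## Effect-direction summary"]
        for key, val in report.sign_summary.items():
            lines.append(f"- {key}: {'yes' if val else 'no'}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
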