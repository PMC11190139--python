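"""End-to-end orchestration: simulate -> maps -> profiles -> metrics -> stats.

`run_case_control` executes the whole chain on a generated cohort and
writes a tidy results bundle (subjects CSV, per-subject profiles CSV,
metrics CSV, stats CSV/JSON, log, config snapshot); `run_within_patients`
adds the severity/medication/comorbidity/trauma analyses for the (ROI,
metric) cells gated significant in stage 1.  All randomness flows from the
config's master seed; per-subject seeds are recorded in the subjects CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import laminar, phantom, profile_metrics, stats
from .config import RunConfig
from .mp2rageme import build_t1_lookup, estimate_t1_map, estimate_t2star_map

__all__ = [
    "profiles_to_frame",
    "average_hemispheres_frame",
    "metrics_frame",
    "simulate_voxel_profiles",
    "run_case_control",
    "run_within_patients",
]

log = logging.getLogger("laminarq")


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format view of a list of :class:`laminar.DepthProfile`."""
    rows = []
    for p in profiles:
        n = len(p.depths)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": [p.subject_id] * n,
                    "roi": [p.roi] * n,
                    "hemisphere": [p.hemisphere] * n,
                    "contrast": [p.contrast] * n,
                    "depth_bin": np.arange(1, n + 1),
                    "depth": p.depths,
                    "value": p.values,
                    "n_voxels": p.n_voxels,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def average_hemispheres_frame(profiles: pd.DataFrame) -> pd.DataFrame:
    """Depthwise left/right average per subject, roi, contrast, bin."""
    lr = profiles[profiles["hemisphere"].isin(["left", "right"])]
    avg = (
        lr.groupby(
            ["subject_id", "roi", "contrast", "depth_bin", "depth"], sort=True
        )
        .agg(value=("value", "mean"), n_voxels=("n_voxels", "sum"))
        .reset_index()
    )
    avg["hemisphere"] = "averaged"
    return avg


def metrics_frame(
    avg_profiles: pd.DataFrame,
    subjects: pd.DataFrame,
    auc_from_fit: bool = True,
) -> pd.DataFrame:
    """Reduce averaged profiles to (mean, auc, offset) and attach covariates."""
    rows = []
    for (sid, roi, contrast), grp in avg_profiles.groupby(
        ["subject_id", "roi", "contrast"], sort=True
    ):
        grp = grp.sort_values("depth_bin")
        prof = laminar.DepthProfile(
            subject_id=sid,
            roi=roi,
            hemisphere="averaged",
            contrast=contrast,
            depths=grp["depth"].to_numpy(),
            values=grp["value"].to_numpy(),
            n_voxels=grp["n_voxels"].to_numpy(),
        )
        m = profile_metrics.compute_metrics(prof, auc_from_fit=auc_from_fit)
        for name, value in (
            ("mean", m.mean_value),
            ("auc", m.auc),
            ("offset", m.offset),
        ):
            rows.append(
                dict(subject_id=sid, roi=roi, contrast=contrast,
                     metric=name, value=value)
            )
    out = pd.DataFrame(rows)
    cov = subjects[
        ["subject_id", "group", "age", "sex", "ids_score", "ctq_score",
         "on_antidepressants", "comorbid_anxiety"]
    ]
    return out.merge(cov, on="subject_id", how="left")


def simulate_voxel_profiles(cohort, config: RunConfig) -> pd.DataFrame:
    """Voxel-tier chain: phantom -> images -> maps -> depth -> profiles."""
    lut = build_t1_lookup(config.acquisition)
    all_profiles = []
    for spec in cohort:
        truth = phantom.make_cortical_phantom(
            grid_shape=config.grid_shape,
            voxel_size=config.voxel_size,
            ribbon_thickness_mm=config.ribbon_thickness_mm,
            spec=spec,
            effects=config.effects,
            undulation_amp_mm=config.undulation_amp_mm,
            undulation_period_mm=config.undulation_period_mm,
        )
        images = phantom.render_subject_images(
            truth,
            config.acquisition,
            noise_sd=config.effects.noise_sd,
            seed=spec.rng_seed,
        )
        t1_map = estimate_t1_map(images["uni"], lut, config.voxel_size)
        t2s_map = estimate_t2star_map(
            images["echoes"], config.acquisition.TEs, config.voxel_size
        )
        depth = laminar.compute_depth_field(truth.labels, config.voxel_size)
        gm = truth.labels == phantom.GM
        for roi in phantom.ROI_CODES:
            for hemi in ("left", "right"):
                mask = laminar.refine_roi_mask(
                    truth.roi_mask(roi, hemi), gm, config.dilation
                )
                for qmap in (t1_map, t2s_map):
                    all_profiles.append(
                        laminar.extract_depth_profile(
                            qmap,
                            mask,
                            depth,
                            n_depths=config.n_depths,
                            min_voxels=config.min_voxels,
                            subject_id=spec.subject_id,
                            roi=roi,
                            hemisphere=hemi,
                        )
                    )
        log.info("subject %s: profiles extracted (seed %d)",
                 spec.subject_id, spec.rng_seed)
    return profiles_to_frame(all_profiles)


def _write_json(stage1, stage2, lateral, path) -> None:
    payload = {
        "case_control": stage1.to_dict(orient="records"),
        "within_patients": stage2.to_dict(orient="records") if stage2 is not None else [],
        "lateralization": lateral.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def run_case_control(config: RunConfig, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full case-control chain; optionally write artifacts.

    Returns a bundle dict with the subjects table, long profiles, the
    lateralization table, the hemisphere-averaged metrics table and the
    stage-1 case-control results.
    """
    master_seed = config.master_seed if seed is None else seed
    rng = np.random.SeedSequence(master_seed)
    cohort_seed, profile_seed = (
        int(s) for s in rng.generate_state(2) % (2**31 - 1)
    )
    log.info("master seed %d -> cohort seed %d, profile seed %d",
             master_seed, cohort_seed, profile_seed)

    cohort = phantom.generate_cohort(
        config.n_mdd, config.n_hc, config.effects, master_seed=cohort_seed
    )
    subjects = phantom.cohort_frame(cohort)

    if config.tier == "voxel":
        profiles = simulate_voxel_profiles(cohort, config)
    else:
        profiles = phantom.simulate_profile_cohort(
            cohort, config.effects, seed=profile_seed, n_depths=config.n_depths
        )

    lateral = stats.lateralization_test(profiles, alpha=config.alpha)
    n_sig = int(lateral["significant"].sum())
    log.info("lateralization: %d/%d tests significant; %s",
             n_sig, len(lateral),
             "keeping hemispheres separate" if n_sig else
             "averaging hemispheres downstream")
    avg = average_hemispheres_frame(profiles)
    metrics = metrics_frame(avg, subjects)
    stage1 = stats.case_control_tests(metrics, alpha=config.alpha)

    bundle = dict(
        subjects=subjects,
        profiles=profiles,
        lateralization=lateral,
        metrics=metrics,
        stage1=stage1,
        master_seed=master_seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        subjects.to_csv(out / "subjects.csv", index=False)
        profiles.to_csv(out / "profiles.csv", index=False)
        metrics.to_csv(out / "metrics.csv", index=False)
        lateral.to_csv(out / "lateralization.csv", index=False)
        stage1.to_csv(out / "stats_case_control.csv", index=False)
        _write_json(stage1, None, lateral, out / "results.json")
    return bundle


def run_within_patients(config: RunConfig, bundle: dict, out_dir=None) -> pd.DataFrame:
    """Stage 2: within-patient analyses for stage-1-significant cells."""
    stage2 = stats.within_patient_analyses(
        bundle["metrics"],
        bundle["stage1"],
        alpha=config.alpha,
        n_boot=config.bootstrap_reps,
        seed=bundle.get("master_seed", config.master_seed),
    )
    if stage2.empty:
        log.info("no (roi, metric) cell passed the case-control gate; "
                 "within-patient table is empty")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stage2.to_csv(out / "stats_within_patients.csv", index=False)
        _write_json(bundle["stage1"], stage2, bundle["lateralization"],
                    out / "results.json")
    return stage2
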