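"""End-to-end orchestration on synthetic data.

``run_pipeline`` exercises every stage in order — simulate -> extract ->
reduce -> crosssec -> stage -> trajectories -> predict — writing each
stage's artifacts plus a manifest (config hash, seeds, row counts,
exclusion counts) to the output directory.  The run is deterministic for a
fixed config: identical config + seed give identical manifests.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import CohortSpec, PhantomSpec, generate_cohort, generate_phantom
from .texture import extract_all
from .features import clean_features, fit_pca, project
from .crosssec import GroupModel, pairwise_contrasts, adjust_pvalues
from .progression import ProgressionModel
from .trajectories import AbnormalityScale, TrajectoryModel, DualTimescaleModel
from .cogpredict import build_prediction_frame, ModelComparison
from .io import PipelineConfig

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

#: outcome -> direction of abnormality for the synthetic cohort
DIRECTIONS = {"adas13": "increasing", "cdrsb": "increasing",
              "mmse": "decreasing", "centiloid": "increasing",
              "csf_ab42": "decreasing", "hippo_volume": "decreasing"}


def _simulate_features(truth, n_visits_by_subject, cfg: PipelineConfig):
    """Per-subject-visit texture features from phantoms tied to disease stage.

    Later disease stages get more, blurrier hyperintense blobs, so the
    synthetic texture genuinely carries disease signal downstream stages can
    detect.
    """
    rows = []
    for _, subj in truth.subjects.iterrows():
        sid = subj["subject_id"]
        for t in n_visits_by_subject.get(sid, []):
            stage = subj["shift_total"] + t
            severity = float(np.clip((stage + 5.0) / 25.0, 0.0, 1.0))
            feats = {}
            subj_rng = np.random.default_rng(
                zlib.crc32(f"vol|{cfg.seed}|{sid}".encode()) % (2**31))
            subj_vol = float(subj_rng.normal(0.0, 0.02))
            for hemi_idx, hemi in enumerate(("left", "right")):
                spec = PhantomSpec(
                    shape=cfg.phantom_shape,
                    cluster_count=4 + int(round(14 * severity)),
                    blob_sigma=0.6 + 1.0 * severity,
                    noise_sd=4.0,
                    radius_scale=float(np.clip(
                        0.97 - 0.10 * severity + subj_vol, 0.75, 1.0)),
                    hemisphere=hemi,
                    seed=zlib.crc32(f"{cfg.seed}|{sid}|{t:.3f}|{hemi_idx}"
                                    .encode()) % (2**31),
                )
                feats[hemi] = generate_phantom(spec)
            vec = extract_all(feats["left"], feats["right"],
                              g_levels=cfg.bins, trim_sigma=cfg.trim_sigma)
            row = dict(subject_id=sid, visit_years=float(t))
            row.update(vec.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": config.to_dict(),
                "config_hash": config.config_hash(), "stages": {}}

    def record(stage, **info):
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    try:
        # -- simulate --------------------------------------------------
        spec = CohortSpec(n_per_group=config.n_per_group,
                          visit_schedule=config.visit_schedule,
                          seed=config.seed)
        cohort, truth = generate_cohort(spec)
        cohort.to_csv(out / "cohort.csv", index=False)
        truth.subjects.to_csv(out / "ground_truth.csv", index=False)
        record("simulate", n_rows=len(cohort),
               n_subjects=cohort["subject_id"].nunique())

        # -- extract ---------------------------------------------------
        visits = cohort.groupby("subject_id")["visit_years"].unique().to_dict()
        features = _simulate_features(truth, visits, config)
        features.to_csv(out / "features.csv", index=False)
        record("extract", n_rows=len(features),
               n_features=features.shape[1] - 2)

        # -- reduce ----------------------------------------------------
        feat_cols = [c for c in features.columns
                     if c not in ("subject_id", "visit_years",
                                  "single_hemisphere", "volume")]
        cleaned, report = clean_features(features[feat_cols],
                                         iqr_mult=config.feature_iqr_mult)
        meta = features[["subject_id", "visit_years"]]
        cleaned = pd.concat([meta, cleaned], axis=1)
        subj_groups = truth.subjects.set_index("subject_id")["group_bl"]
        is_cu = cleaned["subject_id"].map(subj_groups).str.startswith("CU")
        training = is_cu & (cleaned["visit_years"] == 0)
        model = fit_pca(cleaned, training,
                        feature_cols=[c for c in cleaned.columns
                                      if c not in ("subject_id", "visit_years")],
                        retain_threshold=config.pca_retention)
        model.to_json(out / "pca.json")
        scores = project(model, cleaned)
        scores = pd.concat([meta, scores,
                            features[["volume"]].rename(columns={"volume": "tx_volume"})],
                           axis=1)
        scores.to_csv(out / "scores.csv", index=False)
        record("reduce", cells_masked=report.n_cells_masked,
               features_dropped=len(report.dropped_features),
               n_components=len(model.retained),
               variance_shares=[round(float(model.variance_explained[i]), 4)
                                for i in model.retained])

        # -- crosssec --------------------------------------------------
        base = scores[scores["visit_years"] == 0].merge(
            truth.subjects, on="subject_id")
        comp_cols = model.component_names() + ["tx_volume"]
        cs_results = {}
        family = []      # one Holm family across all variables x contrasts
        for col in comp_cols:
            gm = GroupModel(base, col).fit()
            pw = pairwise_contrasts(base, col)
            cs_results[col] = dict(
                f_group=gm.term("group").f_stat,
                p_group=gm.term("group").p_value,
                cohens_f=gm.cohens_f_group,
                contrasts=[{k: v for k, v in c.items()} for c in pw])
            for c in cs_results[col]["contrasts"]:
                family.append((col, c))
        padj = adjust_pvalues([c["p_value"] for _, c in family])
        for (col, c), pa in zip(family, padj):
            c["p_adjusted"] = float(pa)
        with open(out / "crosssec.json", "w") as fh:
            json.dump(cs_results, fh, indent=1, default=float)
        record("crosssec", n_variables=len(comp_cols), n_tests=len(family))

        # -- stage -----------------------------------------------------
        prog = ProgressionModel(cohort, list(config.staging_outcomes),
                                dof=config.progression_dof).fit()
        ab = cohort[cohort["outcome"] == "csf_ab42"]
        staged_ab = prog.predict_disease_time(ab)
        healthy_ab = ab.loc[ab["group_bl"] == "CU-Ab-", "value"]
        try:
            prog.anchor_time_zero(staged_ab, healthy_ab)
        except ValueError as exc:
            log.warning("Time-0 anchoring skipped: %s", exc)
        staged = prog.predict_disease_time(cohort)
        staged.to_csv(out / "staged.csv", index=False)
        record("stage", n_staged=len(staged),
               shift_sd=round(prog.shift_sd, 3),
               timeline_years=round(float(staged["disease_time"].max()
                                          - staged["disease_time"].min()), 2))

        # -- trajectories ---------------------------------------------
        staged_scores = scores.merge(
            staged[["subject_id", "visit_years", "disease_time", "group_bl",
                    "age_bl"]].drop_duplicates(["subject_id", "visit_years"]),
            on=["subject_id", "visit_years"], how="left")
        staged_scores["age"] = (staged_scores["age_bl"]
                                + staged_scores["visit_years"])
        grid = np.linspace(staged_scores["disease_time"].quantile(0.025),
                           staged_scores["disease_time"].quantile(0.975), 60)
        curves, traj_info = {"disease_time": grid}, {}
        healthy = staged_scores["group_bl"] == "CU-Ab-"
        for col in comp_cols:
            try:
                tm = TrajectoryModel(staged_scores, col,
                                     dof_range=config.trajectory_dof_range,
                                     trim=config.quantile_trim).fit()
                direction = ("decreasing" if col == "tx_volume" else "increasing")
                scale = AbnormalityScale.from_healthy(
                    staged_scores.loc[healthy, col].dropna(), col, direction)
                curves[f"{col}_mean"] = tm.predict(grid)
                curves[f"{col}_abnormality"] = tm.abnormality_curve(scale, grid)
                curves[f"{col}_sensitivity"] = tm.sensitivity_curve(grid)
                dual = DualTimescaleModel(staged_scores, col,
                                          dof_range=config.dual_dof_range,
                                          trim=config.quantile_trim).fit()
                traj_info[col] = dict(dof=tm.dof, dual_form=dual.form,
                                      dual_bic=round(dual.bic, 1))
            except ValueError as exc:
                log.warning("trajectory for %s skipped: %s", col, exc)
        pd.DataFrame(curves).to_csv(out / "trajectory_curves.csv", index=False)
        record("trajectories", **{k: v for k, v in traj_info.items()})

        # -- predict ---------------------------------------------------
        cog = cohort[cohort["outcome"].isin(["adas13"])]
        wide = cog.pivot_table(index=["subject_id", "visit_years", "group_bl",
                                      "age_bl", "sex", "education", "icv"],
                               columns="outcome", values="value").reset_index()
        hv = cohort[cohort["outcome"] == "hippo_volume"][
            ["subject_id", "visit_years", "value"]].rename(columns={"value": "hv"})
        wide = wide.merge(hv, on=["subject_id", "visit_years"], how="left")
        wide = wide.merge(scores[["subject_id", "visit_years"]
                                 + model.component_names()],
                          on=["subject_id", "visit_years"], how="left")
        tx_cols = model.component_names()
        frame = build_prediction_frame(wide, "adas13",
                                       horizon_months=config.horizon_months,
                                       window_months=config.window_months,
                                       texture_cols=tx_cols)
        comp = ModelComparison(frame, texture_cols=tx_cols).fit(
            n_boot=config.n_boot, seed=config.seed + 1)
        pred = dict(score="adas13", n=comp.n_subjects,
                    mean_adj_r2={m: round(float(v), 4)
                                 for m, v in comp.model_stats["mean"].items()},
                    comparisons=comp.comparisons.drop(columns=[]).to_dict("records"))
        with open(out / "prediction.json", "w") as fh:
            json.dump(pred, fh, indent=1, default=float)
        record("predict", n_subjects=comp.n_subjects, n_boot=comp.n_boot)
    except Exception as exc:
        stage = len(manifest["stages"])
        manifest["failed_at"] = list(manifest["stages"])[-1] if stage else "simulate"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise RuntimeError(
            f"pipeline failed after stage {manifest.get('failed_at')}: {exc}"
        ) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
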