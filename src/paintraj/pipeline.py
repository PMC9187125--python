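"""End-to-end pipeline: simulate -> cohort -> features -> cluster -> ZICMP -> profiles -> outcomes.

A single YAML/dict config drives the run; a manifest records the config
hash, seeds, and a digest of every stage output so a rerun with the same
config and seed is byte-identical and independently verifiable. The global
seed is fanned out to stages by fixed offsets so stages are independently
rerunnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from paintraj import cohort as cohort_mod
from paintraj import synthetic
from paintraj.clusters import select_k, pca_reduce
from paintraj.features import DEFAULT_WINSOR_PCT, feature_matrix, standardize
from paintraj.outcomes import (bivariate_table, bivariate_to_frame, fit_outcome_model,
                               hosmer_lemeshow, roc_resample, type3_cluster_test)
from paintraj.profiles import cluster_auc_profiles, empirical_mean_trajectory, profiles_to_frame
from paintraj.zicmp import ZicmpSpec, fit_zicmp, predict_decomposition

logger = logging.getLogger(__name__)

STAGES = ("simulate", "cohort", "features", "cluster", "zicmp", "profiles", "outcomes")
# fixed per-stage seed offsets so stages are independently rerunnable
STAGE_SEED_OFFSET = {name: 1000 * i for i, name in enumerate(STAGES)}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)

    def add(self, name: str, outputs: dict):
        self.stages.append({
            "stage": name,
            "seed": None,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {k: _digest(v) for k, v in outputs.items()},
        })

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed, "stages": self.stages}


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _validate(config: dict) -> dict:
    defaults = {
        "preset": "paper", "n_patients": None, "window_h": 96.0, "min_scores": 4,
        "max_los_days": 4.0, "kmin": 2, "kmax": 7, "restarts": 50,
        "zicmp_starts": "warm", "interval_h": 8.0, "outcomes": ["pain_30d", "pain_1y"],
    }
    cfg = {**defaults, **(config or {})}
    if cfg["kmax"] < cfg["kmin"]:
        raise ValueError(f"kmax ({cfg['kmax']}) < kmin ({cfg['kmin']})")
    if cfg["preset"] not in ("paper", "well_separated"):
        raise ValueError(f"unknown preset {cfg['preset']!r}")
    return cfg


def run_pipeline(config=None, out_dir="pipeline_out", seed: int = 17) -> RunManifest:
    """Run all stages under ``out_dir``; returns the manifest (also written as JSON).

    ``config`` may be a dict or a YAML file path. Any stage failure aborts
    with the manifest of completed stages attached to the raised error.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        seed=seed)

    def _finish_stage(name, outputs):
        manifest.add(name, outputs)
        manifest.stages[-1]["seed"] = seed + STAGE_SEED_OFFSET[name]
        (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))

    try:
        # simulate
        maker = synthetic.default_scenario if cfg["preset"] == "paper" else synthetic.well_separated_scenario
        kwargs = {} if cfg["n_patients"] is None else {"n_patients": cfg["n_patients"]}
        scen = maker(seed=seed + STAGE_SEED_OFFSET["simulate"], **kwargs)
        series, baseline, labels = synthetic.generate_cohort(scen)
        pain_csv, base_csv = out / "pain.csv", out / "baseline.csv"
        cohort_mod.write_cohort(series, baseline, pain_csv, base_csv)
        labels_csv = out / "true_labels.csv"
        pd.Series(labels, name="true_label").rename_axis("patient_id").to_csv(labels_csv)
        _finish_stage("simulate", {"pain": pain_csv, "baseline": base_csv, "labels": labels_csv})

        # cohort
        series, baseline, parse = cohort_mod.read_cohort(pain_csv, base_csv)
        series, baseline, report = cohort_mod.apply_inclusion_filters(
            series, baseline, cfg["window_h"], cfg["min_scores"], cfg["max_los_days"])
        filt_pain, filt_base = out / "pain_filtered.csv", out / "baseline_filtered.csv"
        cohort_mod.write_cohort(series, baseline, filt_pain, filt_base)
        report_json = out / "filter_report.json"
        report_json.write_text(json.dumps(report.to_dict(), indent=2))
        _finish_stage("cohort", {"pain": filt_pain, "baseline": filt_base, "report": report_json})

        # features
        feats = feature_matrix(series)
        feats_csv = out / "features.csv"
        feats.to_csv(feats_csv)
        _finish_stage("features", {"features": feats_csv})

        # cluster
        z, _, _ = standardize(feats[list(feats.columns[:24])], winsor_pct=DEFAULT_WINSOR_PCT)
        pca = pca_reduce(z)
        k_star, ccc_table, assignment = select_k(
            pca.scores, range(cfg["kmin"], cfg["kmax"] + 1),
            seed=seed + STAGE_SEED_OFFSET["cluster"], restarts=cfg["restarts"],
            patient_ids=list(z.index))
        assign_csv, ccc_csv, pca_json = out / "assignments.csv", out / "ccc.csv", out / "pca.json"
        pd.Series(assignment.labels, name="cluster").rename_axis("patient_id").to_csv(assign_csv)
        ccc_table.to_csv(ccc_csv, index=False)
        pca_json.write_text(json.dumps(pca.summary(), indent=2))
        _finish_stage("cluster", {"assignments": assign_csv, "ccc": ccc_csv, "pca": pca_json})

        # zicmp per cluster
        fits, curve_frames, diag = {}, [], {}
        by_id = {s.patient_id: s for s in series}
        for lab in sorted(set(assignment.labels.values())):
            members = [by_id[p] for p in sorted(assignment.labels)
                       if assignment.labels[p] == lab]
            fit = fit_zicmp(members, ZicmpSpec(window_h=cfg["window_h"]),
                            starts=cfg["zicmp_starts"],
                            seed=seed + STAGE_SEED_OFFSET["zicmp"])
            fits[lab] = fit
            dec = predict_decomposition(fit, force=True)
            dec.insert(0, "cluster", lab)
            curve_frames.append(dec)
            diag[str(lab)] = {"loglik": fit.loglik, "converged": fit.converged,
                              "nu": fit.nu, "sigma_b": fit.sigma_b,
                              "n_patients": fit.n_patients, "n_obs": fit.n_obs}
        curves_csv, diag_json = out / "zicmp_curves.csv", out / "zicmp_diagnostics.json"
        pd.concat(curve_frames, ignore_index=True).to_csv(curves_csv, index=False)
        coef_csv = out / "zicmp_coefficients.csv"
        pd.concat([f.coefficient_table().assign(cluster=lab) for lab, f in fits.items()],
                  ignore_index=True).to_csv(coef_csv, index=False)
        diag_json.write_text(json.dumps(diag, indent=2))
        _finish_stage("zicmp", {"curves": curves_csv, "coefficients": coef_csv,
                                "diagnostics": diag_json})

        # profiles
        profs = cluster_auc_profiles(fits, interval_h=cfg["interval_h"], force=True)
        profs6 = cluster_auc_profiles(fits, interval_h=6.0, force=True)
        prof_csv, prof6_csv = out / "auc_profiles_8h.csv", out / "auc_profiles_6h.csv"
        profiles_to_frame(profs).to_csv(prof_csv, index=False)
        profiles_to_frame(profs6).to_csv(prof6_csv, index=False)
        emp_csv = out / "empirical_trajectories.csv"
        empirical_mean_trajectory(series, assignment).to_csv(emp_csv, index=False)
        _finish_stage("profiles", {"auc_8h": prof_csv, "auc_6h": prof6_csv,
                                   "empirical": emp_csv})

        # outcomes
        biv = bivariate_to_frame(bivariate_table(baseline, assignment, series=series))
        biv_csv = out / "bivariate_table.csv"
        biv.to_csv(biv_csv, index=False)
        outcome_outputs = {"bivariate": biv_csv}
        for oc in cfg["outcomes"]:
            fit = fit_outcome_model(baseline, assignment, outcome=oc)
            lr, dfree, p3 = type3_cluster_test(fit)
            hl_stat, hl_df, hl_p = hosmer_lemeshow(fit)
            auc, _, auc_ci = roc_resample(fit, B=200,
                                          seed=seed + STAGE_SEED_OFFSET["outcomes"])
            oc_csv = out / f"outcome_{oc}.csv"
            fit.odds_ratios.to_csv(oc_csv, index=False)
            oc_json = out / f"outcome_{oc}_diagnostics.json"
            oc_json.write_text(json.dumps({
                "retained_terms": fit.retained_terms, "n_used": fit.n_used,
                "type3_lr": lr, "type3_df": dfree, "type3_p": p3,
                "hosmer_lemeshow": {"stat": hl_stat, "df": hl_df, "p": hl_p},
                "roc_auc": auc, "roc_auc_ci": auc_ci,
                "selection_trace": fit.selection_trace,
            }, indent=2))
            outcome_outputs[oc] = oc_csv
            outcome_outputs[f"{oc}_diag"] = oc_json
        _finish_stage("outcomes", outcome_outputs)
    except Exception as err:
        err.manifest = manifest
        raise
    return manifest
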