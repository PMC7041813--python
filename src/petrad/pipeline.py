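"""End-to-end workflow: simulate -> extract -> filter -> model -> report.

``run_pipeline`` executes the full feature-selection and modelling chain
on synthetic cohorts and writes every stage's inputs/outputs to an
artifact directory:

1. a repeatability cohort of phantoms with paired repeat scans; features
   extracted from both arms over all four (mask, binning) configurations;
2. the coefficient-of-repeatability filter at the configured percentage
   cut-off;
3. the Spearman independence filter against MTV and SUVmax on arm A,
   with the elbow-clustering diagnostic;
4. the intersection of the two pass sets (the selected robust,
   independent features);
5. a modelling cohort with planted prognostic truth; elastic-net models
   for the three families (rad / clin / all) per endpoint under repeated
   stratified 80/20 train/validation; frequency rankings, pairwise
   Mann-Whitney comparisons and external validation on a held-out cohort.

All randomness flows from the single master seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .config import PipelineConfig, save_config
from .features.extract import extract_all
from .features.registry import ALIASES, enumerate_feature_space
from .model import (
    ENDPOINTS,
    ModelRunSet,
    build_design,
    compare_models,
    external_validate,
    frequency_ranking,
    repeated_train_validate,
)
from .phantom import PhantomSpec, RepeatPairSpec, generate_lesion_image, generate_repeat_pair
from .selection import (
    elbow_cluster_validation,
    independence_filter,
    repeatability_table,
    select_features,
)

__all__ = ["run_repeatability_study", "run_pipeline"]


def run_repeatability_study(
    config: PipelineConfig,
    phantom: PhantomSpec | None = None,
    pair: RepeatPairSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired feature tables (arm A, arm B) over a repeat-scan cohort."""
    phantom = phantom or PhantomSpec()
    pair = pair or RepeatPairSpec()
    extraction = config.extraction()
    rows_a, rows_b = [], []
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    for i in range(config.n_repeat_patients):
        vol = float(np.clip(62.0 * np.exp(rng.normal(0, 0.65)), 10.0,
                            0.45 * np.prod(phantom.grid_shape) * np.prod(phantom.spacing) / 1000.0))
        uptake = float(np.clip(9.0 * np.exp(rng.normal(0, 0.3)), 4.5, 40.0))
        pspec = dataclasses.replace(
            phantom, lesion_volume_cc=vol, base_uptake=uptake,
            texture_amplitude=0.15 * uptake, seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, voi = generate_lesion_image(pspec)
        pspec_pair = dataclasses.replace(pair, seed=int(rng.integers(0, 2**31 - 1)))
        scan_a, scan_b = generate_repeat_pair(image, voi, pspec_pair)
        rows_a.append(extract_all(scan_a, voi, extraction).features)
        rows_b.append(extract_all(scan_b, voi, extraction).features)
    index = pd.Index([f"repeat_{i}" for i in range(config.n_repeat_patients)], name="patient")
    return pd.DataFrame(rows_a, index=index), pd.DataFrame(rows_b, index=index)


def _usable(df: pd.DataFrame, columns: list[str]) -> list[str]:
    return [c for c in columns if c in df.columns and df[c].notna().all()]


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 phantom: PhantomSpec | None = None) -> dict:
    """Run the full chain and write artifacts under ``out_dir``.

    Returns the report dictionary (also written as report.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    phantom = phantom or PhantomSpec()
    extraction = config.extraction()
    registry = [k.qualified for k in enumerate_feature_space(extraction)]
    save_config(config, out / "config.yaml")
    log: list[str] = [f"master seed: {config.seed}", f"registry size: {len(registry)}"]

    # 1. repeatability cohort
    arm_a, arm_b = run_repeatability_study(config, phantom=phantom)
    arm_a.to_csv(out / "features_arm_a.csv")
    arm_b.to_csv(out / "features_arm_b.csv")

    # 2-3. repeatability and independence filters
    rep = repeatability_table(arm_a, arm_b, threshold=config.cr_threshold_pct,
                              convention=config.cr_convention)
    rep.to_csv(out / "repeatability.csv")
    log.append(f"repeatable features: {int(rep['repeatable'].sum())}/{len(rep)}")
    indep = independence_filter(arm_a, cutoff=config.rho_cutoff, config=extraction)
    indep.to_csv(out / "independence.csv")
    log.append(f"independent features: {int(indep['independent'].sum())}/{len(indep)}")

    repeatable_cols = rep.index[rep["repeatable"]].tolist()
    if len(repeatable_cols) >= 3:
        sub = arm_a[repeatable_cols]
        keep = [c for c in repeatable_cols if sub[c].std() > 0]
        corr = sub[keep].corr(method="spearman").abs()
        k, membership = elbow_cluster_validation(corr.to_numpy())
        pd.DataFrame({"feature": keep, "cluster": membership}).to_csv(
            out / "elbow_clusters.csv", index=False
        )
        log.append(f"elbow-suggested clusters among repeatable features: {k}")

    # 4. selection
    audit = select_features(rep, indep)
    audit.to_csv(out / "selection.csv")
    selected = audit.index[audit["selected"]].tolist()
    log.append(f"selected features: {len(selected)}")

    # 5. modelling cohorts
    dev_spec = CohortSpec(n_patients=config.n_patients, seed=config.seed * 1000 + 2)
    ext_spec = dataclasses.replace(
        dev_spec, n_patients=config.n_external, seed=config.seed * 1000 + 3
    )
    dev = generate_cohort(dev_spec, phantom=phantom, config=extraction)
    ext = generate_cohort(ext_spec, phantom=phantom, config=extraction)
    dev.clinical.to_csv(out / "cohort_clinical.csv")
    dev.features.to_csv(out / "cohort_features.csv")
    truth = {
        "planted_coefficients": dev_spec.planted_coefficients,
        "intercepts": dev_spec.intercepts,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    dev.linear_predictors.to_csv(out / "cohort_linear_predictors.csv")

    rad_cols = _usable(dev.features, selected)
    report: dict = {
        "registry_size": len(registry),
        "n_repeatable": int(rep["repeatable"].sum()),
        "n_independent": int(indep["independent"].sum()),
        "n_selected": len(selected),
        "n_selected_usable": len(rad_cols),
        "endpoints": {},
    }

    rankings = []
    for endpoint in ENDPOINTS:
        y = dev.clinical[endpoint].to_numpy(int)
        runsets: dict[str, ModelRunSet] = {}
        ep_report: dict = {"prevalence": float(y.mean()), "families": {}}
        for family in ("rad", "clin", "all"):
            try:
                x = build_design(
                    dev.features[rad_cols] if family != "clin" else None,
                    dev.clinical, family=family,
                )
            except ValueError as exc:
                ep_report["families"][family] = {"error": str(exc)}
                continue
            runs = repeated_train_validate(
                x, y, n_rep=config.n_repetitions, train_fraction=config.train_fraction,
                seed=config.seed * 100
                + 10 * ENDPOINTS.index(endpoint)
                + ("rad", "clin", "all").index(family),
                folds=min(config.cv_folds, int(0.8 * len(y)) - 1),
                l1_ratio=config.l1_ratio, n_lambda=config.n_lambda,
                family=family, endpoint=endpoint,
            )
            runsets[family] = runs
            fam_report = runs.summary()
            # external validation of the best run
            best = runs.best_run if config.best_model_rule == "max_auc" else runs.median_run
            try:
                x_ext = build_design(
                    ext.features[rad_cols] if family != "clin" else None,
                    ext.clinical, family=family,
                )
                fam_report["external_auc"] = external_validate(
                    best.model, x_ext, ext.clinical[endpoint].to_numpy(int)
                )
            except ValueError as exc:
                fam_report["external_auc_error"] = str(exc)
            ep_report["families"][family] = fam_report
            ranking = frequency_ranking(runs)
            ranking.insert(0, "endpoint", endpoint)
            ranking.insert(1, "family", family)
            rankings.append(ranking)
        comparisons = {}
        fams = list(runsets)
        for i, fa in enumerate(fams):
            for fb in fams[i + 1:]:
                p, sig = compare_models(runsets[fa], runsets[fb])
                comparisons[f"{fa}_vs_{fb}"] = {"p_value": p, "significant": sig}
        ep_report["comparisons"] = comparisons
        report["endpoints"][endpoint] = ep_report

    if rankings:
        pd.concat(rankings, ignore_index=True).to_csv(out / "feature_ranking.csv", index=False)
    report["runtime_s"] = round(time.time() - t0, 1)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.append(f"runtime: {report['runtime_s']} s")
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return report
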