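"""Synthetic patient cohorts with known prognostic ground truth.

Each patient gets a phantom lesion (volume and uptake drawn from
distributions matching a locally advanced NSCLC population: median
metabolic volume ~62 cc, median SUVmax ~11-15), clinical covariates
(age, gender, histology, T/N/overall stage) with marginals loosely
matching such cohorts, GTV set to the VOI volume, and binary survival
endpoints drawn from a logistic model with *planted* coefficients on
standardized features.  The true linear predictor is returned so oracle
discrimination (the AUC an ideal model could reach) is computable.

Seeding uses one master seed; patient ``i`` derives its generator from
``SeedSequence(master, spawn_key=(i,))`` so cohorts are extensible without
reshuffling existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .features.extract import extract_all
from .features.registry import ExtractionConfig, enumerate_feature_space
from .images import ROIMask, SUVImage
from .model import ENDPOINTS
from .phantom import PhantomSpec, generate_lesion_image
from .segmentation import mask_volume_cc

__all__ = ["CohortSpec", "CohortBundle", "generate_cohort", "DEFAULT_PLANTED", "DEFAULT_INTERCEPTS"]

HISTOLOGIES = ("adeno", "squamous", "large_cell", "nos_other")
HISTOLOGY_P = (0.35, 0.36, 0.05, 0.24)
STAGES = ("IIB", "IIIA", "IIIB", "IIIC")
STAGE_P = (0.08, 0.44, 0.38, 0.10)
T_P = (0.05, 0.33, 0.28, 0.34)  # T1..T4
N_P = (0.18, 0.09, 0.57, 0.16)  # N0..N3

#: default planted prognostic truth: age plus three independent, repeatable
#: radiomics features, standardized scale (other endpoints left pure-noise)
DEFAULT_PLANTED: dict[str, dict[str, float]] = {
    "os2": {
        "Age": -0.9,
        "shape_Sphericity__MTV25": 1.1,
        "glcm_ClusterTendency__MTV25__bincount64": -1.0,
        "glcm_JointEntropy__MTV25__bincount64": 0.8,
    },
    "pfs2": {},
    "pfs1": {},
    "lrs1": {},
    "dms1": {},
}
#: baseline log-odds giving prevalences near those of such cohorts
DEFAULT_INTERCEPTS: dict[str, float] = {
    "os2": -0.4,   # ~40% two-year overall survival
    "pfs2": -0.9,  # ~29%
    "pfs1": 0.0,   # ~50%
    "lrs1": 0.3,   # ~58%
    "dms1": 0.15,  # ~54%
}


@dataclass
class CohortSpec:
    n_patients: int = 252
    lesion_volume_median_cc: float = 62.0
    lesion_volume_log_sd: float = 0.65
    uptake_median_suv: float = 9.0
    uptake_log_sd: float = 0.3
    age_mean: float = 65.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (36.0, 87.0)
    p_male: float = 0.6
    planted_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {e: dict(DEFAULT_PLANTED[e]) for e in ENDPOINTS}
    )
    intercepts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    seed: int = 0

    def validate(self, config: ExtractionConfig) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        registry = {k.qualified for k in enumerate_feature_space(config)}
        clinical = {"Age", "Gender", "GTV"}
        for endpoint, coefs in self.planted_coefficients.items():
            if endpoint not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {endpoint!r}")
            unknown = [f for f in coefs if f not in registry and f not in clinical]
            if unknown:
                raise ValueError(f"planted features not in the feature space: {unknown}")


@dataclass
class CohortBundle:
    clinical: pd.DataFrame          # covariates + binary endpoints, indexed by patient
    features: pd.DataFrame          # patients x expanded feature registry
    linear_predictors: pd.DataFrame  # true per-endpoint linear predictor (oracle)
    images: list[SUVImage] | None = None
    vois: list[ROIMask] | None = None
    extraction_errors: dict[str, dict[str, str]] = field(default_factory=dict)


def _patient_rng(master_seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(i,)))


def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v


def generate_cohort(
    spec: CohortSpec,
    phantom: PhantomSpec | None = None,
    config: ExtractionConfig | None = None,
    keep_images: bool = False,
) -> CohortBundle:
    """Generate a cohort of phantoms with features, covariates and labels."""
    phantom = phantom or PhantomSpec()
    config = config or ExtractionConfig()
    spec.validate(config)
    master = spec.seed

    feat_rows, clin_rows, images, vois, errors = [], [], [], [], {}
    for i in range(spec.n_patients):
        rng = _patient_rng(master, i)
        vol = float(np.clip(
            spec.lesion_volume_median_cc * np.exp(rng.normal(0, spec.lesion_volume_log_sd)),
            10.0, 0.45 * np.prod(phantom.grid_shape) * np.prod(phantom.spacing) / 1000.0,
        ))
        uptake = float(np.clip(
            spec.uptake_median_suv * np.exp(rng.normal(0, spec.uptake_log_sd)), 4.5, 40.0,
        ))
        pspec = replace(
            phantom,
            lesion_volume_cc=vol,
            base_uptake=uptake,
            texture_amplitude=0.15 * uptake,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, voi = generate_lesion_image(pspec)
        result = extract_all(image, voi, config)
        feat_rows.append(result.features)
        if result.errors:
            errors[f"patient_{i}"] = result.errors
        clin_rows.append(
            {
                "Age": _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range),
                "Gender": "male" if rng.random() < spec.p_male else "female",
                "Histology": HISTOLOGIES[rng.choice(len(HISTOLOGIES), p=HISTOLOGY_P)],
                "T_status": int(rng.choice([1, 2, 3, 4], p=T_P)),
                "N_status": int(rng.choice([0, 1, 2, 3], p=N_P)),
                "Stage": STAGES[rng.choice(len(STAGES), p=STAGE_P)],
                "GTV": mask_volume_cc(voi),
            }
        )
        if keep_images:
            images.append(image)
            vois.append(voi)

    index = pd.Index([f"patient_{i}" for i in range(spec.n_patients)], name="patient")
    features = pd.DataFrame(feat_rows, index=index)
    clinical = pd.DataFrame(clin_rows, index=index)

    # endpoints from the planted logistic model on standardized predictors
    label_rng = np.random.default_rng(np.random.SeedSequence(master, spawn_key=(2**20,)))
    lp = pd.DataFrame(0.0, index=index, columns=list(ENDPOINTS))
    for endpoint in ENDPOINTS:
        eta = np.full(len(index), spec.intercepts.get(endpoint, 0.0))
        for name, beta in spec.planted_coefficients.get(endpoint, {}).items():
            if name == "Gender":
                raw = (clinical["Gender"] == "male").astype(float).to_numpy()
            elif name in clinical.columns:
                raw = clinical[name].to_numpy(float)
            else:
                raw = features[name].to_numpy(float)
            sd = raw.std()
            z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
            eta = eta + beta * z
        lp[endpoint] = eta
        prob = expit(eta)
        y = (label_rng.random(len(index)) < prob).astype(int)
        prevalence = y.mean()
        if prevalence in (0.0, 1.0):
            raise ValueError(
                f"endpoint {endpoint!r} realized prevalence {prevalence:.0%}; "
                "adjust the intercept towards 0"
            )
        clinical[endpoint] = y

    return CohortBundle(
        clinical=clinical,
        features=features,
        linear_predictors=lp,
        images=images if keep_images else None,
        vois=vois if keep_images else None,
        extraction_errors=errors,
    )
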