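"""Elastic-net prognostic models with repeated train/validation.

Per endpoint, three penalized logistic models are compared: radiomics only
(``rad``), clinical variables only (``clin``) and their union (``all``).
Each model is fitted on a stratified 80/20 train/validation split with the
penalty strength chosen by 20-fold cross-validated deviance on the
training part only (mixing parameter alpha = 0.5 by default), the split
repeated many times (100 by default).  Validation discrimination is the
rank-based AUC; model families are compared by a two-sided Mann-Whitney U
test on their AUC samples, and predictors are ranked by how often the
elastic net retains them with a nonzero coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "auc",
    "fit_elastic_net_cv",
    "FittedModel",
    "ModelRun",
    "ModelRunSet",
    "repeated_train_validate",
    "frequency_ranking",
    "compare_models",
    "build_design",
    "external_validate",
]

CLINICAL_COLUMNS = ["Age", "Gender", "Histology", "T_status", "N_status", "Stage", "GTV"]
ENDPOINTS = ("os2", "pfs2", "pfs1", "lrs1", "dms1")


def auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney statistic; ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class FittedModel:
    """Elastic-net logistic model at the CV-selected penalty."""

    coef: pd.Series          # slopes on the standardized design
    intercept: float
    c_selected: float        # inverse penalty strength (1/lambda scale)
    l1_ratio: float
    mean: pd.Series          # standardization statistics (training data)
    std: pd.Series

    @property
    def selected_features(self) -> list[str]:
        return [n for n, v in self.coef.items() if v != 0.0]

    def decision(self, x: pd.DataFrame) -> np.ndarray:
        z = (x[self.coef.index] - self.mean) / self.std
        return self.intercept + z.to_numpy(float) @ self.coef.to_numpy(float)


def _standardize_stats(x: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    mean = x.mean()
    std = x.std(ddof=0).replace(0.0, 1.0)  # constant columns pass through as 0
    return mean, std


def fit_elastic_net_cv(
    x: pd.DataFrame,
    y: np.ndarray,
    folds: int = 20,
    l1_ratio: float = 0.5,
    n_lambda: int = 50,
    random_state: int | None = None,
    standardize: bool = True,
) -> FittedModel:
    """Fit an elastic-net logistic model, penalty chosen by CV deviance.

    The regularization path is a log-spaced grid of ``n_lambda`` penalty
    strengths; the value minimizing mean cross-validated deviance
    (log-loss) over stratified folds is retained and the model refitted on
    the full data at that penalty.
    """
    y = np.asarray(y).astype(int)
    if x.isna().any().any() or not np.all(np.isfinite(x.to_numpy(float))):
        raise ValueError("design matrix contains missing or non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("endpoint has a single class; cannot fit a classifier")
    if len(y) <= folds:
        raise ValueError(f"need more samples ({len(y)}) than CV folds ({folds})")
    if standardize:
        mean, std = _standardize_stats(x)
    else:
        mean = pd.Series(0.0, index=x.columns)
        std = pd.Series(1.0, index=x.columns)
    z = (x - mean) / std
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    model = LogisticRegressionCV(
        Cs=n_lambda,
        cv=cv,
        solver="saga",
        l1_ratios=[l1_ratio],
        scoring="neg_log_loss",
        max_iter=2000,
        tol=1e-4,
        n_jobs=1,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        # scaled-down folds can under-populate the minority class; that is
        # intentional, and sklearn's attribute-transition notice is noise here
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        warnings.simplefilter("ignore", category=FutureWarning)
        warnings.simplefilter("ignore", category=UserWarning)
        model.fit(z.to_numpy(float), y)
    coef = pd.Series(model.coef_.ravel(), index=x.columns)
    coef[np.abs(coef) < 1e-10] = 0.0
    return FittedModel(
        coef=coef,
        intercept=float(model.intercept_[0]),
        c_selected=float(model.C_[0]),
        l1_ratio=l1_ratio,
        mean=mean,
        std=std,
    )


@dataclass
class ModelRun:
    train_idx: np.ndarray
    val_idx: np.ndarray
    model: FittedModel
    val_auc: float

    @property
    def selected_features(self) -> list[str]:
        return self.model.selected_features


@dataclass
class ModelRunSet:
    runs: list[ModelRun]
    family: str = "rad"
    endpoint: str = "os2"

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r.val_auc for r in self.runs])

    def summary(self) -> dict[str, float]:
        a = self.aucs
        return {
            "mean_auc": float(a.mean()),
            "sd_auc": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
            "median_auc": float(np.median(a)),
            "q25_auc": float(np.percentile(a, 25)),
            "q75_auc": float(np.percentile(a, 75)),
            "n_runs": len(a),
        }

    @property
    def best_run(self) -> ModelRun:
        return self.runs[int(np.argmax(self.aucs))]

    @property
    def median_run(self) -> ModelRun:
        order = np.argsort(self.aucs, kind="stable")
        return self.runs[int(order[len(order) // 2])]


def repeated_train_validate(
    x: pd.DataFrame,
    y: np.ndarray,
    n_rep: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    folds: int = 20,
    l1_ratio: float = 0.5,
    n_lambda: int = 50,
    family: str = "rad",
    endpoint: str = "os2",
    max_retries: int = 10,
) -> ModelRunSet:
    """Repeat the stratified split / CV fit / validation-AUC loop.

    Standardization statistics are refit on each repetition's training
    part only.  Degenerate splits (a single-class validation set, possible
    despite stratification at extreme prevalence) are retried with a fresh
    sub-seed up to ``max_retries`` times.  Fully reproducible given seed.
    """
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    runs: list[ModelRun] = []
    idx = np.arange(len(y))
    for _ in range(n_rep):
        for attempt in range(max_retries):
            sub = int(rng.integers(0, 2**31 - 1))
            tr, va = train_test_split(
                idx, train_size=train_fraction, stratify=y, random_state=sub
            )
            if len(np.unique(y[va])) == 2 and len(np.unique(y[tr])) == 2:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate split")
        model = fit_elastic_net_cv(
            x.iloc[tr], y[tr], folds=folds, l1_ratio=l1_ratio,
            n_lambda=n_lambda, random_state=sub % (2**31 - 1),
        )
        scores = model.decision(x.iloc[va])
        runs.append(ModelRun(train_idx=tr, val_idx=va, model=model,
                             val_auc=auc(scores, y[va])))
    return ModelRunSet(runs=runs, family=family, endpoint=endpoint)


def frequency_ranking(runs: ModelRunSet) -> pd.DataFrame:
    """How often each predictor is retained with a nonzero coefficient.

    Sorted by descending count, ties broken lexicographically.
    """
    counts: dict[str, int] = {}
    for run in runs.runs:
        for name in run.selected_features:
            counts[name] = counts.get(name, 0) + 1
    all_names = runs.runs[0].model.coef.index if runs.runs else []
    rows = [(name, counts.get(name, 0)) for name in all_names]
    df = pd.DataFrame(rows, columns=["feature", "count"])
    return df.sort_values(["count", "feature"], ascending=[False, True]).reset_index(drop=True)


def compare_models(runs_a: ModelRunSet, runs_b: ModelRunSet) -> tuple[float, bool]:
    """Two-sided Mann-Whitney U on the two AUC samples; flag at p < 0.05."""
    a, b = runs_a.aucs, runs_b.aucs
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty run sets")
    if len(a) != len(b):
        raise ValueError("run sets must have the same number of repetitions")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0, False  # all values tied
    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return p, bool(p < 0.05)


def build_design(
    features: pd.DataFrame | None,
    clinical: pd.DataFrame,
    family: str = "all",
) -> pd.DataFrame:
    """Assemble the (unstandardized) design matrix for one model family.

    Clinical columns: Age and GTV continuous, Gender binary, T/N stage
    ordinal-coded, Histology and Stage dummy-coded against their most
    frequent category.  Radiomics columns are the selected feature subset.
    Standardization happens downstream on training folds only.
    """
    if family not in {"rad", "clin", "all"}:
        raise ValueError(f"unknown model family {family!r}")
    parts: list[pd.DataFrame] = []
    if family in {"clin", "all"}:
        missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
        if missing:
            raise ValueError(f"clinical table is missing columns: {missing}")
        if clinical[CLINICAL_COLUMNS].isna().any().any():
            raise ValueError("clinical table contains missing values (no imputation)")
        clin = pd.DataFrame(index=clinical.index)
        clin["Age"] = clinical["Age"].astype(float)
        clin["GTV"] = clinical["GTV"].astype(float)
        clin["Gender"] = (
            clinical["Gender"].map({"male": 1, "female": 0}).fillna(clinical["Gender"])
        ).astype(float)
        clin["T_status"] = clinical["T_status"].astype(float)
        clin["N_status"] = clinical["N_status"].astype(float)
        for col in ("Histology", "Stage"):
            ref = clinical[col].mode().iloc[0]
            dummies = pd.get_dummies(clinical[col], prefix=col, dtype=float)
            dummies = dummies.drop(columns=f"{col}_{ref}")
            clin = clin.join(dummies)
        parts.append(clin)
    if family in {"rad", "all"}:
        if features is None or features.shape[1] == 0:
            raise ValueError(
                f"family {family!r} requires radiomics features but the selection is empty"
            )
        if features.isna().any().any():
            raise ValueError("feature table contains missing values (no imputation)")
        parts.append(features.astype(float))
    design = pd.concat(parts, axis=1)
    if design.isna().any().any():
        raise ValueError("design matrix contains missing values after assembly")
    return design


def external_validate(
    model: FittedModel, x_ext: pd.DataFrame, y_ext: np.ndarray
) -> float:
    """AUC of a fitted model on an external cohort.

    The external table must provide the development column dictionary;
    standardization uses the development statistics stored in the model.
    """
    missing = [c for c in model.coef.index if c not in x_ext.columns]
    if missing:
        raise ValueError(f"external table is missing columns: {missing}")
    return auc(model.decision(x_ext), np.asarray(y_ext).astype(int))
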