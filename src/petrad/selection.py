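"""Repeatability and independence filtering of radiomics features.

Repeatability uses the Bland-Altman coefficient of repeatability over
paired repeat scans of the same patients: CR = 1.96 * SD(paired
differences), reported as a percentage of the cohort mean and compared to
the 30% PERCIST-derived cut-off (a stricter 15% phantom-study cut-off is
supported).  Independence is Spearman rank correlation against the two
established prognostic metrics — the metabolic tumour volume of the
feature's own mask configuration and SUVmax — with |rho| >= 0.5 discarded
(boundary inclusive).  The cut-off choice can be sanity-checked with an
elbow analysis of average-linkage hierarchical clustering on 1 - |rho|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .features.registry import ALIASES, ExtractionConfig, enumerate_feature_space

__all__ = [
    "coefficient_of_repeatability",
    "percent_cr",
    "repeatability_table",
    "independence_filter",
    "elbow_cluster_validation",
    "select_features",
]

#: |cohort mean| below this floor makes percentCR non-assessable
MEAN_FLOOR = 1e-8


def coefficient_of_repeatability(
    a: np.ndarray, b: np.ndarray, convention: str = "bland_altman"
) -> float:
    """Coefficient of repeatability of paired measurements.

    ``bland_altman``: CR = 1.96 * SD(a - b) with sample (n-1) SD.
    ``within_subject``: CR = 2.77 * within-subject SD (= SD(a - b)/sqrt(2)),
    the equivalent formulation anchored on the one-way ANOVA estimate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have the same shape")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired values must be finite")
    sd_diff = float(np.std(a - b, ddof=1))
    if convention == "bland_altman":
        return 1.96 * sd_diff
    if convention == "within_subject":
        return 2.77 * sd_diff / np.sqrt(2.0)
    raise ValueError(f"unknown CR convention {convention!r}")


def percent_cr(
    cr: float, cohort_mean: float, threshold: float = 30.0
) -> tuple[float, bool]:
    """CR as a percentage of |cohort mean|, with pass flag (<= threshold).

    A cohort mean below the floor (e.g. a symmetric-about-zero feature)
    makes the percentage non-assessable: returns (nan, False).
    """
    if abs(cohort_mean) < MEAN_FLOOR:
        return float("nan"), False
    pct = 100.0 * cr / abs(cohort_mean)
    return pct, bool(pct <= threshold)


def repeatability_table(
    arm_a: pd.DataFrame,
    arm_b: pd.DataFrame,
    threshold: float = 30.0,
    convention: str = "bland_altman",
) -> pd.DataFrame:
    """Per-feature CR / percentCR / pass over a paired feature table.

    ``arm_a`` and ``arm_b`` are patients x features tables from the two
    repeat scans (same patients, same registry columns).  The percentage
    denominator is the grand mean of the two arms' per-patient averages.
    """
    if not arm_a.columns.equals(arm_b.columns) or not arm_a.index.equals(arm_b.index):
        raise ValueError("paired tables must share patients and feature registry")
    if len(arm_a) < 2:
        raise ValueError("need at least 2 patients")
    rows = []
    for col in arm_a.columns:
        a, b = arm_a[col].to_numpy(float), arm_b[col].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            rows.append((col, np.nan, np.nan, np.nan, False, "insufficient finite pairs"))
            continue
        cr = coefficient_of_repeatability(a[ok], b[ok], convention=convention)
        mean = float(np.mean((a[ok] + b[ok]) / 2.0))
        pct, passed = percent_cr(cr, mean, threshold=threshold)
        reason = "" if passed else ("mean below floor" if np.isnan(pct) else f"percentCR > {threshold:g}")
        rows.append((col, cr, mean, pct, passed, reason))
    return pd.DataFrame(
        rows, columns=["feature", "cr", "cohort_mean", "percent_cr", "repeatable", "reason"]
    ).set_index("feature")


def _reference_columns(config: ExtractionConfig) -> dict[str, str]:
    refs = {"SUVmax": ALIASES["SUVmax"]}
    if "MTV25" in config.masks:
        refs["MTV25"] = ALIASES["MTV2.5"]
    if "MTV40" in config.masks:
        refs["MTV40"] = ALIASES["MTV40"]
    return refs


def independence_filter(
    features: pd.DataFrame,
    cutoff: float = 0.5,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Spearman independence of each feature from MTV and SUVmax.

    Evaluated on a single scan's feature table (arm A of the repeat pair).
    Each feature is tested against the MTV of its own mask configuration
    and against SUVmax; discarded when either |rho| >= cutoff.  The
    reference metrics themselves (SUVmax, MTV2.5, MTV40) stay in the pool:
    they are the established prognostic baseline the filter protects, not
    candidates redundant with it.  Constant features fail by convention.
    """
    config = config or ExtractionConfig()
    if len(features) < 3:
        raise ValueError("need at least 3 patients for rank correlation")
    refs = _reference_columns(config)
    missing = [c for c in refs.values() if c not in features.columns]
    if missing:
        raise ValueError(f"reference columns missing from table: {missing}")
    key_by_name = {k.qualified: k for k in enumerate_feature_space(config)}
    suvmax = features[refs["SUVmax"]].to_numpy(float)
    mtv = {m: features[refs[m]].to_numpy(float) for m in config.masks if m in refs}

    rows = []
    ref_names = set(refs.values())
    for col in features.columns:
        x = features[col].to_numpy(float)
        key = key_by_name.get(col)
        mask_role = key.mask if key is not None and key.mask is not None else config.masks[0]
        if col in ref_names:
            rows.append((col, np.nan, np.nan, True, "reference metric"))
            continue
        ok = np.isfinite(x)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            warnings.warn(f"feature {col} is constant or too sparse; rho undefined")
            rows.append((col, np.nan, np.nan, False, "constant feature"))
            continue
        rho_mtv = spearmanr(x[ok], mtv[mask_role][ok]).statistic
        rho_suv = spearmanr(x[ok], suvmax[ok]).statistic
        worst = np.nanmax(np.abs([rho_mtv, rho_suv]))
        passed = bool(worst < cutoff)
        reason = "" if passed else f"|rho| >= {cutoff:g} vs " + (
            "MTV" if abs(rho_mtv) >= abs(rho_suv) else "SUVmax"
        )
        rows.append((col, rho_mtv, rho_suv, passed, reason))
    return pd.DataFrame(
        rows, columns=["feature", "rho_mtv", "rho_suvmax", "independent", "reason"]
    ).set_index("feature")


def elbow_cluster_validation(
    abs_corr: pd.DataFrame | np.ndarray, drop_fraction: float = 0.1
) -> tuple[int, np.ndarray]:
    """Elbow estimate of the number of feature clusters.

    Average-linkage hierarchical clustering on distance 1 - |rho|.  Total
    within-cluster pairwise dissimilarity W(k) is tracked as the tree is
    cut into k = 1..n clusters; the elbow is one past the last cut whose
    dissimilarity reduction is at least ``drop_fraction`` of the largest
    reduction.  Returns (k, cluster memberships at k).
    """
    c = np.asarray(abs_corr, dtype=float)
    n = c.shape[0]
    if c.shape != (n, n) or not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("expected a square symmetric |rho| matrix")
    if n < 3:
        return n, np.arange(1, n + 1)
    dist = 1.0 - np.clip(np.abs(c), 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")

    def within(labels: np.ndarray) -> float:
        w = 0.0
        for lab in np.unique(labels):
            idx = np.where(labels == lab)[0]
            if len(idx) > 1:
                w += dist[np.ix_(idx, idx)].sum() / 2.0
        return w

    labels_k = {k: fcluster(z, t=k, criterion="maxclust") for k in range(1, n + 1)}
    w = np.array([within(labels_k[k]) for k in range(1, n + 1)])
    drops = w[:-1] - w[1:]  # reduction achieved by cut k -> k+1
    max_drop = drops.max() if drops.size else 0.0
    if max_drop <= 0:
        return 1, labels_k[1]
    significant = np.where(drops >= drop_fraction * max_drop)[0]
    k = int(significant[-1] + 2)  # one past the last significant cut
    return k, labels_k[k]


def select_features(
    repeatability: pd.DataFrame, independence: pd.DataFrame
) -> pd.DataFrame:
    """Intersect the repeatability and independence pass sets.

    Returns an audit table (one row per feature) with the pass flags, the
    final ``selected`` flag and a drop reason.  An empty selection is
    legal (downstream models then use clinical variables only).
    """
    if not repeatability.index.equals(independence.index):
        raise ValueError("result tables must cover the same feature registry")
    audit = pd.DataFrame(index=repeatability.index)
    audit["repeatable"] = repeatability["repeatable"]
    audit["independent"] = independence["independent"]
    audit["selected"] = audit["repeatable"] & audit["independent"]
    reasons = []
    for feat in audit.index:
        if audit.at[feat, "selected"]:
            reasons.append("")
        elif not audit.at[feat, "repeatable"]:
            reasons.append(f"repeatability: {repeatability.at[feat, 'reason']}")
        else:
            reasons.append(f"independence: {independence.at[feat, 'reason']}")
    audit["reason"] = reasons
    if not audit["selected"].any():
        warnings.warn("no feature passed both filters; radiomics selection is empty")
    return audit
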