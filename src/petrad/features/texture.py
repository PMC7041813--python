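"""The 74 texture features (GLCM 23, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5).

Formulas follow the standardized (IBSI-style) definitions computed on the
merged 13-direction matrices of :mod:`.matrices`.  All entropies are in
log2 (bits).  Degenerate single-level ROIs take documented limiting values
(e.g. GLCM Correlation, Imc2 and MCC -> 1; NGTDM Contrast -> 0) instead of
being undefined.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrixSet

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "texture_features",
    "TEXTURE_FEATURE_NAMES",
]

_EPS = np.finfo(float).eps


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(m: TextureMatrixSet) -> dict[str, float]:
    counts = m.glcm
    total = counts.sum()
    ng = m.ng
    p = counts / total if total > 0 else counts
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(ng, dtype=float)          # |i-j| = 0..Ng-1
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in range(ng)])
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in range(2, 2 * ng + 1)])

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((ii * jj * p).sum())
    out["JointAverage"] = mu
    dev = ii + jj - 2 * mu
    out["ClusterProminence"] = float((dev ** 4 * p).sum())
    out["ClusterShade"] = float((dev ** 3 * p).sum())
    out["ClusterTendency"] = float((dev ** 2 * p).sum())
    out["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigma2 > _EPS:
        out["Correlation"] = float(((ii * jj * p).sum() - mu * mu) / sigma2)
    else:
        out["Correlation"] = 1.0  # constant-ROI limit
    da = float((k_diff * p_diff).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = float(-_xlog2x(p_diff).sum())
    out["DifferenceVariance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    out["JointEnergy"] = float((p ** 2).sum())
    hxy = float(-_xlog2x(p).sum())
    out["JointEntropy"] = hxy

    pxpy = np.outer(px, px)
    nzj = p > 0
    hxy1 = float(-(p[nzj] * np.log2(np.maximum(pxpy[nzj], _EPS))).sum())
    hxy2 = float(-_xlog2x(pxpy).sum())
    hx = float(-_xlog2x(px).sum())
    out["Imc1"] = float((hxy - hxy1) / hx) if hx > 0 else 0.0
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    absdiff = np.abs(ii - jj)
    out["Id"] = float((p / (1.0 + absdiff)).sum())
    out["Idm"] = float((p / (1.0 + absdiff ** 2)).sum())
    out["Idmn"] = float((p / (1.0 + absdiff ** 2 / ng ** 2)).sum())
    out["Idn"] = float((p / (1.0 + absdiff / ng)).sum())
    off = absdiff > 0
    out["InverseVariance"] = float((p[off] / absdiff[off] ** 2).sum())
    out["MaximumProbability"] = float(p.max()) if p.size else 0.0
    out["MCC"] = _mcc(p, px, ng)
    out["SumEntropy"] = float(-_xlog2x(p_sum).sum())
    out["SumSquares"] = float(((ii - mu) ** 2 * p).sum())
    return out


def _mcc(p: np.ndarray, px: np.ndarray, ng: int) -> float:
    """Maximal correlation coefficient: sqrt of the 2nd-largest eigenvalue of Q."""
    if ng < 2:
        return 1.0
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    pr = p[np.ix_(keep, keep)]
    pxr = px[keep]
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
    q = (pr / pxr[:, None]) @ (pr / pxr[None, :]).T
    ev = np.linalg.eigvals(q)
    ev = np.sort(np.abs(ev.real))
    second = ev[-2] if ev.size >= 2 else 0.0
    return float(np.sqrt(max(0.0, min(1.0, second))))


def _rowcol_stats(P: np.ndarray):
    total = P.sum()
    ng, nr = P.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nr + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    return total, i, j, ii, jj


def glrlm_features(m: TextureMatrixSet) -> dict[str, float]:
    P = m.glrlm
    nr, i, j, ii, jj = _rowcol_stats(P)
    np_tot = m.n_voxels * m.n_directions
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    pn = P / nr
    pg = row / nr
    pr = col / nr
    mu_g = float((i * pg).sum())
    mu_r = float((j * pr).sum())
    return {
        "ShortRunEmphasis": float((P / jj ** 2).sum() / nr),
        "LongRunEmphasis": float((P * jj ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((row ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((row ** 2).sum() / nr ** 2),
        "RunLengthNonUniformity": float((col ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((col ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / np_tot),
        "GrayLevelVariance": float(((i - mu_g) ** 2 * pg).sum()),
        "RunVariance": float(((j - mu_r) ** 2 * pr).sum()),
        "RunEntropy": float(-_xlog2x(pn).sum()),
        "LowGrayLevelRunEmphasis": float((P / ii ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((P * ii ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (ii ** 2 * jj ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * ii ** 2 / jj ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * jj ** 2 / ii ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * ii ** 2 * jj ** 2).sum() / nr),
    }


def glszm_features(m: TextureMatrixSet) -> dict[str, float]:
    P = m.glszm
    nz, i, j, ii, jj = _rowcol_stats(P)
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    pn = P / nz
    pg = row / nz
    ps = col / nz
    mu_g = float((i * pg).sum())
    mu_s = float((j * ps).sum())
    return {
        "SmallAreaEmphasis": float((P / jj ** 2).sum() / nz),
        "LargeAreaEmphasis": float((P * jj ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((row ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((row ** 2).sum() / nz ** 2),
        "SizeZoneNonUniformity": float((col ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((col ** 2).sum() / nz ** 2),
        "ZonePercentage": float(nz / m.n_voxels),
        "GrayLevelVariance": float(((i - mu_g) ** 2 * pg).sum()),
        "ZoneVariance": float(((j - mu_s) ** 2 * ps).sum()),
        "ZoneEntropy": float(-_xlog2x(pn).sum()),
        "LowGrayLevelZoneEmphasis": float((P / ii ** 2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * ii ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (ii ** 2 * jj ** 2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * ii ** 2 / jj ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * jj ** 2 / ii ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * ii ** 2 * jj ** 2).sum() / nz),
    }


def gldm_features(m: TextureMatrixSet) -> dict[str, float]:
    P = m.gldm
    nz, i, j, ii, jj = _rowcol_stats(P)  # nz == n_voxels
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    pn = P / nz
    pg = row / nz
    pd = col / nz
    mu_g = float((i * pg).sum())
    mu_d = float((j * pd).sum())
    return {
        "SmallDependenceEmphasis": float((P / jj ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((P * jj ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((row ** 2).sum() / nz),
        "DependenceNonUniformity": float((col ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((col ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float(((i - mu_g) ** 2 * pg).sum()),
        "DependenceVariance": float(((j - mu_d) ** 2 * pd).sum()),
        "DependenceEntropy": float(-_xlog2x(pn).sum()),
        "LowGrayLevelEmphasis": float((P / ii ** 2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * ii ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (ii ** 2 * jj ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * ii ** 2 / jj ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * jj ** 2 / ii ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * ii ** 2 * jj ** 2).sum() / nz),
    }


def ngtdm_features(m: TextureMatrixSet) -> dict[str, float]:
    n_i, s_i = m.ngtdm_n, m.ngtdm_s
    n_tot = n_i.sum()
    ng = m.ng
    i = np.arange(1, ng + 1, dtype=float)
    p = n_i / n_tot if n_tot > 0 else n_i
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s_i[present]

    coarse_den = float((p * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6  # capped limit

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = float(
            (pp[:, None] * pp[None, :] * di ** 2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / n_tot)
        )
        busy_den = float(np.abs(ip * pp - (ip * pp)[:, None]).sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        num = np.abs(di) * (
            (pp * sp)[:, None] + (pp * sp)[None, :]
        ) / (pp[:, None] + pp[None, :])
        complexity = float(num.sum() / n_tot)
        s_tot = float(s_i.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * di ** 2).sum()) / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(m: TextureMatrixSet) -> dict[str, float]:
    """All 74 texture features, keys prefixed by matrix family."""
    out: dict[str, float] = {}
    for fam, fn in (
        ("glcm", glcm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("gldm", gldm_features),
        ("ngtdm", ngtdm_features),
    ):
        for name, value in fn(m).items():
            out[f"{fam}_{name}"] = value
    return out


TEXTURE_FEATURE_NAMES: tuple[str, ...] = tuple(
    texture_features(
        TextureMatrixSet(
            glcm=np.array([[2.0, 1.0], [1.0, 0.0]]),
            glrlm=np.array([[1.0, 1.0], [1.0, 0.0]]),
            glszm=np.array([[1.0, 0.0], [1.0, 0.0]]),
            gldm=np.array([[1.0, 1.0], [1.0, 0.0]]),
            ngtdm_n=np.array([2.0, 1.0]),
            ngtdm_s=np.array([0.5, 0.5]),
            ng=2,
            n_voxels=3,
        )
    ).keys()
)
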