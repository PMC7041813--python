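"""Independent brute-force oracles for texture matrices and features.

Everything here is written as plain nested loops straight from the
matrix/feature definitions, deliberately sharing no code with the package
implementation.  Inputs are 3D integer level grids with 0 marking
out-of-mask voxels.
"""

from __future__ import annotations

import math

import numpy as np

# all 26 neighbour offsets, and the 13 unique (half) directions
ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def brute_glcm(lev: np.ndarray, ng: int) -> np.ndarray:
    counts = np.zeros((ng, ng))
    shape = lev.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = lev[x, y, z]
                if a == 0:
                    continue
                for d in ALL_26:  # both directions of each of the 13 offsets
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and lev[q] > 0:
                        counts[a - 1, lev[q] - 1] += 1
    return counts


def brute_glrlm(lev: np.ndarray, ng: int) -> np.ndarray:
    shape = lev.shape
    max_run = max(shape)
    counts = np.zeros((ng, max_run))
    for d in HALF_13:
        seen = np.zeros(shape, dtype=bool)
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if lev[x, y, z] == 0 or seen[x, y, z]:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and lev[prev] == lev[x, y, z]:
                        continue  # not a run start
                    # walk the run
                    length = 0
                    p = (x, y, z)
                    while _inside(shape, p) and lev[p] == lev[x, y, z]:
                        seen[p] = True
                        length += 1
                        p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                    counts[lev[x, y, z] - 1, length - 1] += 1
    used = np.nonzero(counts.sum(axis=0))[0]
    return counts[:, : used[-1] + 1] if used.size else counts[:, :1]


def brute_glszm(lev: np.ndarray, ng: int) -> np.ndarray:
    shape = lev.shape
    n_vox = int((lev > 0).sum())
    counts = np.zeros((ng, max(n_vox, 1)))
    visited = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if lev[x, y, z] == 0 or visited[x, y, z]:
                    continue
                # BFS flood fill over the 26-neighbourhood at this level
                level = lev[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in ALL_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inside(shape, q) and not visited[q] and lev[q] == level:
                            visited[q] = True
                            stack.append(q)
                counts[level - 1, size - 1] += 1
    used = np.nonzero(counts.sum(axis=0))[0]
    return counts[:, : used[-1] + 1] if used.size else counts[:, :1]


def brute_gldm(lev: np.ndarray, ng: int) -> np.ndarray:
    shape = lev.shape
    counts = np.zeros((ng, 27))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = lev[x, y, z]
                if a == 0:
                    continue
                dep = 1  # the centre voxel itself
                for d in ALL_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and lev[q] == a:
                        dep += 1
                counts[a - 1, dep - 1] += 1
    used = np.nonzero(counts.sum(axis=0))[0]
    return counts[:, : used[-1] + 1] if used.size else counts[:, :1]


def brute_ngtdm(lev: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    shape = lev.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = lev[x, y, z]
                if a == 0:
                    continue
                n_i[a - 1] += 1
                nb = [
                    lev[x + d[0], y + d[1], z + d[2]]
                    for d in ALL_26
                    if _inside(shape, (x + d[0], y + d[1], z + d[2]))
                    and lev[x + d[0], y + d[1], z + d[2]] > 0
                ]
                if nb:
                    s_i[a - 1] += abs(a - sum(nb) / len(nb))
    return n_i, s_i


# ---------------------------------------------------------------------------
# straight-from-formula feature oracles (log base 2 throughout)


def _log2(v: float) -> float:
    return math.log2(v) if v > 0 else 0.0


def brute_glcm_features(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    p = counts / total
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    pdif = [0.0] * ng
    psum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pdif[abs(i - j)] += p[i, j]
            psum[i + j] += p[i, j]
    out = {}
    out["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["JointAverage"] = mu
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        out[name] = sum(
            (i + j + 2 - 2 * mu) ** power * p[i, j] for i in range(ng) for j in range(ng)
        )
    out["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if sig2 > 1e-12:
        out["Correlation"] = (out["Autocorrelation"] - mu * mu) / sig2
    else:
        out["Correlation"] = 1.0
    da = sum(k * pdif[k] for k in range(ng))
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(v * _log2(v) for v in pdif)
    out["DifferenceVariance"] = sum((k - da) ** 2 * pdif[k] for k in range(ng))
    out["JointEnergy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(p[i, j] * _log2(p[i, j]) for i in range(ng) for j in range(ng))
    out["JointEntropy"] = hxy
    hx = -sum(v * _log2(v) for v in px)
    hxy1 = -sum(
        p[i, j] * _log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * _log2(px[i] * px[j]) for i in range(ng) for j in range(ng)
    )
    out["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["Id"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    out["Idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    out["Idmn"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    out["Idn"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["InverseVariance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    out["MaximumProbability"] = p.max()
    # MCC via the Q matrix on levels with px > 0
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) < 2:
        out["MCC"] = 1.0
    else:
        q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * px[k]) for k in keep)
        ev = sorted(abs(np.linalg.eigvals(q).real))
        out["MCC"] = math.sqrt(max(0.0, min(1.0, ev[-2])))
    out["SumEntropy"] = -sum(v * _log2(v) for v in psum)
    out["SumSquares"] = sum(
        (i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    return out


def _run_zone_features(P: np.ndarray, n_runs_or_zones: float, n_pix: float,
                       names: dict[str, str]) -> dict[str, float]:
    ng, nr = P.shape
    n = P.sum()
    out = {}
    out[names["se"]] = sum(P[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nr)) / n
    out[names["le"]] = sum(P[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nr)) / n
    row = [sum(P[i, j] for j in range(nr)) for i in range(ng)]
    col = [sum(P[i, j] for i in range(ng)) for j in range(nr)]
    out[names["gln"]] = sum(r**2 for r in row) / n
    if "glnn" in names:
        out[names["glnn"]] = sum(r**2 for r in row) / n**2
    out[names["rln"]] = sum(c**2 for c in col) / n
    if "rlnn" in names:
        out[names["rlnn"]] = sum(c**2 for c in col) / n**2
    if "pct" in names:
        out[names["pct"]] = n / n_pix
    mu_g = sum((i + 1) * row[i] / n for i in range(ng))
    mu_r = sum((j + 1) * col[j] / n for j in range(nr))
    out[names["glv"]] = sum((i + 1 - mu_g) ** 2 * row[i] / n for i in range(ng))
    out[names["rv"]] = sum((j + 1 - mu_r) ** 2 * col[j] / n for j in range(nr))
    out[names["ent"]] = -sum(
        (P[i, j] / n) * _log2(P[i, j] / n) for i in range(ng) for j in range(nr)
    )
    out[names["lgl"]] = sum(P[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nr)) / n
    out[names["hgl"]] = sum(P[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nr)) / n
    out[names["slgl"]] = (
        sum(P[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nr)) / n
    )
    out[names["shgl"]] = (
        sum(P[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nr)) / n
    )
    out[names["llgl"]] = (
        sum(P[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nr)) / n
    )
    out[names["lhgl"]] = (
        sum(P[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nr)) / n
    )
    return out


def brute_glrlm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_features(
        P, P.sum(), 13 * n_voxels,
        {
            "se": "ShortRunEmphasis", "le": "LongRunEmphasis",
            "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
            "rln": "RunLengthNonUniformity", "rlnn": "RunLengthNonUniformityNormalized",
            "pct": "RunPercentage", "glv": "GrayLevelVariance", "rv": "RunVariance",
            "ent": "RunEntropy", "lgl": "LowGrayLevelRunEmphasis",
            "hgl": "HighGrayLevelRunEmphasis", "slgl": "ShortRunLowGrayLevelEmphasis",
            "shgl": "ShortRunHighGrayLevelEmphasis", "llgl": "LongRunLowGrayLevelEmphasis",
            "lhgl": "LongRunHighGrayLevelEmphasis",
        },
    )


def brute_glszm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_features(
        P, P.sum(), n_voxels,
        {
            "se": "SmallAreaEmphasis", "le": "LargeAreaEmphasis",
            "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
            "rln": "SizeZoneNonUniformity", "rlnn": "SizeZoneNonUniformityNormalized",
            "pct": "ZonePercentage", "glv": "GrayLevelVariance", "rv": "ZoneVariance",
            "ent": "ZoneEntropy", "lgl": "LowGrayLevelZoneEmphasis",
            "hgl": "HighGrayLevelZoneEmphasis", "slgl": "SmallAreaLowGrayLevelEmphasis",
            "shgl": "SmallAreaHighGrayLevelEmphasis", "llgl": "LargeAreaLowGrayLevelEmphasis",
            "lhgl": "LargeAreaHighGrayLevelEmphasis",
        },
    )


def brute_gldm_features(P: np.ndarray) -> dict[str, float]:
    out = _run_zone_features(
        P, P.sum(), P.sum(),
        {
            "se": "SmallDependenceEmphasis", "le": "LargeDependenceEmphasis",
            "gln": "GrayLevelNonUniformity",
            "rln": "DependenceNonUniformity", "rlnn": "DependenceNonUniformityNormalized",
            "glv": "GrayLevelVariance", "rv": "DependenceVariance",
            "ent": "DependenceEntropy", "lgl": "LowGrayLevelEmphasis",
            "hgl": "HighGrayLevelEmphasis", "slgl": "SmallDependenceLowGrayLevelEmphasis",
            "shgl": "SmallDependenceHighGrayLevelEmphasis",
            "llgl": "LargeDependenceLowGrayLevelEmphasis",
            "lhgl": "LargeDependenceHighGrayLevelEmphasis",
        },
    )
    return out


def brute_ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    ng = len(n_i)
    n = n_i.sum()
    p = n_i / n
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    coarse_den = sum(p[i] * s_i[i] for i in range(ng))
    out = {"Coarseness": 1.0 / coarse_den if coarse_den > 0 else 1e6}
    if ngp > 1:
        out["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
            * (s_i.sum() / n)
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        out["Busyness"] = coarse_den / busy_den if busy_den > 0 else 0.0
        out["Complexity"] = (
            sum(
                abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / n
        )
        s_tot = s_i.sum()
        out["Strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        out.update({"Contrast": 0.0, "Busyness": 0.0, "Complexity": 0.0, "Strength": 0.0})
    return out


def brute_all_texture_features(lev: np.ndarray, ng: int) -> dict[str, float]:
    """All 74 features, keyed like the package (family_Name)."""
    n_voxels = int((lev > 0).sum())
    out = {}
    for name, v in brute_glcm_features(brute_glcm(lev, ng)).items():
        out[f"glcm_{name}"] = v
    for name, v in brute_glrlm_features(brute_glrlm(lev, ng), n_voxels).items():
        out[f"glrlm_{name}"] = v
    for name, v in brute_glszm_features(brute_glszm(lev, ng), n_voxels).items():
        out[f"glszm_{name}"] = v
    for name, v in brute_gldm_features(brute_gldm(lev, ng)).items():
        out[f"gldm_{name}"] = v
    n_i, s_i = brute_ngtdm(lev, ng)
    for name, v in brute_ngtdm_features(n_i, s_i).items():
        out[f"ngtdm_{name}"] = v
    return out
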