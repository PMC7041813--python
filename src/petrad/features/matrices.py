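"""Texture matrices over a discretized ROI.

All five matrix families are built from a *single* merged matrix pooling
the 13 unique 3D direction vectors at Chebyshev distance 1 (the 26
neighbours modulo central symmetry):

* GLCM  — symmetric gray-level co-occurrence counts pooled over the 13
  offsets and their opposites;
* GLRLM — run-length counts, runs traced independently per direction and
  the 13 per-direction matrices summed;
* GLSZM — sizes of 26-connected constant-level zones;
* GLDM  — dependence counts over the 26-neighbourhood at zero gray-level
  tolerance, the centre voxel included in the dependence size;
* NGTDM — per-level voxel counts n_i and summed absolute differences s_i
  between a voxel's level and the mean level of its available in-mask
  neighbours (voxels with no in-mask neighbour contribute 0 to s_i).

Computation is restricted to the bounding box of the mask.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..segmentation import DiscretizedROI

__all__ = ["TextureMatrixSet", "texture_matrices", "DIRECTIONS_13"]

# the 13 unique direction vectors: first non-zero component positive
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)
assert len(DIRECTIONS_13) == 13


@dataclass
class TextureMatrixSet:
    glcm: np.ndarray       # Ng x Ng symmetric counts
    glrlm: np.ndarray      # Ng x Rmax run counts (merged over 13 directions)
    glszm: np.ndarray      # Ng x Zmax zone-size counts
    gldm: np.ndarray       # Ng x Dmax dependence counts
    ngtdm_n: np.ndarray    # per-level voxel counts n_i, length Ng
    ngtdm_s: np.ndarray    # per-level summed neighbourhood differences s_i
    ng: int
    n_voxels: int
    n_directions: int = 13


def _offset_slices(shape, off):
    """Slice pair (src, dst) such that src + off == dst, elementwise."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _crop(disc: DiscretizedROI) -> np.ndarray:
    mask = disc.mask.values
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return disc.level_grid[sl]


def _glcm(lev: np.ndarray, ng: int) -> np.ndarray:
    counts = np.zeros((ng, ng), dtype=float)
    for off in DIRECTIONS_13:
        src, dst = _offset_slices(lev.shape, off)
        a, b = lev[src], lev[dst]
        valid = (a > 0) & (b > 0)
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    return counts + counts.T  # each pair counted in both directions


def _glrlm(lev: np.ndarray, ng: int) -> np.ndarray:
    max_run = int(max(lev.shape))
    counts = np.zeros((ng, max_run), dtype=float)
    inmask = lev > 0
    for off in DIRECTIONS_13:
        src, dst = _offset_slices(lev.shape, off)
        # link[x] : voxel x continues its run at x + off
        link = np.zeros(lev.shape, dtype=bool)
        link[src] = inmask[src] & inmask[dst] & (lev[src] == lev[dst])
        # remaining run length from x, by backward propagation along off
        run = inmask.astype(np.int64)
        for _ in range(max_run - 1):
            nxt = np.zeros(lev.shape, dtype=np.int64)
            nxt[src] = run[dst]
            new = np.where(link, 1 + nxt, inmask.astype(np.int64))
            if np.array_equal(new, run):
                break
            run = new
        # run starts: in-mask voxels not continued from x - off
        start = inmask.copy()
        start[dst] &= ~link[src]
        lv = lev[start] - 1
        rl = run[start] - 1
        np.add.at(counts, (lv, rl), 1.0)
    used = counts.sum(axis=0).nonzero()[0]
    rmax = used[-1] + 1 if used.size else 1
    return counts[:, :rmax]


def _glszm(lev: np.ndarray, ng: int, n_vox: int) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=int)
    counts = np.zeros((ng, n_vox), dtype=float)
    for g in range(1, ng + 1):
        comp, n_comp = ndimage.label(lev == g, structure=structure)
        if n_comp:
            sizes = np.bincount(comp.ravel())[1:]
            np.add.at(counts, (g - 1, sizes - 1), 1.0)
    used = counts.sum(axis=0).nonzero()[0]
    zmax = used[-1] + 1 if used.size else 1
    return counts[:, :zmax]


def _gldm(lev: np.ndarray, ng: int) -> np.ndarray:
    inmask = lev > 0
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        src, dst = _offset_slices(lev.shape, off)
        eq = inmask[src] & inmask[dst] & (lev[src] == lev[dst])
        dep[src] += eq
        dep[dst] += eq
    dep += 1  # centre voxel counts towards its own dependence
    counts = np.zeros((ng, 27), dtype=float)
    np.add.at(counts, (lev[inmask] - 1, dep[inmask] - 1), 1.0)
    used = counts.sum(axis=0).nonzero()[0]
    dmax = used[-1] + 1 if used.size else 1
    return counts[:, :dmax]


def _ngtdm(lev: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    inmask = lev > 0
    nb_sum = np.zeros(lev.shape, dtype=float)
    nb_cnt = np.zeros(lev.shape, dtype=np.int64)
    for off in DIRECTIONS_13:
        src, dst = _offset_slices(lev.shape, off)
        both = inmask[src] & inmask[dst]
        nb_sum[src] += np.where(both, lev[dst], 0)
        nb_cnt[src] += both
        nb_sum[dst] += np.where(both, lev[src], 0)
        nb_cnt[dst] += both
    n_i = np.zeros(ng, dtype=float)
    s_i = np.zeros(ng, dtype=float)
    has_nb = inmask & (nb_cnt > 0)
    mean_nb = np.zeros(lev.shape, dtype=float)
    mean_nb[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    np.add.at(n_i, lev[inmask] - 1, 1.0)
    np.add.at(s_i, lev[has_nb] - 1, np.abs(lev[has_nb] - mean_nb[has_nb]))
    return n_i, s_i


def texture_matrices(disc: DiscretizedROI) -> TextureMatrixSet:
    """Build all five texture matrices for a discretized ROI."""
    lev = _crop(disc)
    ng = disc.ng
    n_vox = int((lev > 0).sum())
    n_i, s_i = _ngtdm(lev, ng)
    return TextureMatrixSet(
        glcm=_glcm(lev, ng),
        glrlm=_glrlm(lev, ng),
        glszm=_glszm(lev, ng, n_vox),
        gldm=_gldm(lev, ng),
        ngtdm_n=n_i,
        ngtdm_s=s_i,
        ng=ng,
        n_voxels=n_vox,
    )
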