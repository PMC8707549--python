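"""Gray-level texture matrices: GLCM, GLRLM, GLSZM, NGTDM.

Conventions (recorded in provenance):

* GLCM — distance-1 offsets over the 13 unique 3D directions, symmetric
  accumulation, only voxel pairs fully inside the mask; features are read
  from a single pooled matrix rather than per-direction matrices.
* GLRLM — runs confined to the mask, one matrix per direction, features
  averaged over the 13 directions.
* GLSZM — 26-connected zones of identical level, one matrix.
* NGTDM — only voxels whose complete 26-neighborhood lies in the mask
  contribute; coarseness uses epsilon = 1e-12 and is capped at 1e12.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .quantize import QuantizedROI

__all__ = [
    "OFFSETS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]

#: The 13 unique direction vectors of the 26-neighborhood (one per +/- pair).
OFFSETS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

_EPS = 1e-12
_COARSENESS_CAP = 1e12  # documented maximum: 1/epsilon


def _shifted_views(a: np.ndarray, off: tuple[int, int, int]):
    """Overlapping views of ``a`` displaced by ``off`` (first, second)."""
    sl_a, sl_b = [], []
    for d, n in zip(off, a.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return a[tuple(sl_a)], a[tuple(sl_b)]


def glcm_matrix(q: QuantizedROI) -> np.ndarray:
    """Pooled symmetric co-occurrence counts, normalized to probabilities."""
    n = q.n_levels
    counts = np.zeros((n, n), dtype=np.float64)
    lv = q.levels
    for off in OFFSETS_13:
        a, b = _shifted_views(lv, off)
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        idx = a[ok] - 1, b[ok] - 1
        np.add.at(counts, idx, 1.0)
        np.add.at(counts, idx[::-1], 1.0)  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pair for GLCM")
    return counts / total


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_features(q: QuantizedROI) -> tuple[dict, set]:
    values: dict[str, float] = {}
    undefined: set[str] = set()
    try:
        p = glcm_matrix(q)
    except ValueError:
        names = [
            "GLCM_Entropy", "GLCM_Diff_Entropy", "GLCM_Contrast",
            "GLCM_Dissimilarity", "GLCM_Homogeneity", "GLCM_Energy",
            "GLCM_Correlation", "GLCM_Sum_Average", "GLCM_Sum_Entropy",
            "GLCM_Cluster_Shade", "GLCM_Cluster_Prominence", "GLCM_Max_Probability",
        ]
        return {k: 0.0 for k in names}, set(names)

    n = q.n_levels
    i = np.arange(1, n + 1, dtype=np.float64)[:, None]
    j = np.arange(1, n + 1, dtype=np.float64)[None, :]
    diff = np.abs(i - j)

    values["GLCM_Entropy"] = _entropy2(p)
    # difference distribution p_{|i-j|}
    pdiff = np.zeros(n)
    for k in range(n):
        pdiff[k] = p[diff == k].sum()
    values["GLCM_Diff_Entropy"] = _entropy2(pdiff)
    values["GLCM_Contrast"] = float((p * (i - j) ** 2).sum())
    values["GLCM_Dissimilarity"] = float((p * diff).sum())
    values["GLCM_Homogeneity"] = float((p / (1.0 + (i - j) ** 2)).sum())
    values["GLCM_Energy"] = float((p**2).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i > 0 and var_j > 0:
        values["GLCM_Correlation"] = float(
            (p * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j)
        )
    else:
        values["GLCM_Correlation"] = 0.0
        undefined.add("GLCM_Correlation")
    # sum distribution p_{i+j}, k = 2..2n
    psum = np.zeros(2 * n + 1)
    ksum = (np.add.outer(np.arange(1, n + 1), np.arange(1, n + 1))).ravel()
    np.add.at(psum, ksum, p.ravel())
    kvals = np.arange(2 * n + 1, dtype=np.float64)
    values["GLCM_Sum_Average"] = float((kvals * psum).sum())
    values["GLCM_Sum_Entropy"] = _entropy2(psum)
    dev = i + j - mu_i - mu_j
    values["GLCM_Cluster_Shade"] = float((p * dev**3).sum())
    values["GLCM_Cluster_Prominence"] = float((p * dev**4).sum())
    values["GLCM_Max_Probability"] = float(p.max())
    return values, undefined


def _runs_in_direction(levels: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix r(level, length) for one direction, runs in-mask."""
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum((s * abs(d)) ** 2 for s, d in zip(shape, off))))) + 2
    nlev = int(levels.max())
    r = np.zeros((nlev, max_len + 1), dtype=np.float64)
    inb = lambda z, y, x: 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]
    for z0, y0, x0 in zip(*np.nonzero(levels)):
        pz, py, px = z0 - off[0], y0 - off[1], x0 - off[2]
        lev = levels[z0, y0, x0]
        # only start a run if the predecessor does not continue it
        if inb(pz, py, px) and levels[pz, py, px] == lev:
            continue
        length = 1
        z, y, x = z0 + off[0], y0 + off[1], x0 + off[2]
        while inb(z, y, x) and levels[z, y, x] == lev:
            length += 1
            z, y, x = z + off[0], y + off[1], x + off[2]
        r[lev - 1, length] += 1.0
    return r


def glrlm_features(q: QuantizedROI) -> tuple[dict, set]:
    """Direction-averaged run-length features over the 13 directions."""
    np_vox = q.n_voxels
    if np_vox == 0:
        raise ValueError("empty mask")
    per_dir: dict[str, list[float]] = {}
    for off in OFFSETS_13:
        r = _runs_in_direction(q.levels, off)
        nr = r.sum()
        lengths = np.arange(r.shape[1], dtype=np.float64)
        lengths[0] = 1.0  # column 0 is always empty; avoid 0/0
        glev = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
        feats = {
            "Run_SPE": float((r / lengths**2).sum() / nr),
            "Run_LRE": float((r * lengths**2).sum() / nr),
            "Run_PP": float(nr / np_vox),
            "Run_GLN": float((r.sum(axis=1) ** 2).sum() / nr),
            "Run_RLN": float((r.sum(axis=0) ** 2).sum() / nr),
            "Run_LGRE": float((r / glev**2).sum() / nr),
            "Run_HGRE": float((r * glev**2).sum() / nr),
        }
        for k, v in feats.items():
            per_dir.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in per_dir.items()}, set()


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Zone counts z(level, size) from 26-connected same-level components."""
    structure = np.ones((3, 3, 3), dtype=bool)
    nlev = int(q.levels.max())
    max_size = q.n_voxels
    z = np.zeros((nlev, max_size + 1), dtype=np.float64)
    for lev in range(1, nlev + 1):
        comp, ncomp = ndimage.label(q.levels == lev, structure=structure)
        if ncomp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        for s in sizes:
            z[lev - 1, int(s)] += 1.0
    return z


def glszm_features(q: QuantizedROI) -> tuple[dict, set]:
    z = glszm_matrix(q)
    nz = z.sum()
    sizes = np.arange(z.shape[1], dtype=np.float64)
    sizes[0] = 1.0
    glev = np.arange(1, z.shape[0] + 1, dtype=np.float64)[:, None]
    values = {
        "Zone_SAE": float((z / sizes**2).sum() / nz),
        "Zone_LAE": float((z * sizes**2).sum() / nz),
        "Zone_ZP": float(nz / q.n_voxels),
        "Zone_GLN": float((z.sum(axis=1) ** 2).sum() / nz),
        "Zone_ZSN": float((z.sum(axis=0) ** 2).sum() / nz),
        "Zone_LGZE": float((z / glev**2).sum() / nz),
        "Zone_HGZE": float((z * glev**2).sum() / nz),
    }
    return values, set()


def ngtdm_features(q: QuantizedROI) -> tuple[dict, set]:
    """Neighboring gray-tone difference features (Amadasun & King forms)."""
    names = ["NGTDM_Coarseness", "NGTDM_Contrast", "NGTDM_Busyness",
             "NGTDM_Complexity", "NGTDM_Strength"]
    lv = q.levels
    mask = lv > 0
    # complete 26-neighborhood must be inside the mask
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if not eroded.any():
        return {k: 0.0 for k in names}, set(names)

    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.convolve(lv.astype(np.float64), kernel, mode="constant")
    neigh_mean = neigh_sum / 26.0

    nlev = int(lv.max())
    s = np.zeros(nlev + 1)
    cnt = np.zeros(nlev + 1)
    vals = lv[eroded]
    diffs = np.abs(vals - neigh_mean[eroded])
    np.add.at(s, vals, diffs)
    np.add.at(cnt, vals, 1.0)
    nvalid = cnt.sum()
    p = cnt / nvalid

    present = np.nonzero(p > 0)[0]
    i = present.astype(np.float64)
    pi, si = p[present], s[present]
    ng = len(present)

    values: dict[str, float] = {}
    undefined: set[str] = set()
    denom = float((pi * si).sum())
    values["NGTDM_Coarseness"] = float(min(1.0 / (_EPS + denom), _COARSENESS_CAP))
    if ng > 1:
        ii, jj = np.meshgrid(i, i, indexing="ij")
        ppi, ppj = np.meshgrid(pi, pi, indexing="ij")
        values["NGTDM_Contrast"] = float(
            (ppi * ppj * (ii - jj) ** 2).sum() / (ng * (ng - 1)) * s.sum() / nvalid
        )
        busy_den = float(np.abs(ii * ppi - jj * ppj).sum())
        values["NGTDM_Busyness"] = denom / busy_den if busy_den > 0 else 0.0
        ssi, ssj = np.meshgrid(si, si, indexing="ij")
        values["NGTDM_Complexity"] = float(
            (np.abs(ii - jj) * (ppi * ssi + ppj * ssj) / (ppi + ppj)).sum() / nvalid
        )
        values["NGTDM_Strength"] = float(
            ((ppi + ppj) * (ii - jj) ** 2).sum() / (_EPS + s.sum())
        )
    else:
        for k in ("NGTDM_Contrast", "NGTDM_Busyness", "NGTDM_Complexity",
                  "NGTDM_Strength"):
            values[k] = 0.0
            undefined.add(k)
    return values, undefined
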