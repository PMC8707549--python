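"""Filter-bank features: Laplacian of Gaussian, 3D Laws energies, Haar wavelet.

The LoG kernel is built explicitly (truncation radius 4*sigma) and
DC-corrected so its coefficients sum to zero; features summarize the
in-mask filter response.  Laws features use the classic separable 5-tap
kernels L5/E5/S5 combined into 3D masks; the 27 ordered combinations are
averaged over axis permutations, giving 10 distinct multiset features.
Wavelet features are mean absolute coefficients of the 8 subbands of a
one-level 3D Haar transform over the lesion bounding box.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pywt
from scipy import ndimage, signal

__all__ = ["log_kernel", "log_features", "laws_features", "wavelet_features"]

_HIST_BINS = 64

_LAWS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
}


def log_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """3D Laplacian-of-Gaussian kernel, DC-corrected to zero sum."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = int(np.ceil(truncate * sigma))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = zz**2 + yy**2 + xx**2
    gauss = np.exp(-r2 / (2.0 * sigma**2))
    gauss /= gauss.sum()
    kern = (r2 - 3.0 * sigma**2) / sigma**4 * gauss
    return kern - kern.mean()  # DC correction


def _response_summary(resp: np.ndarray, prefix: str) -> dict:
    values = {
        f"{prefix}_Mean": float(resp.mean()),
        f"{prefix}_SD": float(resp.std()),
    }
    if resp.max() - resp.min() < 1e-8:
        # single-bin rule: effectively constant response
        values[f"{prefix}_Entropy"] = 0.0
        values[f"{prefix}_Uniformity"] = 1.0
    else:
        hist, _ = np.histogram(resp, bins=_HIST_BINS)
        p = hist / hist.sum()
        nz = p[p > 0]
        values[f"{prefix}_Entropy"] = float(-(nz * np.log2(nz)).sum())
        values[f"{prefix}_Uniformity"] = float((p**2).sum())
    return values


def log_features(
    volume: np.ndarray,
    mask: np.ndarray,
    sigmas=(1.5, 2.5),
) -> tuple[dict, set]:
    """Entropy/mean/sd/uniformity of the LoG response at each sigma.

    Feature suffixes _p1, _p2, ... index the position of the sigma in the
    configured list.
    """
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    values: dict[str, float] = {}
    for k, sigma in enumerate(sigmas, start=1):
        kern = log_kernel(sigma)
        if any(ks > vs for ks, vs in zip(kern.shape, volume.shape)):
            raise ValueError(
                f"LoG kernel {kern.shape} exceeds volume {volume.shape} at sigma={sigma}"
            )
        # edge-replicate padding keeps the boundary from leaking zeros into
        # the response (a constant volume then responds exactly zero)
        radius = kern.shape[0] // 2
        padded = np.pad(volume, radius, mode="edge")
        resp = signal.fftconvolve(padded, kern, mode="same")[
            radius:-radius, radius:-radius, radius:-radius
        ]
        summary = _response_summary(resp[mask], "LoG")
        for key, v in summary.items():  # LoG_Mean -> LoG_Mean_p1 etc.
            values[f"{key}_p{k}"] = v
    return values, set()


def laws_features(volume: np.ndarray, mask: np.ndarray) -> tuple[dict, set]:
    """Mean absolute 3D Laws filter response in the mask, 10 multiset masks."""
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    by_multiset: dict[str, list[float]] = {}
    for names in product(_LAWS_1D, repeat=3):
        resp = volume
        for axis, nm in enumerate(names):
            resp = ndimage.convolve1d(resp, _LAWS_1D[nm], axis=axis, mode="reflect")
        key = "Laws_" + "".join(sorted(names))
        by_multiset.setdefault(key, []).append(float(np.abs(resp[mask]).mean()))
    return {k: float(np.mean(v)) for k, v in by_multiset.items()}, set()


WAVELET_SUBBANDS = ["aaa", "aad", "ada", "add", "daa", "dad", "dda", "ddd"]


def wavelet_features(volume: np.ndarray, mask: np.ndarray) -> tuple[dict, set]:
    """Per-subband mean |coefficient| of a one-level 3D Haar transform.

    Computed over the lesion bounding box; coefficients are weighted by the
    mask support down-sampled to the coefficient grid (a 2x2x2 block counts
    as support if any of its voxels is in the mask).  A bounding box smaller
    than 8 voxels on any axis leaves the family undefined.
    """
    names = [f"Wavelet_{b.upper()}" for b in WAVELET_SUBBANDS]
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    coords = np.nonzero(mask)
    bbox = tuple(slice(int(c.min()), int(c.max()) + 1) for c in coords)
    crop = volume[bbox]
    mcrop = mask[bbox]
    if any(s < 8 for s in crop.shape):
        return {k: 0.0 for k in names}, set(names)

    # pad to even sizes so coefficient grids align with 2x2x2 blocks
    pad = [(0, s % 2) for s in crop.shape]
    crop = np.pad(crop, pad, mode="edge")
    mcrop = np.pad(mcrop, pad, mode="edge")
    support = (
        mcrop.reshape(crop.shape[0] // 2, 2, crop.shape[1] // 2, 2, crop.shape[2] // 2, 2)
        .any(axis=(1, 3, 5))
    )

    coeffs = pywt.dwtn(crop, "haar", mode="periodization")
    values: dict[str, float] = {}
    for band in WAVELET_SUBBANDS:
        c = coeffs[band]
        sel = np.abs(c[support])
        values[f"Wavelet_{band.upper()}"] = float(sel.mean()) if sel.size else 0.0
    return values, set()
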