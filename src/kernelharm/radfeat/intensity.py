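"""Histogram-derived intensity features and gradient (edge-frequency) features."""

from __future__ import annotations

import numpy as np

__all__ = ["intensity_features", "edge_freq_features", "edge_freq_mean"]

_HIST_BINS = 64


def _population_moment(vals: np.ndarray, k: int) -> float:
    return float(np.mean((vals - vals.mean()) ** k))


def _skewness(vals: np.ndarray) -> tuple[float, bool]:
    """Population skewness m3 / m2^1.5; (0, flagged) for zero variance."""
    m2 = _population_moment(vals, 2)
    if m2 == 0:
        return 0.0, True
    return _population_moment(vals, 3) / m2**1.5, False


def intensity_features(volume: np.ndarray, mask: np.ndarray) -> tuple[dict, set]:
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = volume[mask]

    values: dict[str, float] = {}
    undefined: set[str] = set()

    values["Intensity_Mean"] = float(vals.mean())
    values["Intensity_SD"] = float(vals.std())  # population sd
    values["Intensity_Variance"] = float(vals.var())
    values["Intensity_Min"] = float(vals.min())
    values["Intensity_Max"] = float(vals.max())
    values["Intensity_Range"] = float(vals.max() - vals.min())
    values["Intensity_Median"] = float(np.median(vals))
    q75, q25 = np.percentile(vals, [75, 25])
    values["Intensity_IQR"] = float(q75 - q25)
    values["Intensity_P10"] = float(np.percentile(vals, 10))
    values["Intensity_P25"] = float(q25)
    values["Intensity_P90"] = float(np.percentile(vals, 90))
    values["Intensity_Energy"] = float(np.mean(vals**2))
    if values["Intensity_Mean"] != 0:
        values["Intensity_CV"] = values["Intensity_SD"] / abs(values["Intensity_Mean"])
    else:
        values["Intensity_CV"] = 0.0
        undefined.add("Intensity_CV")

    # histogram entropy / uniformity over the in-mask range
    if vals.max() > vals.min():
        hist, _ = np.histogram(vals, bins=_HIST_BINS)
        p = hist / hist.sum()
        nz = p[p > 0]
        values["Intensity_Entropy"] = float(-(nz * np.log2(nz)).sum())
        values["Intensity_Uniformity"] = float((p**2).sum())
    else:
        values["Intensity_Entropy"] = 0.0
        values["Intensity_Uniformity"] = 1.0

    sk3, flag3 = _skewness(vals)
    values["Intensity_Skewness_3D"] = sk3
    if flag3:
        undefined.add("Intensity_Skewness_3D")

    # 2D variant: mean of per-axial-slice skewness, slices with >= 10 voxels
    slice_sk = []
    for z in range(volume.shape[2]):
        m = mask[:, :, z]
        if int(m.sum()) >= 10:
            sk, flag = _skewness(volume[:, :, z][m])
            if not flag:
                slice_sk.append(sk)
    if slice_sk:
        values["Intensity_Skewness_2D"] = float(np.mean(slice_sk))
    else:
        values["Intensity_Skewness_2D"] = 0.0
        undefined.add("Intensity_Skewness_2D")

    m2 = _population_moment(vals, 2)
    if m2 > 0:
        values["Intensity_Kurtosis"] = _population_moment(vals, 4) / m2**2
    else:
        values["Intensity_Kurtosis"] = 0.0
        undefined.add("Intensity_Kurtosis")
    return values, undefined


def _gradient_magnitude(volume: np.ndarray, spacing) -> np.ndarray:
    grads = np.gradient(volume, *spacing)
    return np.sqrt(sum(g**2 for g in grads))


def edge_freq_features(
    volume: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> tuple[dict, set]:
    """Summaries of the central-difference gradient magnitude inside the mask."""
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    gm = _gradient_magnitude(volume, spacing)[mask]
    return {
        "EdgeFreq_Mean": float(gm.mean()),
        "EdgeFreq_SD": float(gm.std()),
        "EdgeFreq_P90": float(np.percentile(gm, 90)),
        "EdgeFreq_Max": float(gm.max()),
    }, set()


def edge_freq_mean(volume: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Mean in-mask 3D gradient magnitude (central differences)."""
    values, _ = edge_freq_features(volume, mask, spacing)
    return values["EdgeFreq_Mean"]
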