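"""Lesion shape descriptors and boundary-sharpness (sigmoid slope) features.

Shape features depend only on the mask and the voxel spacing, so they are
identical across kernel renderings of the same lesion — the baseline
against which texture-feature reproducibility is judged.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.distance import pdist

__all__ = ["shape_features", "sigmoid_slope_features"]


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total area of mask voxel faces exposed to the outside."""
    sz, sy, sx = spacing
    face_areas = (sy * sx, sz * sx, sz * sy)  # faces normal to z, y, x
    area = 0.0
    for axis, fa in enumerate(face_areas):
        m = mask.astype(np.int8)
        d = np.diff(m, axis=axis)
        exposed = np.abs(d).sum()
        # boundary faces at the array edges
        first = np.take(m, 0, axis=axis).sum()
        last = np.take(m, m.shape[axis] - 1, axis=axis).sum()
        area += fa * float(exposed + first + last)
    return area


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(mask & ~eroded)


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> tuple[dict, set]:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = spacing[0] * spacing[1] * spacing[2]
    n = int(mask.sum())
    volume = n * voxel_volume
    area = _surface_area(mask, spacing)

    surf = _surface_voxels(mask).astype(np.float64) * np.asarray(spacing)
    max_diam = float(pdist(surf).max()) if len(surf) > 1 else 0.0

    bbox_vol = 1.0
    for c, s in zip(np.nonzero(mask), spacing):
        bbox_vol *= (int(c.max()) - int(c.min()) + 1) * s

    values = {
        "Shape_Volume_mm3": volume,
        "Shape_SurfaceArea_mm2": area,
        "Shape_Compactness": float(36.0 * np.pi * volume**2 / area**3),
        "Shape_Sphericity": float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area),
        "Shape_MaxDiameter3D_mm": max_diam,
        "Shape_SurfaceToVolume": float(area / volume),
        "Shape_EquivSphereDiameter_mm": float((6.0 * volume / np.pi) ** (1.0 / 3.0)),
        "Shape_Extent": float(volume / bbox_vol),
    }
    return values, set()


# --- boundary sharpness ------------------------------------------------------

_DIRECTIONS_26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.float64,
)
_DIRECTIONS_26 /= np.linalg.norm(_DIRECTIONS_26, axis=1, keepdims=True)


def _logistic(t, a, b, t0, s):
    with np.errstate(over="ignore"):  # saturated tails are fine
        return a + b / (1.0 + np.exp(-(t - t0) / s))


def sigmoid_slope_features(
    volume: np.ndarray,
    mask: np.ndarray,
    n_directions: int = 26,
    step: float = 0.25,
) -> tuple[dict, set]:
    """Mean maximum slope of logistic fits to radial boundary profiles.

    Rays are cast from the mask centroid along the 26 unit directions; the
    intensity profile along each ray (trilinear sampling, ``step``-voxel
    spacing, out to twice the boundary distance) is fitted with
    ``I(t) = a + b / (1 + exp(-(t - t0)/s))``, ``s > 0``.  The reported
    Sigmoid_Slope is the mean of |b|/(4s) — the magnitude of the logistic's
    maximum slope — over successful fits; Sigmoid_Amplitude is the mean |b|.
    Fewer than 3 successful fits leaves both undefined.
    """
    names = ["Sigmoid_Slope", "Sigmoid_Amplitude"]
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    centroid = np.array(ndimage.center_of_mass(mask))

    slopes, amps = [], []
    dirs = _DIRECTIONS_26[:n_directions]
    for d in dirs:
        # boundary distance along this ray
        t_edge = None
        t = 0.0
        for _ in range(int(max(volume.shape) / step)):
            pos = centroid + t * d
            if np.any(pos < 0) or np.any(pos > np.array(volume.shape) - 1):
                break
            idx = tuple(np.round(pos).astype(int))
            if not mask[idx]:
                t_edge = t
                break
            t += step
        if t_edge is None or t_edge <= 0:
            continue
        ts = np.arange(0.0, 2.0 * t_edge + step, step)
        coords = centroid[:, None] + d[:, None] * ts[None, :]
        inside = np.all((coords >= 0) & (coords <= (np.array(volume.shape) - 1)[:, None]), axis=0)
        ts = ts[inside]
        if len(ts) < 8:
            continue
        profile = ndimage.map_coordinates(volume, coords[:, inside], order=3,
                                          mode="nearest")
        rng_prof = profile.max() - profile.min()
        if rng_prof < 1e-9:
            continue  # flat profile: no edge to fit
        p0 = [profile[0], profile[-1] - profile[0], t_edge, 1.0]
        try:
            popt, _ = optimize.curve_fit(
                _logistic,
                ts,
                profile,
                p0=p0,
                bounds=(
                    [-np.inf, -np.inf, 0.0, 1e-3],
                    [np.inf, np.inf, ts[-1], ts[-1]],
                ),
                maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        a, b, t0, s = popt
        if s <= 0:
            continue
        slopes.append(abs(b) / (4.0 * s))
        amps.append(abs(b))

    if len(slopes) < 3:
        return {k: 0.0 for k in names}, set(names)
    return {
        "Sigmoid_Slope": float(np.mean(slopes)),
        "Sigmoid_Amplitude": float(np.mean(amps)),
    }, set()
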