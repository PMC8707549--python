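"""Gray-level quantization of a masked ROI.

All texture matrices operate on a quantized ROI: in-mask intensities are
binned into ``n_levels`` equal-width bins spanning the in-mask range, giving
integer levels 1..n_levels (0 marks out-of-mask voxels).  A constant ROI
maps entirely to level 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuantizedROI", "quantize_roi"]


@dataclass
class QuantizedROI:
    levels: np.ndarray  # 3D int array over the mask's bounding box; 0 outside
    n_levels: int
    bin_edges: np.ndarray  # strictly increasing intensity edges

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


def _bounding_box(mask: np.ndarray) -> tuple[slice, ...]:
    coords = np.nonzero(mask)
    return tuple(slice(int(c.min()), int(c.max()) + 1) for c in coords)


def quantize_roi(volume: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> QuantizedROI:
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")

    bbox = _bounding_box(mask)
    vol = volume[bbox]
    msk = mask[bbox]
    vals = vol[msk]
    lo, hi = float(vals.min()), float(vals.max())

    levels = np.zeros(vol.shape, dtype=np.int32)
    if hi == lo:
        # degenerate constant ROI: everything is level 1
        levels[msk] = 1
        edges = np.array([lo, lo + 1.0])
    else:
        edges = np.linspace(lo, hi, n_levels + 1)
        lv = np.floor((vol[msk] - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
        levels[msk] = np.clip(lv, 1, n_levels)
    return QuantizedROI(levels=levels, n_levels=n_levels, bin_edges=edges)
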