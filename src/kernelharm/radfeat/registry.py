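"""Feature registry, extraction driver and feature tables.

The default registry ("dev89") holds 89 named features spanning the 11
families, divided into 23 groups used for grouped reproducibility
summaries.  The group mapping is a plain dict and can be edited or replaced
by the caller; every registered feature belongs to exactly one family and
one group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantize import quantize_roi
from .texture import glcm_features, glrlm_features, glszm_features, ngtdm_features
from .intensity import intensity_features, edge_freq_features
from .shape import shape_features, sigmoid_slope_features
from .filters import log_features, laws_features, wavelet_features

__all__ = [
    "FeatureDefinition",
    "ExtractorConfig",
    "FeatureVector",
    "FeatureTable",
    "REGISTRY",
    "FAMILIES",
    "feature_names",
    "feature_groups",
    "extract_all",
    "extract_table",
]

EXTRACTOR_VERSION = "kernelharm-radfeat-1"


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    family: str
    group: int  # 1..23, heatmap grouping


def _build_registry() -> list[FeatureDefinition]:
    defs: list[FeatureDefinition] = []

    def add(names, family, group):
        for n in names:
            defs.append(FeatureDefinition(n, family, group))

    add(["Shape_Volume_mm3", "Shape_EquivSphereDiameter_mm"], "shape", 1)
    add(["Shape_SurfaceArea_mm2", "Shape_SurfaceToVolume"], "shape", 2)
    add(["Shape_Compactness", "Shape_Sphericity", "Shape_MaxDiameter3D_mm",
         "Shape_Extent"], "shape", 3)
    add(["Intensity_Mean", "Intensity_Median", "Intensity_Min", "Intensity_Max"],
        "intensity", 4)
    add(["Intensity_SD", "Intensity_Variance", "Intensity_Range", "Intensity_IQR",
         "Intensity_CV"], "intensity", 5)
    add(["Intensity_P10", "Intensity_P25", "Intensity_P90", "Intensity_Energy"],
        "intensity", 6)
    add(["Intensity_Entropy", "Intensity_Uniformity", "Intensity_Skewness_2D",
         "Intensity_Skewness_3D", "Intensity_Kurtosis"], "intensity", 7)
    add(["GLCM_Entropy", "GLCM_Diff_Entropy", "GLCM_Sum_Entropy"], "GLCM", 8)
    add(["GLCM_Contrast", "GLCM_Dissimilarity", "GLCM_Homogeneity"], "GLCM", 9)
    add(["GLCM_Energy", "GLCM_Correlation", "GLCM_Max_Probability",
         "GLCM_Sum_Average"], "GLCM", 10)
    add(["GLCM_Cluster_Shade", "GLCM_Cluster_Prominence"], "GLCM", 11)
    add(["Run_SPE", "Run_LRE", "Run_LGRE", "Run_HGRE"], "GLRLM", 12)
    add(["Run_PP", "Run_GLN", "Run_RLN"], "GLRLM", 13)
    add(["Zone_SAE", "Zone_LAE", "Zone_LGZE", "Zone_HGZE"], "GLSZM", 14)
    add(["Zone_ZP", "Zone_GLN", "Zone_ZSN"], "GLSZM", 15)
    add(["NGTDM_Coarseness", "NGTDM_Contrast", "NGTDM_Busyness",
         "NGTDM_Complexity", "NGTDM_Strength"], "NGTDM", 16)
    add(["LoG_Entropy_p1", "LoG_Mean_p1", "LoG_SD_p1", "LoG_Uniformity_p1"],
        "LoG", 17)
    add(["LoG_Entropy_p2", "LoG_Mean_p2", "LoG_SD_p2", "LoG_Uniformity_p2"],
        "LoG", 18)
    add(["EdgeFreq_Mean", "EdgeFreq_SD", "EdgeFreq_P90", "EdgeFreq_Max"],
        "edge", 19)
    add(["Sigmoid_Slope", "Sigmoid_Amplitude"], "sharpness", 20)
    add(["Laws_L5L5L5", "Laws_E5L5L5", "Laws_L5L5S5"], "Laws", 21)
    add(["Laws_E5E5L5", "Laws_E5L5S5", "Laws_L5S5S5", "Laws_E5E5E5",
         "Laws_E5E5S5", "Laws_E5S5S5", "Laws_S5S5S5"], "Laws", 22)
    add([f"Wavelet_{b}" for b in
         ("AAA", "AAD", "ADA", "ADD", "DAA", "DAD", "DDA", "DDD")], "wavelet", 23)
    return defs


#: Default ("dev89") registry: 89 features, 11 families, 23 groups.
REGISTRY: list[FeatureDefinition] = _build_registry()
FAMILIES = tuple(sorted({d.family for d in REGISTRY}))

assert len(REGISTRY) == 89
assert len({d.name for d in REGISTRY}) == 89
assert len({d.group for d in REGISTRY}) == 23


def feature_names(registry=None) -> list[str]:
    return [d.name for d in (registry or REGISTRY)]


def feature_groups(registry=None) -> dict[str, int]:
    """name -> group id mapping (user-editable grouping config)."""
    return {d.name: d.group for d in (registry or REGISTRY)}


@dataclass(frozen=True)
class ExtractorConfig:
    n_levels: int = 32  # equal-width quantization bins
    log_sigmas: tuple[float, ...] = (1.5, 2.5)  # voxels
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class FeatureVector:
    values: dict  # feature name -> value (finite; flagged names keep a value)
    undefined: set  # names whose value is a placeholder, not a measurement
    provenance: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        """Values with undefined features masked to NaN."""
        s = pd.Series(self.values, dtype=float)
        for name in self.undefined:
            if name in s.index:
                s[name] = np.nan
        return s


def extract_all(
    volume: np.ndarray,
    mask: np.ndarray,
    config: ExtractorConfig | None = None,
    image_id: str = "",
    setting: str = "",
) -> FeatureVector:
    """Run every registered feature on one (volume, mask) pair.

    Per-feature undefined flags propagate without aborting the vector;
    identical input yields an identical vector.
    """
    config = config or ExtractorConfig()
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must be aligned")

    values: dict[str, float] = {}
    undefined: set[str] = set()

    def run(fn, *args, **kw):
        v, u = fn(*args, **kw)
        values.update(v)
        undefined.update(u)

    q = quantize_roi(volume, mask, config.n_levels)
    run(glcm_features, q)
    run(glrlm_features, q)
    run(glszm_features, q)
    run(ngtdm_features, q)
    run(intensity_features, volume, mask)
    run(edge_freq_features, volume, mask, config.spacing)
    run(shape_features, mask, config.spacing)
    run(sigmoid_slope_features, volume, mask)
    run(log_features, volume, mask, config.log_sigmas)
    run(laws_features, volume, mask)
    run(wavelet_features, volume, mask)

    registered = set(feature_names())
    missing = registered - set(values)
    if missing:
        raise RuntimeError(f"extractor did not produce registered features: {missing}")
    values = {d.name: values[d.name] for d in REGISTRY}  # registry order
    undefined &= registered
    return FeatureVector(
        values=values,
        undefined=undefined,
        provenance={
            "image_id": image_id,
            "setting": setting,
            "extractor_version": EXTRACTOR_VERSION,
            "n_levels": config.n_levels,
            "log_sigmas": list(config.log_sigmas),
        },
    )


@dataclass
class FeatureTable:
    """Patients x features for one kernel setting; undefined cells are NaN."""

    data: pd.DataFrame  # index: patient id; columns: feature names
    setting: str = ""

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient ids")

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, setting: str = "") -> "FeatureTable":
        df = pd.read_csv(path, index_col="id")
        return cls(data=df, setting=setting)


def extract_table(
    volumes: dict,
    masks: dict,
    config: ExtractorConfig | None = None,
    setting: str = "",
) -> FeatureTable:
    """Extract features for many patients: id -> volume, id -> mask."""
    rows = {}
    for pid, vol in volumes.items():
        fv = extract_all(vol, masks[pid], config, image_id=pid, setting=setting)
        rows[pid] = fv.as_series()
    df = pd.DataFrame(rows).T
    df.index.name = "id"
    return FeatureTable(data=df, setting=setting)
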