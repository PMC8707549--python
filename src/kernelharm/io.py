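"""Volume and table I/O: NIfTI round-trips, feature CSVs, optional DICOM."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .radfeat import FeatureTable

__all__ = ["read_volume", "write_volume", "read_feature_table",
           "write_feature_table", "read_dicom_series"]


def read_volume(path: str | Path):
    """Read a NIfTI volume; returns (values float32-exact, spacing mm)."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot read volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_volume(volume: np.ndarray, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a volume as float32 NIfTI with a diagonal spacing affine."""
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_feature_table(path: str | Path, setting: str = "") -> FeatureTable:
    """Read a features CSV; missing cells become NaN (undefined), not zero."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    return FeatureTable.from_csv(path, setting=setting)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_csv(path)


def read_dicom_series(directory: str | Path):
    """Assemble a DICOM series into a volume ordered by slice position.

    Slices are sorted by the z component of ImagePositionPatient, falling
    back to InstanceNumber.  Returns (volume with axial slices along the
    last axis, spacing).
    """
    import pydicom

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f), force=True)
        pos = getattr(ds, "ImagePositionPatient", None)
        z = float(pos[2]) if pos is not None else float(
            getattr(ds, "InstanceNumber", len(slices))
        )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append((z, ds.pixel_array.astype(np.float64) * slope + intercept))
    slices.sort(key=lambda t: t[0])
    vol = np.stack([s for _, s in slices], axis=2)
    ds0 = pydicom.dcmread(str(files[0]), force=True)
    px = getattr(ds0, "PixelSpacing", [1.0, 1.0])
    zs = [z for z, _ in slices]
    dz = float(np.median(np.diff(zs))) if len(zs) > 1 else float(
        getattr(ds0, "SliceThickness", 1.0)
    )
    return vol, (float(px[0]), float(px[1]), abs(dz))
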