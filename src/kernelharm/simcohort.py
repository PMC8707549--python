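"""Synthetic paired-kernel CT cohorts.

Generates phantom chest-CT-like volumes, each containing one spherical
lesion with a correlated random texture, and renders every phantom twice:
once under a "smooth" reconstruction kernel (low-pass frequency response,
low noise) and once under a "sharp" kernel (high-frequency boost, high
noise).  A binary label (mutant-like vs wildtype-like) modulates the
lesion's texture statistics so that texture features carry discriminative
signal, which is what the downstream mixed-kernel AUC analysis measures.

The kernel model is deliberately minimal: a radially symmetric frequency
response applied slice-wise in 2D Fourier space, plus additive Gaussian
noise.  It reproduces the two properties that matter for harmonization
studies — sharp kernels boost resolution and noise together — without
simulating projections or scanner-specific MTF curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "KernelProfile",
    "PhantomSpec",
    "GroundTruthVolume",
    "LesionMask",
    "PatientRecord",
    "Cohort",
    "generate_phantom",
    "apply_kernel",
    "generate_cohort",
    "write_cohort",
    "SMOOTH_KERNEL",
    "SHARP_KERNEL",
]


@dataclass(frozen=True)
class KernelProfile:
    """Frequency response + noise level of one reconstruction kernel.

    The response is ``R(f) = 1 + mtf_gain * s(f / mtf_cutoff)`` where ``s``
    is a smoothstep ramp rising from 0 at zero frequency and saturating at 1
    above the cutoff, so DC is always preserved.  ``mtf_gain`` < 0 attenuates
    high frequencies (smooth kernel), > 0 boosts them (sharp kernel).
    ``noise_sigma`` is the standard deviation of additive zero-mean Gaussian
    noise in intensity (HU-like) units.
    """

    name: str
    mtf_gain: float
    mtf_cutoff: float  # cycles/voxel, in (0, 0.5]
    noise_sigma: float

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 < self.mtf_cutoff <= 0.5):
            raise ValueError("mtf_cutoff must be in (0, 0.5] cycles/voxel")

    def response(self, freq: np.ndarray) -> np.ndarray:
        """Radial frequency response R(f); R(0) = 1 exactly."""
        u = np.clip(np.abs(freq) / self.mtf_cutoff, 0.0, 1.0)
        ramp = u * u * (3.0 - 2.0 * u)  # smoothstep, saturates at 1
        return 1.0 + self.mtf_gain * ramp


#: Default study kernels: the smooth kernel suppresses high frequencies and
#: carries little noise; the sharp kernel boosts them and is much noisier.
SMOOTH_KERNEL = KernelProfile("smooth", mtf_gain=-0.7, mtf_cutoff=0.20, noise_sigma=5.0)
SHARP_KERNEL = KernelProfile("sharp", mtf_gain=1.0, mtf_cutoff=0.25, noise_sigma=40.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of one synthetic patient phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    background_level: float = -800.0  # lung parenchyma, HU-like
    lesion_center: tuple[float, float, float] | None = None  # default: grid center
    lesion_radius: float = 6.0  # voxels
    texture_correlation_length: float = 1.5  # voxels
    texture_contrast: float = 80.0  # intensity units (sd of lesion texture)
    lesion_level: float = 0.0  # mean lesion intensity, HU-like
    label_effect: float = 1.5  # multiplies texture params when label == 1
    lesion_radius_jitter: float = 0.2  # per-phantom relative radius variation
    lesion_center_jitter: float = 1.0  # per-phantom center displacement, voxels

    def center(self) -> np.ndarray:
        if self.lesion_center is not None:
            return np.asarray(self.lesion_center, dtype=float)
        return (np.asarray(self.grid_shape, dtype=float) - 1.0) / 2.0

    def validate(self) -> None:
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be >= 0")
        if self.label_effect <= 0:
            raise ValueError("label_effect must be > 0")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be > 0")
        c = self.center()
        shape = np.asarray(self.grid_shape, dtype=float)
        if np.any(c - self.lesion_radius < 2.0) or np.any(
            c + self.lesion_radius > shape - 1.0 - 2.0
        ):
            raise ValueError("lesion must fit inside the grid with a >=2-voxel margin")


@dataclass
class GroundTruthVolume:
    values: np.ndarray  # 3D, HU-like
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ground-truth volume must be finite")


@dataclass
class LesionMask:
    values: np.ndarray  # 3D boolean
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if int(self.values.sum()) < 27:
            raise ValueError("lesion mask needs at least 27 foreground voxels")


@dataclass
class PatientRecord:
    id: str
    truth: GroundTruthVolume
    smooth_image: np.ndarray
    sharp_image: np.ndarray
    mask: LesionMask
    label: int


@dataclass
class Cohort:
    records: list[PatientRecord]
    generation_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def __len__(self) -> int:
        return len(self.records)


def _correlated_noise(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary correlated field: Gaussian-smoothed white noise, unit sd."""
    white = rng.standard_normal(shape)
    if corr_len > 0:
        smooth = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        return smooth
    return white


def generate_phantom(
    spec: PhantomSpec, label: int, seed: int
) -> tuple[GroundTruthVolume, LesionMask]:
    """Build one noise-free ground-truth phantom and its lesion mask.

    The lesion interior carries a stationary correlated texture (smoothed
    white noise with the spec's correlation length, scaled to
    ``texture_contrast``).  For label-1 phantoms both the contrast and the
    correlation length are multiplied by ``label_effect``, shifting the
    distribution of intensity and texture features between classes.

    Lesion geometry varies per phantom (radius and center jitter drawn from
    the seed), emulating anatomical variability; the drawn geometry is
    clamped so the lesion always keeps a 2-voxel margin inside the grid.
    """
    spec.validate()
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(seed)

    shape = tuple(spec.grid_shape)
    idx = np.indices(shape, dtype=float)
    c = spec.center().copy()
    radius = spec.lesion_radius
    if spec.lesion_center_jitter > 0:
        c = c + rng.uniform(-spec.lesion_center_jitter, spec.lesion_center_jitter, 3)
    if spec.lesion_radius_jitter > 0:
        radius = radius * (1.0 + rng.uniform(-spec.lesion_radius_jitter,
                                             spec.lesion_radius_jitter))
    # clamp so the (jittered) lesion keeps its margin; never below 2 voxels
    room = min(min(c[k] - 2.0, shape[k] - 3.0 - c[k]) for k in range(3))
    radius = float(np.clip(radius, 2.0, room))
    dist = np.sqrt(sum((idx[k] - c[k]) ** 2 for k in range(3)))
    mask = dist <= radius

    contrast = spec.texture_contrast
    corr = spec.texture_correlation_length
    if label == 1:
        contrast = contrast * spec.label_effect
        corr = corr * spec.label_effect

    vol = np.full(shape, spec.background_level, dtype=np.float64)
    texture = _correlated_noise(shape, corr, rng) * contrast
    vol[mask] = spec.lesion_level + texture[mask]

    return (
        GroundTruthVolume(vol, spec.voxel_spacing),
        LesionMask(mask, spec.voxel_spacing),
    )


def apply_kernel(truth: GroundTruthVolume, kernel: KernelProfile, seed: int) -> np.ndarray:
    """Render a ground-truth volume under one reconstruction kernel.

    Slice-wise 2D processing, matching CT reconstruction: each axial slice
    is Fourier transformed, multiplied by the kernel's radial response, and
    inverse transformed; zero-mean Gaussian noise is then added.
    """
    vol = np.asarray(truth.values, dtype=np.float64)
    if not np.all(np.isfinite(vol)):
        raise ValueError("input volume must be finite")
    ny, nx = vol.shape[0], vol.shape[1]
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    freq = np.sqrt(fy**2 + fx**2)
    resp = kernel.response(freq)

    out = np.empty_like(vol)
    for z in range(vol.shape[2]):
        spec2 = np.fft.fft2(vol[:, :, z])
        out[:, :, z] = np.fft.ifft2(spec2 * resp).real
    if kernel.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, kernel.noise_sigma, size=out.shape)
    return out


def _record_seed(master_seed: int, index: int, stream: int = 0) -> int:
    """Deterministic per-record seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n: int,
    prevalence: float,
    spec: PhantomSpec | None = None,
    smooth: KernelProfile = SMOOTH_KERNEL,
    sharp: KernelProfile = SHARP_KERNEL,
    seed: int = 0,
    id_prefix: str = "P",
) -> Cohort:
    """Generate ``n`` labeled patients with paired smooth/sharp renderings.

    Exactly ``round(n * prevalence)`` records are positive; the label order
    is a seed-deterministic permutation.  Per-record phantom and noise seeds
    are derived from the master seed so regeneration is bit-identical.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    spec = spec or PhantomSpec()
    spec.validate()

    n_pos = int(round(n * prevalence))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng = np.random.default_rng(_record_seed(seed, 0, stream=9))
    labels = labels[rng.permutation(n)]

    records: list[PatientRecord] = []
    for i in range(n):
        truth, mask = generate_phantom(spec, int(labels[i]), _record_seed(seed, i, 0))
        smo = apply_kernel(truth, smooth, _record_seed(seed, i, 1))
        shp = apply_kernel(truth, sharp, _record_seed(seed, i, 2))
        records.append(
            PatientRecord(
                id=f"{id_prefix}{i:04d}",
                truth=truth,
                smooth_image=smo,
                sharp_image=shp,
                mask=mask,
                label=int(labels[i]),
            )
        )
    params = {
        "n": n,
        "prevalence": prevalence,
        "spec": asdict(spec),
        "smooth": asdict(smooth),
        "sharp": asdict(sharp),
        "seed": seed,
    }
    return Cohort(records, params)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as NIfTI volumes plus a manifest CSV and JSON sidecar.

    One file per record per rendering (smooth, sharp, truth) and one mask
    file; the manifest lists id, label and file paths.
    """
    import nibabel as nib
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        affine = np.diag(list(rec.truth.spacing) + [1.0])
        paths = {}
        for tag, arr in (
            ("truth", rec.truth.values),
            ("smooth", rec.smooth_image),
            ("sharp", rec.sharp_image),
            ("mask", rec.mask.values.astype(np.uint8)),
        ):
            p = out_dir / f"{rec.id}_{tag}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), p)
            paths[tag] = p.name
        rows.append({"id": rec.id, "label": rec.label, **paths})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out_dir / "generation_params.json", "w") as fh:
        json.dump(cohort.generation_params, fh, indent=2, sort_keys=True)
    return manifest
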