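"""Broadband power per cortical parcel and the three oscillatory-activity scores.

The front end of the pipeline: source-space signals for 78 cortical atlas
regions are reduced to broadband (0.5-48 Hz) band-integrated power, and the
tumor mask — drawn on the same voxel grid as the atlas — is dilated twice so
that parcels overlapping the dilated mask define the peritumor set.  Three
per-patient scores follow: peritumor (mean power over the peritumor parcels),
global (mean over all parcels) and non-tumor (mean over the remaining
parcels), each z-scored across the patient cohort before any statistics.

All volumes are voxel-indexed on one shared grid; registration of atlas and
mask onto individual anatomy is upstream and out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage, signal

__all__ = [
    "LabeledVolume",
    "MaskVolume",
    "RegionPowerVector",
    "ObaMeasures",
    "band_power",
    "dilate_mask",
    "peritumor_regions",
    "compute_oba",
    "zscore_cohort",
    "zscore_reference",
]


@dataclass(frozen=True)
class LabeledVolume:
    """3D integer atlas grid: 0 background, 1..n_regions parcel labels."""

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 3D grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_regions + 1)[1:]

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabeledVolume":
        img = nib.load(str(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj).astype(int), vox)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))


@dataclass(frozen=True)
class MaskVolume:
    """Binary tumor mask on the same voxel grid as its atlas."""

    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask.any():
            raise ValueError("mask has no foreground voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_nifti(cls, path: str | Path) -> "MaskVolume":
        img = nib.load(str(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj) > 0, vox)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(path))


@dataclass(frozen=True)
class RegionPowerVector:
    """Per-region broadband absolute power for one patient (consistent arbitrary units)."""

    patient_id: str
    power: np.ndarray
    band_hz: tuple[float, float] = (0.5, 48.0)
    sampling_rate_hz: float = 1250.0

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("power must be finite and nonnegative")
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class ObaMeasures:
    """Peritumor / global / non-tumor activity for one patient.

    Raw values are arithmetic means of region powers, so the exact identity
    R * global = |peri| * peritumor + (R - |peri|) * nontumor holds.  The
    z-fields are filled in after cohort-level normalization.
    """

    patient_id: str
    peritumor_raw: float
    global_raw: float
    nontumor_raw: float
    peritumor_region_ids: frozenset[int]
    peritumor_z: float = field(default=np.nan)
    global_z: float = field(default=np.nan)
    nontumor_z: float = field(default=np.nan)
    global_z_ref: float = field(default=np.nan)


def band_power(
    signal_array,
    sampling_rate_hz: float,
    band_hz: tuple[float, float] = (0.5, 48.0),
    segment_s: float = 4.0,
) -> float:
    """Band-integrated power of a signal via Welch's PSD estimate.

    Hann-windowed segments of ``segment_s`` seconds with 50% overlap; the PSD
    is integrated over ``band_hz`` by the trapezoid rule, so the result is in
    squared signal units (a variance share, by Parseval).
    """
    x = np.asarray(signal_array, dtype=float)
    lo, hi = band_hz
    if not 0.0 <= lo < hi:
        raise ValueError(f"invalid band {band_hz}")
    if hi > sampling_rate_hz / 2.0:
        raise ValueError(f"band edge {hi} Hz above Nyquist {sampling_rate_hz / 2.0} Hz")
    nperseg = int(round(segment_s * sampling_rate_hz))
    if x.size < nperseg:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {segment_s}-s PSD window"
        )
    freqs, psd = signal.welch(
        x, fs=sampling_rate_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[sel], freqs[sel]))


def dilate_mask(mask: MaskVolume, iterations: int = 2) -> MaskVolume:
    """Binary dilation with the 3x3x3 box structuring element, applied repeatedly.

    Two iterations of the box kernel define the peritumor neighborhood used
    throughout; the output always contains the input.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    structure = np.ones((3, 3, 3), dtype=bool)
    dil = ndimage.binary_dilation(mask.mask, structure=structure, iterations=iterations)
    return MaskVolume(dil, mask.voxel_size_mm)


def peritumor_regions(
    atlas: LabeledVolume,
    dilated: MaskVolume,
    min_overlap_voxels: int = 1,
    core: MaskVolume | None = None,
) -> frozenset[int]:
    """Atlas regions overlapping the dilated tumor mask.

    A region counts as peritumor when at least ``min_overlap_voxels`` of its
    voxels lie inside the mask (default 1: any overlap).  By default regions
    fully inside the tumor core are included — the peritumor set covers the
    tumor and its surround.  Passing the undilated ``core`` mask switches to
    the stricter reading that drops regions lying entirely within the core.
    """
    if atlas.labels.shape != dilated.mask.shape:
        raise ValueError(
            f"shape mismatch: atlas {atlas.labels.shape} vs mask {dilated.mask.shape}"
        )
    inside = atlas.labels[dilated.mask]
    counts = np.bincount(inside[inside > 0], minlength=atlas.n_regions + 1)
    hit = frozenset(int(r) for r in np.flatnonzero(counts >= min_overlap_voxels) if r > 0)
    if core is not None:
        if core.mask.shape != atlas.labels.shape:
            raise ValueError("core mask shape does not match the atlas")
        hit = frozenset(
            r for r in hit if (np.asarray(atlas.labels == r) & ~core.mask).any()
        )
    if not hit:
        warnings.warn("dilated tumor mask overlaps no atlas region", stacklevel=2)
    return hit


def compute_oba(power: RegionPowerVector, peri: frozenset[int] | set[int]) -> ObaMeasures:
    """Raw peritumor / global / non-tumor means from one patient's region powers."""
    r = len(power.power)
    peri = frozenset(int(i) for i in peri)
    if not peri:
        raise ValueError("tumor mask overlaps no atlas region: peritumor set is empty")
    if not peri <= set(range(1, r + 1)):
        raise ValueError(f"peritumor region ids {sorted(peri)} outside 1..{r}")
    idx = np.array(sorted(peri)) - 1
    in_peri = np.zeros(r, dtype=bool)
    in_peri[idx] = True
    peritumor = float(power.power[in_peri].mean())
    global_ = float(power.power.mean())
    nontumor = float(power.power[~in_peri].mean()) if (~in_peri).any() else peritumor
    return ObaMeasures(power.patient_id, peritumor, global_, nontumor, peri)


def zscore_cohort(values) -> np.ndarray:
    """Z-scores against the sample's own mean and SD (divisor n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance: z-scores undefined")
    return (v - v.mean()) / sd


def zscore_reference(values, ref_mean: float, ref_sd: float) -> np.ndarray:
    """Z-scores against an external reference cohort (e.g. healthy controls)."""
    if ref_sd <= 0.0:
        raise ValueError("reference SD must be positive")
    return (np.asarray(values, dtype=float) - ref_mean) / ref_sd
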