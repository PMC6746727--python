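"""K-edge subtraction and inverse K-edge subtraction of paired CT scans.

The iodine (KES) image is the plain slicewise difference

    KES = mu_unfiltered - mu_filtered ,

which cancels every material whose attenuation varies smoothly across the
iodine K edge (tissue, water, calcium) and keeps the contrast agent, whose
attenuation jumps at the edge.  The calcium (inverse KES) image scales the
filtered scan by the cubic energy-correction coefficient

    c = (E_unfiltered / E_filtered)**3

before subtracting the unfiltered scan: the photoelectric cross section of
edge-free materials falls ~E^-3, so c compensates the mean-energy difference
of the two scans and makes calcium-bearing structures stand out while the
iodine signal inverts.  The mean energies enter from the scans' spectral
metadata (single source of truth), and the ratio direction is configurable
(the convention here scales the filtered scan up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .recon import ReconSlice

__all__ = [
    "KESVolume",
    "ROIStats",
    "energy_correction_coefficient",
    "kes_subtract",
    "inverse_kes",
    "roi_stats",
    "threshold_segment",
]


@dataclass(frozen=True)
class KESVolume:
    """Signed mu-difference volume (1/mm)."""

    values: np.ndarray
    kind: str  # "kes_iodine" | "inverse_kes_calcium"
    correction_coefficient: float
    voxel_size_mm: float

    def __post_init__(self) -> None:
        if self.kind not in ("kes_iodine", "inverse_kes_calcium"):
            raise ValidationError(f"unknown KES kind {self.kind!r}")
        if self.kind == "kes_iodine" and self.correction_coefficient != 1.0:
            raise ValidationError("plain KES has correction coefficient 1")


@dataclass(frozen=True)
class ROIStats:
    region_label: str
    mean: float
    std: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValidationError("ROI must contain at least one voxel")


def _check_pair(unfiltered: ReconSlice, filtered: ReconSlice) -> None:
    if unfiltered.values.shape != filtered.values.shape:
        raise ValidationError("scan grids differ")
    if not np.isclose(unfiltered.voxel_size_mm, filtered.voxel_size_mm):
        raise ValidationError("scan voxel sizes differ")


def energy_correction_coefficient(mean_energy_unfiltered_kev: float,
                                  mean_energy_filtered_kev: float,
                                  ratio_order: str = "unfiltered_over_filtered"
                                  ) -> float:
    """Cubic ratio of the scans' mean energies, c = (E_unf/E_filt)**3
    (or the inverse order if requested)."""
    if mean_energy_unfiltered_kev <= 0 or mean_energy_filtered_kev <= 0:
        raise ValidationError("mean energies must be positive")
    r = mean_energy_unfiltered_kev / mean_energy_filtered_kev
    if ratio_order == "filtered_over_unfiltered":
        r = 1.0 / r
    elif ratio_order != "unfiltered_over_filtered":
        raise ValidationError(f"unknown ratio_order {ratio_order!r}")
    return float(r**3)


def kes_subtract(unfiltered: ReconSlice, filtered: ReconSlice) -> KESVolume:
    """Iodine image: unfiltered minus filtered, no scaling, signed output."""
    _check_pair(unfiltered, filtered)
    return KESVolume(values=unfiltered.values - filtered.values,
                     kind="kes_iodine", correction_coefficient=1.0,
                     voxel_size_mm=unfiltered.voxel_size_mm)


def inverse_kes(unfiltered: ReconSlice, filtered: ReconSlice,
                ratio_order: str = "unfiltered_over_filtered") -> KESVolume:
    """Calcium image: c * filtered - unfiltered with the cubic energy
    correction c computed from the scans' mean-energy metadata."""
    _check_pair(unfiltered, filtered)
    for r in (unfiltered, filtered):
        if r.mean_energy_kev is None or not np.isfinite(r.mean_energy_kev):
            raise ValidationError(f"scan {r.scan_label!r} lacks mean energy")
    c = energy_correction_coefficient(unfiltered.mean_energy_kev,
                                      filtered.mean_energy_kev, ratio_order)
    return KESVolume(values=c * filtered.values - unfiltered.values,
                     kind="inverse_kes_calcium", correction_coefficient=c,
                     voxel_size_mm=unfiltered.voxel_size_mm)


def roi_stats(values: np.ndarray, mask: np.ndarray,
              region_label: str = "") -> ROIStats:
    """Arithmetic mean and population standard deviation over a mask."""
    m = np.asarray(mask, bool)
    if m.shape != np.asarray(values).shape:
        raise ValidationError("mask and volume grids differ")
    if not m.any():
        raise ValidationError("empty ROI mask")
    v = np.asarray(values)[m]
    return ROIStats(region_label=region_label, mean=float(v.mean()),
                    std=float(v.std()), n_voxels=int(v.size))


def threshold_segment(values: np.ndarray, lo: float, hi: float,
                      min_size: int = 16) -> np.ndarray:
    """Histogram-band segmentation: voxels with lo <= value <= hi, keeping
    connected components of at least ``min_size`` voxels."""
    if lo >= hi:
        raise ValidationError("need lo < hi")
    band = (np.asarray(values) >= lo) & (np.asarray(values) <= hi)
    labels, n = ndimage.label(band)
    if n == 0:
        return np.zeros_like(band)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_size)
    keep = keep[keep > 0]
    return np.isin(labels, keep)
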