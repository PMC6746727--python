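"""Tomographic reconstruction of mu maps from transmission sinograms.

Filtered backprojection (ramp or apodized filter) is the default engine; a
simple simultaneous-iterative (SIRT-type) least-squares solver is provided as
a stand-in for statistical iterative methods, with agreement asserted at
ROI level only.  Transmissions are floored before the logarithm (Poisson
zeros at low dose), and a circular field-of-view mask is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import iradon, radon

from .errors import ConvergenceError, ValidationError
from .forward import Sinogram, _fov_mask

__all__ = ["ReconSlice", "fbp", "sirt", "roi_mean"]


@dataclass(frozen=True)
class ReconSlice:
    """Reconstructed linear attenuation (1/mm) on the acquisition grid."""

    values: np.ndarray
    voxel_size_mm: float
    scan_label: str
    mean_energy_kev: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(~np.isfinite(v)):
            raise ValidationError("reconstruction contains non-finite values")

    def write(self, path_tiff) -> None:
        path = Path(path_tiff)
        tifffile.imwrite(path, self.values.astype(np.float32))
        pd.DataFrame({
            "key": ["scan_label", "mean_energy_kev", "voxel_size_mm"],
            "value": [self.scan_label, self.mean_energy_kev,
                      self.voxel_size_mm],
        }).to_csv(path.with_suffix(".csv"), index=False)

    @classmethod
    def read(cls, path_tiff) -> "ReconSlice":
        path = Path(path_tiff)
        meta = dict(pd.read_csv(path.with_suffix(".csv"),
                                dtype=str).itertuples(index=False, name=None))
        return cls(values=tifffile.imread(path),
                   voxel_size_mm=float(meta["voxel_size_mm"]),
                   scan_label=meta["scan_label"],
                   mean_energy_kev=float(meta["mean_energy_kev"]))


def _neg_log(sinogram: Sinogram, floor: float) -> np.ndarray:
    if floor <= 0:
        raise ValidationError("transmission floor must be positive")
    t = sinogram.transmission
    bad = ~(t > 0)
    if np.any(bad) and floor <= 0:  # unreachable guard, floor handles zeros
        rows = np.unique(np.argwhere(bad)[:, 0])
        raise ValidationError(f"nonpositive transmission in rays {rows[:20]}")
    return -np.log(np.maximum(t, floor))


def fbp(sinogram: Sinogram, filter_name: str = "ramp",
        floor: float = 1e-6) -> ReconSlice:
    """Parallel-beam filtered backprojection of -log(T), in 1/mm."""
    p = _neg_log(sinogram, floor)
    n = sinogram.geometry.n_detector_bins
    img = iradon(p.T, theta=sinogram.geometry.angles_deg,
                 filter_name=filter_name, circle=True, output_size=n)
    img = np.where(_fov_mask(n), img, 0.0) / sinogram.voxel_size_mm
    return ReconSlice(values=img, voxel_size_mm=sinogram.voxel_size_mm,
                      scan_label=sinogram.scan_label,
                      mean_energy_kev=sinogram.mean_energy_kev)


def sirt(sinogram: Sinogram, n_iter: int = 100, nonneg: bool = False,
         floor: float = 1e-6) -> ReconSlice:
    """SIRT least-squares reconstruction.

    x <- x + C * A^T(R * (b - A x)) with row/column normalizers
    R = 1/A(1), C = 1/A^T(1); the first iterate from a zero start is a single
    weighted backprojection.  Raises if the residual norm grows on two
    consecutive iterations.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    b = _neg_log(sinogram, floor)  # units mu * voxel after /voxel at the end
    geo = sinogram.geometry
    n = geo.n_detector_bins
    fov = _fov_mask(n).astype(float)

    def fwd(x: np.ndarray) -> np.ndarray:
        return radon(x * fov, theta=geo.angles_deg, circle=True).T

    def adj(p: np.ndarray) -> np.ndarray:
        return iradon(p.T, theta=geo.angles_deg, filter_name=None,
                      circle=True, output_size=n) * fov

    row_sum = fwd(fov)
    col_sum = adj(np.ones_like(b))
    r_w = np.where(row_sum > 1e-9, 1.0 / np.maximum(row_sum, 1e-9), 0.0)
    c_w = np.where(col_sum > 1e-9, 1.0 / np.maximum(col_sum, 1e-9), 0.0)

    x = np.zeros((n, n))
    prev, grew = np.inf, 0
    for _ in range(n_iter):
        resid = b - fwd(x)
        x = x + c_w * adj(r_w * resid)
        if nonneg:
            x = np.maximum(x, 0.0)
        norm = float(np.linalg.norm(resid))
        if norm > prev * (1 + 1e-12):
            grew += 1
            if grew >= 2:
                raise ConvergenceError(
                    f"residual grew on two consecutive iterations ({norm:g})")
        else:
            grew = 0
        prev = norm
    # b is mu integrated in voxel steps of the projector's pixel units
    img = x / sinogram.voxel_size_mm
    return ReconSlice(values=img, voxel_size_mm=sinogram.voxel_size_mm,
                      scan_label=sinogram.scan_label,
                      mean_energy_kev=sinogram.mean_energy_kev)


def roi_mean(recon: ReconSlice, mask: np.ndarray, erode_px: int = 0) -> float:
    """Mean reconstructed mu over a mask, optionally eroded to exclude
    partial-volume rims."""
    m = np.asarray(mask, bool)
    if erode_px > 0:
        from scipy.ndimage import binary_erosion
        m = binary_erosion(m, iterations=erode_px)
    if not m.any():
        raise ValidationError("empty ROI after erosion")
    return float(recon.values[m].mean())
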