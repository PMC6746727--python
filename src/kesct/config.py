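"""Single-config description of the full experiment.

The default configuration reproduces the imaging protocol: peak energy
33.69 keV (unfiltered mean 33.18 keV), 290 um effective solid-iodine filter,
1000 equally-spaced projections over 360 degrees at 44 ms each, 512x512
slices at 70 um effective pixels, flux 1.3e10 photons/s.  A ``desk-test``
profile shrinks the grid and view count for sub-minute runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field

import yaml

from .dose import DEFAULT_KERMA_TO_EFFECTIVE_SV_PER_GY
from .errors import ValidationError
from .phantom import KidneyPhantomConfig
from .spectrum import DEFAULT_FILTER_THICKNESS_UM, SourceConfig

__all__ = ["ExperimentConfig", "validate_config"]


@dataclass(frozen=True)
class ExperimentConfig:
    source: SourceConfig = field(default_factory=SourceConfig)
    phantom: KidneyPhantomConfig = field(default_factory=KidneyPhantomConfig)
    filter_thickness_um: float = DEFAULT_FILTER_THICKNESS_UM
    n_angles: int = 1000
    angular_span_deg: float = 360.0
    exposure_ms: float = 44.0
    noise: bool = True
    acquisition_mode: str = "mono"        # "mono" | "poly"
    detector_weighting: str = "energy"    # "energy" | "counting"
    detector_pixel_um: float | None = 74.8  # None: derived from voxel size
    recon_engine: str = "fbp"             # "fbp" | "sirt"
    # Hann-apodized FBP approximates the noise behaviour of the regularized
    # iterative reconstruction the measured ROI spreads come from; plain
    # "ramp" is available but noise-maximal.
    fbp_filter: str = "hann"
    sirt_iterations: int = 60
    kes_ratio_order: str = "unfiltered_over_filtered"
    segmentation_band: tuple[float, float] = (0.19, 0.23)
    segmentation_band_kes: tuple[float, float] = (0.10, 0.30)
    segmentation_min_size: int = 32
    conversion_coefficient_sv_gy: float = DEFAULT_KERMA_TO_EFFECTIVE_SV_PER_GY
    output_dir: str = "kesct_out"
    seed: int = 7

    @property
    def exposure_s(self) -> float:
        return self.exposure_ms / 1000.0

    @property
    def scan_time_s(self) -> float:
        return self.n_angles * self.exposure_s

    @classmethod
    def desk_test(cls, **overrides) -> "ExperimentConfig":
        """Small profile (256^2 grid, 180 views) for quick runs."""
        base = cls(
            phantom=KidneyPhantomConfig(grid_size=256, voxel_size_mm=0.14),
            n_angles=180, detector_pixel_um=None, **overrides)
        return base

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation_band"] = list(self.segmentation_band)
        d["segmentation_band_kes"] = list(self.segmentation_band_kes)
        d["phantom"]["vessel_radius_range_mm"] = \
            list(self.phantom.vessel_radius_range_mm)
        d["phantom"]["kidney_axes_mm"] = list(self.phantom.kidney_axes_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        violations = validate_config(d)
        if violations:
            raise ValidationError("; ".join(violations))
        d = dict(d)
        src = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in d.pop("source", {}).items()}
        ph = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in d.pop("phantom", {}).items()}
        for k in ("segmentation_band", "segmentation_band_kes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(source=SourceConfig(**src),
                   phantom=KidneyPhantomConfig(**ph), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _known_fields(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def validate_config(config: "ExperimentConfig | dict") -> list[str]:
    """Collect invariant violations (empty list == valid).  Violations are
    data, not exceptions, so invalid raw configs can be inspected."""
    d = config.to_dict() if isinstance(config, ExperimentConfig) else dict(config)
    out: list[str] = []

    src = d.get("source", {})
    for k in src:
        if k not in _known_fields(SourceConfig):
            out.append(f"source.{k}: unknown field")
    fwhm = src.get("fwhm_fraction", SourceConfig().fwhm_fraction)
    if not (0 < fwhm <= 0.045):
        out.append(f"source.fwhm_fraction={fwhm}: bandwidth bound is 4.5% FWHM")
    peak = src.get("peak_energy_kev", SourceConfig().peak_energy_kev)
    if not (15.0 <= peak <= 35.0):
        out.append(f"source.peak_energy_kev={peak}: source is tunable in [15, 35] keV")
    flux = src.get("total_flux", SourceConfig().total_flux)
    if flux <= 0:
        out.append("source.total_flux must be positive")

    ph = d.get("phantom", {})
    for k in ph:
        if k not in _known_fields(KidneyPhantomConfig):
            out.append(f"phantom.{k}: unknown field")
    nv = ph.get("n_vessels", KidneyPhantomConfig().n_vessels)
    if not (3 <= nv <= 10):
        out.append(f"phantom.n_vessels={nv}: must lie in [3, 10]")

    def chk(name, pred, msg):
        if name in d and not pred(d[name]):
            out.append(f"{name}={d[name]}: {msg}")

    chk("filter_thickness_um", lambda v: v > 0, "filter thickness must be positive")
    chk("n_angles", lambda v: v >= 1, "need at least one projection")
    chk("exposure_ms", lambda v: v > 0, "exposure must be positive")
    chk("acquisition_mode", lambda v: v in ("mono", "poly"), "unknown mode")
    chk("detector_weighting", lambda v: v in ("energy", "counting"),
        "unknown weighting")
    chk("recon_engine", lambda v: v in ("fbp", "sirt"), "unknown engine")
    chk("sirt_iterations", lambda v: v >= 1, "need at least one iteration")
    chk("kes_ratio_order",
        lambda v: v in ("unfiltered_over_filtered", "filtered_over_unfiltered"),
        "unknown ratio order")
    chk("conversion_coefficient_sv_gy", lambda v: v >= 0, "must be >= 0")
    chk("seed", lambda v: isinstance(v, int) and 0 <= v < 2**31 - 2,
        "seed must be a small non-negative integer")
    for k in ("segmentation_band", "segmentation_band_kes"):
        if k in d and not d[k][0] < d[k][1]:
            out.append(f"{k}={d[k]}: need lo < hi")
    known = _known_fields(ExperimentConfig)
    for k in d:
        if k not in known:
            out.append(f"{k}: unknown field")
    return out
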