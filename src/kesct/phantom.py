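"""Kidney-like voxel phantoms with iodinated vessels and a calcium-oxalate
stone, plus analytic oracle phantoms.

The default phantom is a 2-D slice: a plastic beaker ring holding a water
bath, a soft-tissue ellipse (the kidney), a handful of contrast-agent-filled
vessel discs and one calcium-oxalate stone disc sitting on the kidney
surface.  The two clinically confusable inserts are *calibrated*, not nominal:
the vessel iodine concentration and the stone bulk density are solved so that
their linear attenuation at the unfiltered scan's mean energy (33.18 keV)
equals the measured reference values 0.2184 and 0.2105 1/mm.  Their contrast
is then 0.0079 1/mm by construction - below the noise floor of a default-dose
scan, which is precisely the clinical indistinguishability the subtraction
method resolves.

Primitives are hard-edged (no partial-volume blending), keeping the analytic
projection oracles exact.  Geometry is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError
from .materials import (Material, MaterialRegistry, default_registry,
                        iodinated_water, make_mixture)

__all__ = [
    "Primitive",
    "PhantomSpec",
    "MuMap",
    "KidneyPhantomConfig",
    "kidney_phantom",
    "render_mu_map",
    "label_map",
    "region_masks",
    "disc_phantom",
    "calibrate_vessel_concentration",
    "calibrate_stone_density",
    "vessel_material",
    "stone_material",
    "ground_truth_table",
]

VESSEL_MU_REFERENCE = 0.2184  # 1/mm at 33.18 keV, measured contrast-agent value
STONE_MU_REFERENCE = 0.2105   # 1/mm at 33.18 keV, measured kidney-stone value
CALIBRATION_ENERGY_KEV = 33.18


@dataclass(frozen=True)
class Primitive:
    """A painted shape: 'ellipse' (disc when axes are equal) or 'annulus'.

    ``center_mm`` is (y, x) from the grid centre; ``axes_mm`` are semi-axes
    for an ellipse and (outer, inner) radii for an annulus."""

    shape: str
    center_mm: tuple[float, float]
    axes_mm: tuple[float, float]
    material: Material
    label: str
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "annulus"):
            raise ValidationError(f"unknown primitive shape {self.shape!r}")
        if min(self.axes_mm) <= 0:
            raise ValidationError("primitive axes must be positive")
        if self.shape == "annulus" and self.axes_mm[1] >= self.axes_mm[0]:
            raise ValidationError("annulus inner radius must be < outer radius")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric phantom: ordered primitives painted over an air background
    (painter's order: later primitives overwrite earlier ones)."""

    grid_shape: tuple[int, int]
    voxel_size_mm: float
    primitives: tuple[Primitive, ...]
    background: Material | None = None

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        half = min(self.grid_shape) * self.voxel_size_mm / 2.0
        for p in self.primitives:
            extent = max(p.axes_mm) + float(np.hypot(*p.center_mm))
            if extent > half + 1e-9:
                raise ValidationError(
                    f"primitive {p.label!r} extends outside the grid")

    def coords_mm(self):
        ny, nx = self.grid_shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel_size_mm
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.voxel_size_mm
        return np.meshgrid(y, x, indexing="ij")


@dataclass(frozen=True)
class MuMap:
    """Per-voxel linear attenuation (1/mm) at a stated energy."""

    values: np.ndarray
    energy_kev: float
    voxel_size_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            raise ValidationError("mu map must be finite and >= 0")


def _primitive_mask(p: Primitive, phantom: PhantomSpec) -> np.ndarray:
    yy, xx = phantom.coords_mm()
    cy, cx = p.center_mm
    dy, dx = yy - cy, xx - cx
    if p.rotation_deg:
        th = np.deg2rad(p.rotation_deg)
        dy, dx = (np.cos(th) * dy - np.sin(th) * dx,
                  np.sin(th) * dy + np.cos(th) * dx)
    if p.shape == "ellipse":
        ay, ax = p.axes_mm
        return (dy / ay) ** 2 + (dx / ax) ** 2 <= 1.0
    outer, inner = p.axes_mm
    r2 = dy**2 + dx**2
    return (r2 <= outer**2) & (r2 > inner**2)


def render_mu_map(phantom: PhantomSpec, energy_kev: float) -> MuMap:
    """Rasterize per-voxel mu (1/mm) at one energy; hard edges, painter's
    order."""
    out = np.zeros(phantom.grid_shape, dtype=float)
    if phantom.background is not None:
        out += phantom.background.linear_attenuation(energy_kev)
    for p in phantom.primitives:
        out[_primitive_mask(p, phantom)] = p.material.linear_attenuation(energy_kev)
    return MuMap(values=out, energy_kev=energy_kev,
                 voxel_size_mm=phantom.voxel_size_mm)


def label_map(phantom: PhantomSpec) -> tuple[np.ndarray, dict[str, int]]:
    """Integer region labels in painter's order; 0 is background (air).
    Primitives sharing a label name share an id, so the labels partition the
    grid."""
    ids = {"air": 0}
    out = np.zeros(phantom.grid_shape, dtype=np.int32)
    for p in phantom.primitives:
        if p.label not in ids:
            ids[p.label] = len(ids)
        out[_primitive_mask(p, phantom)] = ids[p.label]
    return out, ids


def region_masks(phantom: PhantomSpec) -> dict[str, np.ndarray]:
    lab, ids = label_map(phantom)
    return {name: lab == i for name, i in ids.items()}


def material_regions(phantom: PhantomSpec) -> list[tuple[Material, np.ndarray]]:
    """Exclusive (material, mask) pairs after painting, for spectral
    projection (one path-length map per material)."""
    lab, _ = label_map(phantom)
    out = []
    seen: dict[str, int] = {}
    # walk primitives in order; labels repeat for vessels
    lab_of = {}
    for p in phantom.primitives:
        lab_of[p.label] = p.material
    masks = region_masks(phantom)
    for name, mask in masks.items():
        if name == "air":
            if phantom.background is not None and mask.any():
                out.append((phantom.background, mask))
            continue
        if mask.any():
            out.append((lab_of[name], mask))
    return out


# --- calibration ----------------------------------------------------------

@lru_cache(maxsize=None)
def calibrate_vessel_concentration(target_mu: float = VESSEL_MU_REFERENCE,
                                   energy_kev: float = CALIBRATION_ENERGY_KEV) -> float:
    """Iodine concentration (mg/ml) of the vessel solution such that its
    linear attenuation at ``energy_kev`` equals ``target_mu`` (1/mm).

    Solved numerically; the in-vessel concentration after injection is not a
    published quantity, the measured attenuation is."""
    from scipy.optimize import brentq

    def err(mg_ml: float) -> float:
        return iodinated_water(mg_ml).linear_attenuation(energy_kev) - target_mu

    return float(brentq(err, 0.0, 1000.0, xtol=1e-10))


@lru_cache(maxsize=None)
def calibrate_stone_density(target_mu: float = STONE_MU_REFERENCE,
                            energy_kev: float = CALIBRATION_ENERGY_KEV) -> float:
    """Effective bulk density (g/cm^3) of the 90/10 whewellite/weddellite
    stone such that mu(``energy_kev``) = ``target_mu``; real stones are porous
    and organic-bound, so the effective density is below the mineral value."""
    mix = _stone_mixture(1.0)
    mu_rho = mix.mass_attenuation(energy_kev)  # cm^2/g
    return float(target_mu * 10.0 / mu_rho)


def _stone_mixture(density: float, registry: MaterialRegistry | None = None) -> Material:
    reg = registry or default_registry()
    return make_mixture(
        [(reg.get("whewellite"), 0.9), (reg.get("weddellite"), 0.1)],
        name="calcium_oxalate_stone", density=density)


@lru_cache(maxsize=None)
def vessel_material() -> Material:
    return iodinated_water(calibrate_vessel_concentration(), name="vessel")


@lru_cache(maxsize=None)
def stone_material() -> Material:
    return _stone_mixture(calibrate_stone_density())


# --- the default kidney-like phantom --------------------------------------

@dataclass(frozen=True)
class KidneyPhantomConfig:
    """Geometry knobs of the kidney-like slice phantom.

    Sizes not published for the real specimen (stone diameter, vessel
    diameters) are config-exposed defaults: stone 3 mm, vessels 0.8-2 mm.
    """

    grid_size: int = 512
    voxel_size_mm: float = 0.07
    seed: int = 7
    n_vessels: int = 6
    vessel_radius_range_mm: tuple[float, float] = (0.4, 1.0)
    stone_radius_mm: float = 1.5
    kidney_axes_mm: tuple[float, float] = (11.0, 7.5)
    kidney_rotation_deg: float = 20.0
    beaker_outer_mm: float = 16.8
    beaker_wall_mm: float = 1.0
    max_retries: int = 500

    def __post_init__(self) -> None:
        if not (3 <= self.n_vessels <= 10):
            raise ValidationError("n_vessels must lie in [3, 10]")
        if self.stone_radius_mm <= 0 or self.grid_size < 64:
            raise ValidationError("invalid phantom geometry")


def kidney_phantom(config: KidneyPhantomConfig | None = None,
                   registry: MaterialRegistry | None = None) -> PhantomSpec:
    """Deterministic (seeded) kidney-like phantom.

    Water-bath annulus in a plastic beaker, soft-tissue kidney ellipse,
    ``n_vessels`` calibrated iodinated vessel discs inside the kidney, and
    one calibrated calcium-oxalate stone disc on the kidney surface ("in the
    skin surrounding the kidney").
    """
    cfg = config or KidneyPhantomConfig()
    reg = registry or default_registry()
    rng = np.random.default_rng(cfg.seed)

    prims: list[Primitive] = [
        Primitive("annulus", (0.0, 0.0),
                  (cfg.beaker_outer_mm, cfg.beaker_outer_mm - cfg.beaker_wall_mm),
                  reg.get("pvp"), "beaker"),
        Primitive("ellipse", (0.0, 0.0),
                  (cfg.beaker_outer_mm - cfg.beaker_wall_mm,) * 2,
                  reg.get("water"), "water_bath"),
        Primitive("ellipse", (0.0, 0.0), cfg.kidney_axes_mm,
                  reg.get("soft_tissue"), "tissue", cfg.kidney_rotation_deg),
    ]

    # stone on the kidney boundary, fully inside the bath
    ay, ax = cfg.kidney_axes_mm
    th = np.deg2rad(cfg.kidney_rotation_deg)
    for _ in range(cfg.max_retries):
        phi = rng.uniform(0, 2 * np.pi)
        by, bx = ay * np.sin(phi), ax * np.cos(phi)  # boundary point, unrotated
        cy = np.cos(th) * by + np.sin(th) * bx
        cx = -np.sin(th) * by + np.cos(th) * bx
        if np.hypot(cy, cx) + cfg.stone_radius_mm < \
                cfg.beaker_outer_mm - cfg.beaker_wall_mm - 0.5:
            break
    else:  # pragma: no cover - geometry always admits a boundary point
        raise PlacementError("could not place the stone on the kidney surface")
    stone = Primitive("ellipse", (float(cy), float(cx)),
                      (cfg.stone_radius_mm,) * 2, stone_material(), "stone")

    vessels: list[Primitive] = []
    vm = vessel_material()
    tries = 0
    while len(vessels) < cfg.n_vessels:
        if tries > cfg.max_retries:
            raise PlacementError(
                f"placed {len(vessels)}/{cfg.n_vessels} vessels after "
                f"{cfg.max_retries} retries")
        tries += 1
        r = rng.uniform(*cfg.vessel_radius_range_mm)
        # sample inside the unrotated kidney ellipse with a margin, then rotate
        u, v = rng.uniform(-1, 1, size=2)
        if u**2 + v**2 > 1:
            continue
        my, mx = u * (ay - r - 0.6), v * (ax - r - 0.6)
        py = np.cos(th) * my + np.sin(th) * mx
        px = -np.sin(th) * my + np.cos(th) * mx
        ok = np.hypot(py - stone.center_mm[0], px - stone.center_mm[1]) > \
            r + cfg.stone_radius_mm + 0.3
        for q in vessels:
            if np.hypot(py - q.center_mm[0], px - q.center_mm[1]) <= \
                    r + q.axes_mm[0] + 0.3:
                ok = False
                break
        if ok:
            vessels.append(Primitive("ellipse", (float(py), float(px)),
                                     (r, r), vm, "vessel"))

    prims.extend(vessels)
    prims.append(stone)
    return PhantomSpec(grid_shape=(cfg.grid_size, cfg.grid_size),
                       voxel_size_mm=cfg.voxel_size_mm,
                       primitives=tuple(prims),
                       background=reg.get("air"))


def disc_phantom(radius_mm: float, mu_per_mm: float, grid_size: int = 256,
                 voxel_size_mm: float = 0.07, energy_kev: float = 33.18) -> MuMap:
    """Centred uniform disc oracle: parallel line integrals have the closed
    form 2*mu*sqrt(r^2 - s^2)."""
    half = grid_size * voxel_size_mm / 2.0
    if radius_mm >= half:
        raise ValidationError("disc does not fit inside the grid")
    c = (np.arange(grid_size) - (grid_size - 1) / 2.0) * voxel_size_mm
    yy, xx = np.meshgrid(c, c, indexing="ij")
    vals = np.where(yy**2 + xx**2 <= radius_mm**2, mu_per_mm, 0.0)
    return MuMap(values=vals, energy_kev=energy_kev, voxel_size_mm=voxel_size_mm)


def ground_truth_table(phantom: PhantomSpec,
                       energies_kev=(33.18, 32.59)) -> pd.DataFrame:
    """Region-by-region ground-truth mu at the scan energies."""
    rows = []
    mats: dict[str, Material] = {}
    for p in phantom.primitives:
        mats.setdefault(p.label, p.material)
    if phantom.background is not None:
        mats["air"] = phantom.background
    for name, mat in mats.items():
        row = {"region": name, "material": mat.name,
               "density_g_cm3": mat.density}
        for e in energies_kev:
            row[f"mu_{e:g}keV_1_mm"] = mat.linear_attenuation(e)
        rows.append(row)
    return pd.DataFrame(rows)
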