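"""X-ray mass-attenuation tables with absorption-edge handling.

Tabulated mass-attenuation coefficients mu/rho (cm^2/g) are packaged as TSV
resources sampled on a dense 15-60 keV grid.  Absorption-edge energies appear
exactly twice in a table: the first row carries the below-edge value, the
second the above-edge value.  Queries interpolate in log(E)-log(mu/rho) space
within edge-free segments (photoelectric cross sections are near power laws),
and never interpolate across a duplicated edge pair: a query exactly at an
edge energy returns the below-edge value, a query strictly above it the
above-edge branch.

A :class:`Material` couples a table (or a mass-fraction mixture of other
materials) with a bulk density, giving linear attenuation in 1/mm.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import EnergyRangeError, UnknownMaterialError, ValidationError

ENERGY_RANGE_KEV = (15.0, 60.0)
IODINE_K_EDGE_KEV = 33.1694

__all__ = [
    "AttenuationTable",
    "Material",
    "MaterialRegistry",
    "default_registry",
    "load_table",
    "make_mixture",
    "iodinated_water",
    "IODINE_K_EDGE_KEV",
    "ENERGY_RANGE_KEV",
]


@dataclass(frozen=True)
class AttenuationTable:
    """Sampled (energy, mu/rho) curve for one material.

    Parameters
    ----------
    material_name:
        Registry name of the material.
    density:
        Bulk density in g/cm^3 (> 0, except for abstract tables).
    energies, mu_over_rho:
        Sample arrays; energies non-decreasing, each edge energy present
        exactly twice, mu/rho strictly positive.
    edges:
        Absorption-edge energies (keV) duplicated in ``energies``.
    """

    material_name: str
    density: float
    energies: np.ndarray
    mu_over_rho: np.ndarray
    edges: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.mu_over_rho, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", v)
        if e.ndim != 1 or e.shape != v.shape or e.size < 2:
            raise ValidationError("table needs matching 1-D energy/value arrays")
        if np.any(np.diff(e) < 0):
            raise ValidationError(f"{self.material_name}: energies must be non-decreasing")
        if np.any(v <= 0):
            raise ValidationError(f"{self.material_name}: mu/rho must be positive")
        dup = e[:-1][np.diff(e) == 0]
        if sorted(dup.tolist()) != sorted(self.edges):
            raise ValidationError(
                f"{self.material_name}: duplicated energies {dup.tolist()} "
                f"do not match declared edges {list(self.edges)}"
            )

    @classmethod
    def from_tsv(cls, path, material_name: str, density: float,
                 edges: Sequence[float] = ()) -> "AttenuationTable":
        data = np.loadtxt(path, skiprows=1)
        return cls(material_name=material_name, density=density,
                   energies=data[:, 0], mu_over_rho=data[:, 1],
                   edges=tuple(float(x) for x in edges))

    def __call__(self, energy_kev) -> np.ndarray | float:
        """Interpolated mu/rho (cm^2/g) at ``energy_kev`` (scalar or array)."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise EnergyRangeError(
                f"{self.material_name}: energy outside table range "
                f"[{lo:g}, {hi:g}] keV"
            )
        idx = np.searchsorted(self.energies, e, side="left")
        idx = np.clip(idx, 1, len(self.energies) - 1)
        x0, x1 = self.energies[idx - 1], self.energies[idx]
        y0, y1 = self.mu_over_rho[idx - 1], self.mu_over_rho[idx]
        # bracketing samples never coincide: searchsorted(side="left") points
        # the segment below an exact edge query and past the pair above it
        t = np.log(e / x0) / np.log(x1 / x0)
        out = np.exp((1.0 - t) * np.log(y0) + t * np.log(y1))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class Material:
    """A named material: either a direct attenuation table or a mass-fraction
    mixture of other materials, plus a bulk density (g/cm^3)."""

    name: str
    density: float
    table: AttenuationTable | None = None
    components: tuple[tuple["Material", float], ...] = ()

    def __post_init__(self) -> None:
        if (self.table is None) == (not self.components):
            raise ValidationError(
                f"{self.name}: exactly one of table/components must be given"
            )
        if self.components:
            fr = np.array([w for _, w in self.components], dtype=float)
            if np.any((fr < 0) | (fr > 1)):
                raise ValidationError(f"{self.name}: mass fractions must lie in [0, 1]")
            if abs(float(fr.sum()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.name}: mass fractions sum to {fr.sum():.12f}, not 1"
                )
        if self.density < 0:
            raise ValidationError(f"{self.name}: density must be >= 0")

    def mass_attenuation(self, energy_kev):
        """mu/rho in cm^2/g; mixtures are mass-fraction-weighted sums."""
        if self.table is not None:
            return self.table(energy_kev)
        return sum(w * comp.mass_attenuation(energy_kev)
                   for comp, w in self.components)

    def linear_attenuation(self, energy_kev):
        """Linear attenuation mu in 1/mm: (mu/rho) * rho, converted from 1/cm."""
        return self.mass_attenuation(energy_kev) * self.density / 10.0

    def with_density(self, density: float, name: str | None = None) -> "Material":
        return replace(self, density=density, name=name or self.name)


def make_mixture(components: Sequence[tuple[Material, float]], name: str,
                 density: float) -> Material:
    """Mixture by the mass-fraction rule; density is supplied, not derived."""
    return Material(name=name, density=density,
                    components=tuple((m, float(w)) for m, w in components))


def iodinated_water(mg_per_ml: float, registry: "MaterialRegistry | None" = None,
                    name: str | None = None) -> Material:
    """Aqueous iodine solution at ``mg_per_ml`` of dissolved iodine.

    Volume-additive model: the solution density is rho_water + c, and the
    iodine/water mass fractions follow from the concentration.  This is how
    the contrast-agent-filled vessels are parameterized.
    """
    if mg_per_ml < 0:
        raise ValidationError("concentration must be >= 0")
    reg = registry or default_registry()
    c = mg_per_ml / 1000.0  # g/cm^3 of iodine
    rho = reg.get("water").density + c
    return make_mixture(
        [(reg.get("iodine"), c / rho), (reg.get("water"), 1.0 - c / rho)],
        name=name or f"iodinated_water_{mg_per_ml:g}mg_ml",
        density=rho,
    )


def _read_cfg():
    cfg = configparser.ConfigParser()
    with resources.files("kesct.data").joinpath("materials.cfg").open() as fh:
        cfg.read_file(fh)
    return cfg


def load_table(table_name: str, material_name: str | None = None,
               density: float = 0.0, edges: Sequence[float] = ()) -> AttenuationTable:
    """Load a raw packaged TSV table (e.g. ``air_energy_absorption``)."""
    path = resources.files("kesct.data").joinpath(f"{table_name}.tsv")
    if not path.is_file():
        raise UnknownMaterialError(table_name)
    with path.open("rb") as fh:
        return AttenuationTable.from_tsv(
            fh, material_name or table_name, density, edges)


class MaterialRegistry:
    """Name -> Material mapping backed by the packaged registry config."""

    def __init__(self) -> None:
        self._cfg = _read_cfg()
        self._cache: dict[str, Material] = {}

    def names(self) -> list[str]:
        return list(self._cfg.sections())

    def get(self, name: str) -> Material:
        if name not in self._cache:
            if name not in self._cfg:
                raise UnknownMaterialError(name)
            sec = self._cfg[name]
            edges = tuple(float(x) for x in sec.get("edges", "").split()) \
                if sec.get("edges") else ()
            table = load_table(sec["table"].removesuffix(".tsv"), name,
                               sec.getfloat("density"), edges)
            self._cache[name] = Material(name=name, density=table.density,
                                         table=table)
        return self._cache[name]


@lru_cache(maxsize=1)
def default_registry() -> MaterialRegistry:
    return MaterialRegistry()
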