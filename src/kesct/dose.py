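"""Air-kerma and effective-dose accounting for an acquisition protocol.

Air kerma rate is the spectral sum of energy fluence times the mass
energy-absorption coefficient of dry air,

    Kdot = sum_E [Phi(E)/A] * E * (mu_en/rho)_air(E),

with the beam area A taken from the stated elliptic beam extent scaled to
the position of interest.  Effective dose applies an organ-level
kerma-to-effective-dose conversion coefficient (Sv/Gy); the default value is
back-solved from the published 10.32 mGy -> 2.67 mSv pair for kidney
imaging, since the underlying conversion tabulation is not reproduced here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ValidationError
from .materials import load_table
from .spectrum import Spectrum

__all__ = ["DoseReport", "air_kerma_rate", "total_dose",
           "DEFAULT_KERMA_TO_EFFECTIVE_SV_PER_GY"]

KEV_TO_J = 1.602176634e-16
#: Kerma -> effective dose for the kidney protocol (Sv/Gy), back-solved from
#: the published total-kerma/effective-dose pair.
DEFAULT_KERMA_TO_EFFECTIVE_SV_PER_GY = 2.67e-3 / 10.32e-3


@lru_cache(maxsize=1)
def _air_muen():
    return load_table("air_energy_absorption", "air (mu_en/rho)")


def air_kerma_rate(spectrum: Spectrum, beam_area_mm2: float) -> float:
    """Air kerma rate in mGy/s for a beam of ``beam_area_mm2`` uniformly
    carrying the spectrum's fluence."""
    if beam_area_mm2 <= 0:
        raise ValidationError("beam area must be positive")
    muen = np.asarray(_air_muen()(spectrum.energies))  # cm^2/g
    area_cm2 = beam_area_mm2 / 100.0
    # photons/s/cm^2 * J * cm^2/g * 1000 g/kg = Gy/s
    gy_per_s = float(np.sum(spectrum.fluence_rate / area_cm2
                            * spectrum.energies * KEV_TO_J * muen) * 1000.0)
    return gy_per_s * 1000.0  # mGy/s


@dataclass(frozen=True)
class DoseReport:
    """Per-scan kerma rates and times, totals, and effective dose."""

    kerma_rate_mgy_s: dict[str, float]
    scan_time_s: dict[str, float]
    conversion_coefficient_sv_gy: float = DEFAULT_KERMA_TO_EFFECTIVE_SV_PER_GY
    total_kerma_mgy: float = field(init=False)
    effective_dose_msv: float = field(init=False)

    def __post_init__(self) -> None:
        if set(self.kerma_rate_mgy_s) != set(self.scan_time_s):
            raise ValidationError("kerma rates and scan times must share labels")
        if any(t <= 0 for t in self.scan_time_s.values()):
            raise ValidationError("scan times must be positive")
        if any(k < 0 for k in self.kerma_rate_mgy_s.values()) or \
                self.conversion_coefficient_sv_gy < 0:
            raise ValidationError("dose quantities must be >= 0")
        total = sum(self.kerma_rate_mgy_s[k] * self.scan_time_s[k]
                    for k in self.kerma_rate_mgy_s)
        object.__setattr__(self, "total_kerma_mgy", total)
        object.__setattr__(self, "effective_dose_msv",
                           total * self.conversion_coefficient_sv_gy)

    def to_dict(self) -> dict:
        return {
            "kerma_rate_mgy_s": dict(self.kerma_rate_mgy_s),
            "scan_time_s": dict(self.scan_time_s),
            "total_kerma_mgy": self.total_kerma_mgy,
            "conversion_coefficient_sv_gy": self.conversion_coefficient_sv_gy,
            "effective_dose_msv": self.effective_dose_msv,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DoseReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kerma_rate_mgy_s=d["kerma_rate_mgy_s"],
                   scan_time_s=d["scan_time_s"],
                   conversion_coefficient_sv_gy=d["conversion_coefficient_sv_gy"])


def total_dose(kerma_rate_mgy_s: dict[str, float],
               scan_time_s: dict[str, float],
               conversion_coefficient_sv_gy: float =
               DEFAULT_KERMA_TO_EFFECTIVE_SV_PER_GY) -> DoseReport:
    """Total kerma = sum of rate x time per scan; effective dose applies the
    conversion coefficient to the total."""
    return DoseReport(kerma_rate_mgy_s=dict(kerma_rate_mgy_s),
                      scan_time_s=dict(scan_time_s),
                      conversion_coefficient_sv_gy=conversion_coefficient_sv_gy)
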