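"""Pycnometer density determination of the model sebum.

Standard pharmacopoeial water-displacement method at 20 degC: a known mass
of sebum displaces water in a calibrated pycnometer, and

    d = m1 * 0.997 / (w + m1 - m2) + 0.0012        [g/cm^3]

where m1 is the sebum mass, w the mass of water filling the pycnometer,
m2 the mass of sebum plus topped-up water, 0.997 g/cm^3 the density of
water at 20 degC and 0.0012 an air-buoyancy weighing correction applied
additively.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import AIR_BUOYANCY_CORRECTION, WATER_DENSITY_20C_G_PER_CM3

__all__ = ["PycnometerMeasurement", "pycnometer_density"]


@dataclass(frozen=True)
class PycnometerMeasurement:
    """One pycnometer run: sebum mass, water fill mass, combined mass (g)."""

    m1: float  # sebum mass
    w: float  # mass of water filling the pycnometer
    m2: float  # sebum plus topped-up water
    water_density: float = WATER_DENSITY_20C_G_PER_CM3  # g/cm^3 at 20 degC
    air_correction: float = AIR_BUOYANCY_CORRECTION

    def __post_init__(self) -> None:
        if self.m1 < 0 or self.w < 0 or self.m2 < 0:
            raise ValueError("masses must be non-negative")
        if not self.displaced_water_mass > 0:
            raise ValueError(
                f"displaced water mass w + m1 - m2 = {self.displaced_water_mass} "
                "must be positive"
            )

    @property
    def displaced_water_mass(self) -> float:
        return self.w + self.m1 - self.m2


def pycnometer_density(meas: PycnometerMeasurement) -> float:
    """Sebum density in g/cm^3 from a pycnometer measurement."""
    return (
        meas.m1 * meas.water_density / meas.displaced_water_mass
        + meas.air_correction
    )
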