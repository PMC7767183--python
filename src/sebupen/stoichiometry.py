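"""Mass/volume bookkeeping from a pH drop to a reacted sebum volume.

The neutralisation reaction is 1:1 in moles:

    R1-COOH + R2-NH2 (aq) -> R1-COO- [NH3+ -R2] (aq)

so the drop in undissociated alcoholamine concentration between two time
points fixes, through the molar masses, the mass of stearic acid consumed;
the known stearic-acid mass fraction of the model sebum then scales that up
to a reacted sebum mass, and the sebum density converts mass to volume.

Units are explicit throughout: masses in g, concentrations in mol/dm^3,
applied-solution volumes in dm^3, sebum volumes in mm^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping

from .chem import AlcoholamineSpec
from .constants import G_PER_MG, MM3_PER_DM3, STEARIC_MOLAR_MASS
from .chem import conc_from_ph

logger = logging.getLogger(__name__)

__all__ = [
    "SebumComposition",
    "ReactionMasses",
    "undissociated_amine_mass",
    "reacted_amine_mass",
    "reacted_acid_mass",
    "reacted_sebum_mass",
    "reacted_sebum_volume",
    "ph_to_reacted_volume",
]

#: default model skin sebum mass fractions
DEFAULT_SEBUM_FRACTIONS: Dict[str, float] = {
    "triglycerides": 0.34,
    "stearic_acid": 0.24,
    "lanolin": 0.26,
    "squalene": 0.12,
    "cholesterol": 0.04,
}


@dataclass(frozen=True)
class SebumComposition:
    """Model skin sebum: component mass fractions and bulk density.

    The default mixture is triglycerides 34%, stearic acid 24% (the free
    fatty acid that reacts with the alcoholamine), lanolin 26%, squalene
    12%, cholesterol 4%, with a pycnometer-determined density of
    0.842 mg/mm^3.
    """

    fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEBUM_FRACTIONS)
    )
    density_mg_per_mm3: float = 0.842
    stearic_molar_mass: float = STEARIC_MOLAR_MASS  # g/mol

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sebum fractions must sum to 1, got {total}")
        for name, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {name}={f} outside [0, 1]")
        if not self.density_mg_per_mm3 > 0:
            raise ValueError("sebum density must be positive")
        if not self.fractions.get("stearic_acid", 0.0) > 0:
            raise ValueError("stearic_acid fraction must be positive")

    @property
    def stearic_fraction(self) -> float:
        return self.fractions["stearic_acid"]

    @property
    def density_g_per_mm3(self) -> float:
        return self.density_mg_per_mm3 * G_PER_MG


@dataclass(frozen=True)
class ReactionMasses:
    """Per-time-point mass bookkeeping of the neutralisation reaction."""

    m_z: float  # unreacted (undissociated) alcoholamine, g
    m_zp: float  # reacted alcoholamine, g
    m_kp: float  # reacted stearic acid, g
    m_s: float  # reacted sebum, g

    def __post_init__(self) -> None:
        for name in ("m_z", "m_zp", "m_kp", "m_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.m_s < self.m_kp:
            raise ValueError("reacted sebum mass cannot be below reacted acid mass")


def undissociated_amine_mass(Cb: float, amine: AlcoholamineSpec, Vr: float) -> float:
    """Mass (g) of undissociated alcoholamine: m_z = Cb * M * Vr.

    ``Cb`` in mol/dm^3, ``Vr`` (applied solution volume) in dm^3.
    """
    if Cb < 0:
        raise ValueError(f"Cb must be non-negative, got {Cb}")
    if not Vr > 0:
        raise ValueError(f"Vr must be positive, got {Vr}")
    return Cb * amine.molar_mass * Vr


def reacted_amine_mass(m_z0: float, m_zn: float, policy: str = "clamp") -> float:
    """Reacted alcoholamine mass m_zp = m_z(t0) - m_z(tn), in g.

    A negative result means the pH rose between the two time points
    (e.g. an electrode transient caused by floating reacted-sebum
    particles).  Under the default ``clamp`` policy it is reported as 0
    with a logged flag; ``raw`` preserves the negative value for
    diagnostics.
    """
    if m_z0 < 0 or m_zn < 0:
        raise ValueError("masses must be non-negative")
    if policy not in ("clamp", "raw"):
        raise ValueError(f"unknown policy {policy!r}")
    m_zp = m_z0 - m_zn
    if m_zp < 0 and policy == "clamp":
        logger.warning(
            "negative reacted amine mass %.3e g (pH rose); clamped to 0", m_zp
        )
        return 0.0
    return m_zp


def reacted_acid_mass(
    m_zp: float,
    amine_molar_mass: float = 105.14,
    acid_molar_mass: float = STEARIC_MOLAR_MASS,
    direction: str = "physical",
) -> float:
    """Reacted stearic acid mass (g) from reacted alcoholamine mass.

    The neutralisation is 1:1 in moles, so physically
    m_kp = m_zp * M_acid / M_amine (``direction='physical'``, default).
    The transposed ratio m_zp * M_amine / M_acid is retained as
    ``direction='as_printed'`` for audit; it fails mass balance on
    realistic reacted volumes (it would require more reacted alcoholamine
    than was applied) and is never the default.
    """
    if m_zp < 0:
        raise ValueError(f"m_zp must be non-negative, got {m_zp}")
    if direction == "physical":
        return m_zp * acid_molar_mass / amine_molar_mass
    if direction == "as_printed":
        return m_zp * amine_molar_mass / acid_molar_mass
    raise ValueError(f"unknown direction {direction!r}")


def reacted_sebum_mass(m_kp: float, sebum: SebumComposition) -> float:
    """Reacted sebum mass (g): reacted acid mass / stearic mass fraction."""
    if m_kp < 0:
        raise ValueError(f"m_kp must be non-negative, got {m_kp}")
    return m_kp / sebum.stearic_fraction


def reacted_sebum_volume(m_s: float, sebum: SebumComposition) -> float:
    """Reacted sebum volume (mm^3): V_s = m_s / d_s with d_s in g/mm^3."""
    if m_s < 0:
        raise ValueError(f"m_s must be non-negative, got {m_s}")
    return m_s / sebum.density_g_per_mm3


def ph_to_reacted_volume(
    ph0: float,
    phn: float,
    amine: AlcoholamineSpec,
    Vr: float,
    sebum: SebumComposition,
    direction: str = "physical",
    policy: str = "clamp",
) -> float:
    """Full chain pH(t0), pH(tn) -> reacted sebum volume in mm^3.

    Sequential composition of concentration inversion, amine mass,
    reacted-amine difference, acid mass, sebum mass and sebum volume.
    ``Vr`` is the applied solution volume in dm^3.
    """
    Cb0 = conc_from_ph(ph0, amine.constants)
    Cbn = conc_from_ph(phn, amine.constants)
    m_z0 = undissociated_amine_mass(Cb0, amine, Vr)
    m_zn = undissociated_amine_mass(Cbn, amine, Vr)
    m_zp = reacted_amine_mass(m_z0, m_zn, policy=policy)
    m_kp = reacted_acid_mass(
        m_zp if m_zp > 0 else 0.0,
        amine_molar_mass=amine.molar_mass,
        acid_molar_mass=sebum.stearic_molar_mass,
        direction=direction,
    )
    if m_zp < 0:  # raw policy carried a negative through
        m_kp = -reacted_acid_mass(
            -m_zp,
            amine_molar_mass=amine.molar_mass,
            acid_molar_mass=sebum.stearic_molar_mass,
            direction=direction,
        )
        m_s = m_kp / sebum.stearic_fraction
        return m_s / sebum.density_g_per_mm3
    m_s = reacted_sebum_mass(m_kp, sebum)
    return reacted_sebum_volume(m_s, sebum)
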