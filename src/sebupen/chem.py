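"""Weak-base pH equilibrium and salt-hydrolysis equilibrium.

An alcoholamine such as AMPD is a weak base; the pH of its dilute aqueous
solution follows from the base dissociation equilibrium,

    pH = pKw - 1/2 (pKb - log10 Cb),

where ``Cb`` is the total molar base concentration.  Inverting this relation
lets the concentration of undissociated base remaining in solution be read
off a measured pH, which is the basis of the stoichiometric penetration
method.  The amine soap formed by neutralisation is a salt of a weak acid
and a weak base; its hydrolysis constant and the pH of its aqueous solution
follow the textbook expressions

    Kh = Kw / (Ka * Kb),        pH = 1/2 (pKw + pKa - pKb).

Activity coefficients and ionic-strength corrections are deliberately not
applied: the equilibria are used as illustrative bookkeeping for a complex
reacting mixture, not as a precision speciation model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .constants import AMPD_MOLAR_MASS, AMPD_PKB_FROM_PKA, PKW_25C

__all__ = [
    "AcidBaseConstants",
    "AlcoholamineSpec",
    "ph_of_weak_base",
    "conc_from_ph",
    "hydrolysis_constant",
    "salt_solution_ph",
]


@dataclass(frozen=True)
class AcidBaseConstants:
    """Dissociation exponents for an acid/base pair in water.

    Parameters
    ----------
    pKb : float
        Base dissociation exponent, ``-log10 Kb``.
    pKw : float, default 14.0
        Exponent of the ionic product of water (25 degC value).
    pKa : float, optional
        Acid dissociation exponent of the partner weak acid; only needed
        for the salt-hydrolysis operations.
    """

    pKb: float
    pKw: float = PKW_25C
    pKa: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.pKw > 0:
            raise ValueError(f"pKw must be positive, got {self.pKw}")
        if not self.pKb > 0:
            raise ValueError(f"pKb must be positive, got {self.pKb}")

    @property
    def Kw(self) -> float:
        return 10.0 ** (-self.pKw)

    @property
    def Kb(self) -> float:
        return 10.0 ** (-self.pKb)

    @property
    def Ka(self) -> float:
        if self.pKa is None:
            raise ValueError("pKa is not set on these constants")
        return 10.0 ** (-self.pKa)


@dataclass(frozen=True)
class AlcoholamineSpec:
    """Identity and constants of the penetrating alcoholamine base."""

    name: str = "AMPD"
    molar_mass: float = AMPD_MOLAR_MASS  # g/mol
    constants: AcidBaseConstants = field(
        default_factory=lambda: AcidBaseConstants(pKb=AMPD_PKB_FROM_PKA)
    )

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "AlcoholamineSpec":
        """Build a spec from a plain mapping, e.g. a parsed YAML/JSON block.

        Recognised keys: ``name``, ``molar_mass``, ``pKb``, ``pKw``, ``pKa``.
        """
        constants = AcidBaseConstants(
            pKb=float(cfg.get("pKb", AMPD_PKB_FROM_PKA)),
            pKw=float(cfg.get("pKw", PKW_25C)),
            pKa=None if cfg.get("pKa") is None else float(cfg["pKa"]),
        )
        return cls(
            name=str(cfg.get("name", "AMPD")),
            molar_mass=float(cfg.get("molar_mass", AMPD_MOLAR_MASS)),
            constants=constants,
        )


def ph_of_weak_base(Cb: float, constants: AcidBaseConstants) -> float:
    """pH of a weak-base solution of total molar concentration ``Cb``.

    Implements pH = pKw - 1/2 (pKb - log10 Cb).

    Parameters
    ----------
    Cb : float
        Total base concentration in mol/dm^3; must be positive.
    """
    if not Cb > 0:
        raise ValueError(f"Cb must be positive, got {Cb}")
    return constants.pKw - 0.5 * (constants.pKb - math.log10(Cb))


def conc_from_ph(pH: float, constants: AcidBaseConstants) -> float:
    """Molar base concentration from a measured pH.

    Exact algebraic inverse of :func:`ph_of_weak_base`:
    Cb = 10^(2 pH - 2 pKw + pKb).

    A pH at or above pKw is non-physical for this model (it implies
    Cb >= 10^pKb); a warning is emitted and the formula is still applied
    so that the caller can inspect the flagged value.
    """
    if not pH > 0:
        raise ValueError(f"pH must be positive, got {pH}")
    if pH >= constants.pKw:
        warnings.warn(
            f"pH {pH} >= pKw {constants.pKw}: inverted concentration is "
            "outside the weak-base model's validity",
            stacklevel=2,
        )
    return 10.0 ** (2.0 * pH - 2.0 * constants.pKw + constants.pKb)


def hydrolysis_constant(Ka: float, Kb: float, Kw: float = 1.0e-14) -> float:
    """Hydrolysis constant Kh = Kw / (Ka * Kb) of a weak-acid/weak-base salt."""
    if not (Ka > 0 and Kb > 0 and Kw > 0):
        raise ValueError(f"Ka, Kb, Kw must all be positive, got {Ka}, {Kb}, {Kw}")
    return Kw / (Ka * Kb)


def salt_solution_ph(constants: AcidBaseConstants) -> float:
    """pH of an aqueous solution of a salt of a weak acid and a weak base.

    Implements pH = 1/2 (pKw + pKa - pKb); independent of the salt
    concentration to first order, as is standard for this case.
    """
    if constants.pKa is None:
        raise ValueError("salt_solution_ph requires pKa on the constants")
    return 0.5 * (constants.pKw + constants.pKa - constants.pKb)
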