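"""Monomer–dimer self-association equilibria.

Closed-form and numerical solvers for the thermodynamic core shared by the
isotherm-fitting and stopped-flow stages: speciation of a total protein
concentration into free monomer and dimer, the weight-average molar mass
measured by SEC-MALS, the signal-weighted sedimentation-coefficient isotherm
measured by sedimentation-velocity AUC, and the coupled competition between
dimerization and ribosome binding.

Conventions
-----------
* The dimerization constant is the dissociation constant of the dimer,
  ``Kd = [M]^2 / [D]``, with the free monomer ``m`` in monomer-molar units
  and the dimer ``d`` in dimer-particle-molar units.  With this convention
  a protein at total concentration ``CT = Kd`` (monomer units) is exactly
  50% monomer / 50% dimer by mass.
* Internal units are fixed: concentrations in µM, masses in kDa,
  sedimentation coefficients in S, time in s.  Conversion to M⁻¹s⁻¹ happens
  only when bimolecular rate constants are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DEFAULTS",
    "SelfAssociationModel",
    "SpeciationState",
    "SwModel",
    "CoupledEquilibria",
    "CoupledSpeciation",
    "solve_speciation",
    "weight_average_mass",
    "sw_isotherm",
    "coupled_speciation",
]

#: Default physical constants for the Trigger Factor system.
#:
#: ========  =======  =====================================================
#: key       value    meaning
#: ========  =======  =====================================================
#: Mm_kDa    48.0     monomer molar mass (dimer plateau 96 kDa)
#: Kd_dim    2.0      dimerization dissociation constant, µM
#: Kd_rib    0.5      TF–vacant-ribosome dissociation constant, µM
#: kdiss     10.0     intrinsic dimer dissociation rate, s⁻¹
#: kon_m     0.5      monomer–substrate association, µM⁻¹s⁻¹ (0.5e6 M⁻¹s⁻¹)
#: koff_m    6.0      monomer–substrate dissociation, s⁻¹
#: kon_d     1.1      dimer–substrate association, µM⁻¹s⁻¹ (1.1e6 M⁻¹s⁻¹)
#: koff_d    30.0     dimer–substrate dissociation, s⁻¹
#: ========  =======  =====================================================
DEFAULTS: dict[str, float] = {
    "Mm_kDa": 48.0,
    "Kd_dim_uM": 2.0,
    "Kd_rib_uM": 0.5,
    "kdiss_per_s": 10.0,
    "kon_m_uM_s": 0.5,
    "koff_m_per_s": 6.0,
    "kon_d_uM_s": 1.1,
    "koff_d_per_s": 30.0,
}


@dataclass(frozen=True)
class SelfAssociationModel:
    """Monomer–dimer self-association model ``2M ⇌ D``.

    Parameters
    ----------
    Mm : float
        Monomer molar mass in kDa.
    Kd_dim : float
        Dimerization dissociation constant ``[M]^2/[D]`` in µM.
    """

    Mm: float = DEFAULTS["Mm_kDa"]
    Kd_dim: float = DEFAULTS["Kd_dim_uM"]

    def __post_init__(self) -> None:
        if not (self.Mm > 0):
            raise ValueError(f"monomer mass must be positive, got {self.Mm}")
        if not (self.Kd_dim > 0):
            raise ValueError(f"Kd_dim must be positive, got {self.Kd_dim}")


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium partitioning of a total concentration into species.

    Attributes
    ----------
    CT : float
        Total protein concentration in monomer units (µM).
    m : float
        Free monomer concentration (µM).
    d : float
        Dimer particle concentration (µM); ``m + 2 d == CT``.
    """

    CT: float
    m: float
    d: float

    @property
    def monomer_mass_fraction(self) -> float:
        """Fraction of protein mass in the monomeric state, ``m/CT``."""
        return self.m / self.CT if self.CT > 0 else 1.0

    @property
    def dimer_mass_fraction(self) -> float:
        """Fraction of protein mass in the dimeric state, ``2d/CT``."""
        return 2.0 * self.d / self.CT if self.CT > 0 else 0.0


@dataclass(frozen=True)
class SwModel:
    """Sedimentation-coefficient isotherm model for a monomer–dimer system.

    ``sM`` and ``sD`` are the species sedimentation coefficients in
    Svedberg; a dimer must sediment faster than its monomer.
    """

    sM: float
    sD: float
    model: SelfAssociationModel = field(default_factory=SelfAssociationModel)

    def __post_init__(self) -> None:
        if not (0 < self.sM < self.sD):
            raise ValueError(
                f"require 0 < sM < sD, got sM={self.sM}, sD={self.sD}"
            )


def solve_speciation(CT: float, model: SelfAssociationModel) -> SpeciationState:
    """Partition total concentration ``CT`` into free monomer and dimer.

    Solves the mass balance ``2 m^2 / Kd + m - CT = 0`` for the unique
    non-negative root

    .. math:: m = \\frac{K_d}{4}\\left(\\sqrt{1 + 8 C_T/K_d} - 1\\right)

    and sets ``d = (CT - m)/2``.

    Parameters
    ----------
    CT : float
        Total protein concentration in monomer units (µM), ``>= 0``.
    model : SelfAssociationModel

    Returns
    -------
    SpeciationState
    """
    if CT < 0:
        raise ValueError(f"total concentration must be non-negative, got {CT}")
    if CT == 0:
        return SpeciationState(CT=0.0, m=0.0, d=0.0)
    Kd = model.Kd_dim
    # rationalized root avoids cancellation when 8 CT/Kd is small;
    # d from the equilibrium condition keeps m^2/d = Kd to machine precision
    m = 2.0 * CT / (1.0 + math.sqrt(1.0 + 8.0 * CT / Kd))
    d = m * m / Kd
    return SpeciationState(CT=CT, m=m, d=d)


def weight_average_mass(CT: float, model: SelfAssociationModel) -> float:
    """Weight-average molar mass of a monomer–dimer mixture (kDa).

    .. math::

        M_w = M_m \\, \\frac{8 C_T + K_d - \\sqrt{K_d^2 + 8 C_T K_d}}{4 C_T}

    The infinite-dilution limit is ``Mm`` (all monomer) and the
    high-concentration plateau is ``2 Mm`` (all dimer); the expression is
    0/0 at ``CT == 0``, so zero or negative concentrations are rejected —
    callers wanting the dilution limit should use ``model.Mm`` directly.
    """
    if CT <= 0:
        raise ValueError(
            f"Mw is defined for CT > 0 (limit CT->0 is Mm); got CT={CT}"
        )
    Kd = model.Kd_dim
    # rationalized form of Mm (8CT + Kd - sqrt(Kd^2 + 8 CT Kd)) / (4 CT):
    # multiplying through by the conjugate removes the CT << Kd cancellation
    b = 8.0 * CT + Kd
    return model.Mm * 2.0 * b / (b + math.sqrt(Kd * (Kd + 8.0 * CT)))


def sw_isotherm(CT: float, sw_model: SwModel) -> float:
    """Signal-weighted average sedimentation coefficient sw(CT), in S.

    Assumes equal mass-specific signal for monomer and dimer, so the
    weights are the species mass fractions:

    .. math:: s_w = \\frac{s_M\\,m + s_D\\,(C_T - m)}{C_T}

    with ``m`` the free monomer concentration at ``CT``.
    """
    if CT <= 0:
        raise ValueError(f"sw isotherm requires CT > 0, got {CT}")
    spec = solve_speciation(CT, sw_model.model)
    return (sw_model.sM * spec.m + sw_model.sD * (CT - spec.m)) / CT


@dataclass(frozen=True)
class CoupledEquilibria:
    """Inputs of the dimerization / ribosome-binding competition.

    A TF monomer can either self-associate (``2M ⇌ D``, constant
    ``Kd_dim``) or bind a vacant ribosome (``M + R ⇌ MR``, constant
    ``Kd_rib``); the dimer cannot bind the ribosome because its
    ribosome-binding loop is buried in the dimer interface.
    """

    model: SelfAssociationModel = field(default_factory=SelfAssociationModel)
    Kd_rib: float = DEFAULTS["Kd_rib_uM"]
    CT_TF: float = 0.0
    CT_rib: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Kd_rib > 0):
            raise ValueError(f"Kd_rib must be positive, got {self.Kd_rib}")
        if self.CT_TF < 0 or self.CT_rib < 0:
            raise ValueError("total concentrations must be non-negative")


@dataclass(frozen=True)
class CoupledSpeciation:
    """Solution of the coupled system: concentrations and TF fractions."""

    m: float           # free TF monomer, µM
    d: float           # TF dimer particles, µM
    r: float           # free ribosome, µM
    mr: float          # TF·ribosome complex, µM
    frac_monomer: float
    frac_dimer: float
    frac_ribosome_bound: float


def coupled_speciation(ce: CoupledEquilibria) -> CoupledSpeciation:
    """Solve the coupled dimerization / ribosome-binding equilibria.

    Root-finds on the free monomer concentration ``m``: with
    ``r(m) = CT_rib / (1 + m/Kd_rib)`` the TF mass balance

    ``m + 2 m^2/Kd_dim + m r(m)/Kd_rib - CT_TF = 0``

    is strictly increasing in ``m``, so a bracketed Brent search on
    ``[0, CT_TF]`` converges unconditionally.

    Returns TF fractions (monomer, dimer, ribosome-bound) that sum to 1.
    """
    CT, Crib = ce.CT_TF, ce.CT_rib
    if CT == 0:
        return CoupledSpeciation(0.0, 0.0, Crib, 0.0, 1.0, 0.0, 0.0)
    Kd, Kr = ce.model.Kd_dim, ce.Kd_rib

    def balance(m: float) -> float:
        r = Crib / (1.0 + m / Kr)
        return m + 2.0 * m * m / Kd + m * r / Kr - CT

    try:
        m = brentq(balance, 0.0, CT, xtol=1e-15, rtol=1e-14, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise ArithmeticError(
            f"coupled speciation failed to converge for CT_TF={CT}, "
            f"CT_rib={Crib}, Kd_dim={Kd}, Kd_rib={Kr}: {exc}"
        ) from exc
    r = Crib / (1.0 + m / Kr)
    mr = m * r / Kr
    d = m * m / Kd
    return CoupledSpeciation(
        m=m, d=d, r=r, mr=mr,
        frac_monomer=m / CT,
        frac_dimer=2.0 * d / CT,
        frac_ribosome_bound=mr / CT,
    )


def speciation_oracle_bisection(
    CT: float, model: SelfAssociationModel, tol: float = 1e-12
) -> float:
    """Free monomer by plain bisection on the mass-balance polynomial.

    Deliberately naive; used in the test suite as an independent check of
    the closed-form root in :func:`solve_speciation`.
    """
    if CT == 0:
        return 0.0
    f = lambda m: 2.0 * m * m / model.Kd_dim + m - CT
    lo, hi = 0.0, CT
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
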