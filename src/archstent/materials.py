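"""Constitutive models for the aortic wall, dissection flap and stent metals.

The wall and flap use the isotropic hyperelastic Raghavan–Vorp law

    W(I1) = C10 (I1 - 3) + C20 (I1 - 3)^2        [MPa]

with the first invariant ``I1`` of the left Cauchy–Green tensor. Flap
chronicity is modelled by scaling (C10, C20) by a stiffness ratio in (0, 1]:
an acute, mobile flap is much softer than the wall (ratio 0.01), a chronic
flap as stiff as the wall (ratio 1).

The stent wire (nitinol) and the crimping tool (steel) are linear elastic;
nitinol stays close to the ~1 % linear regime during deployment, so no
superelastic phase transformation is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HyperelasticParams",
    "LinearElasticParams",
    "AORTIC_WALL",
    "NITINOL",
    "STEEL",
    "DEFAULT_STIFFNESS_RATIOS",
    "strain_energy",
    "uniaxial_cauchy_stress",
    "uniaxial_first_invariant",
    "scale_flap_stiffness",
    "small_strain_modulus",
]

DEFAULT_STIFFNESS_RATIOS = (1.0, 0.1, 0.01)


@dataclass(frozen=True)
class HyperelasticParams:
    """Raghavan–Vorp constants in MPa."""

    C10: float
    C20: float

    def __post_init__(self) -> None:
        if not self.C10 > 0:
            raise ValueError(f"C10 must be positive, got {self.C10}")
        if self.C20 < 0:
            raise ValueError(f"C20 must be non-negative, got {self.C20}")


@dataclass(frozen=True)
class LinearElasticParams:
    """Linear elastic metal: Young's modulus E [GPa], Poisson ratio, density [kg/m^3]."""

    E: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not 0 < self.nu < 0.5:
            raise ValueError(f"nu must be in (0, 0.5), got {self.nu}")
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")

    @property
    def E_MPa(self) -> float:
        return self.E * 1000.0


#: Aortic wall constants (literature values for dissected thoracic aorta).
AORTIC_WALL = HyperelasticParams(C10=0.174, C20=1.881)
#: Nitinol support rings, linear-elastic approximation.
NITINOL = LinearElasticParams(E=83.0, nu=0.33, rho=6450.0)
#: Steel crimping tool.
STEEL = LinearElasticParams(E=210.0, nu=0.3, rho=7850.0)


def strain_energy(I1, p: HyperelasticParams):
    """Strain-energy density W(I1) in MPa.

    Raises ``ValueError`` for I1 < 3, which is unattainable for an
    isochoric deformation.
    """
    I1 = np.asarray(I1, dtype=float)
    if np.any(I1 < 3.0 - 1e-12):
        raise ValueError("first invariant I1 must be >= 3")
    x = I1 - 3.0
    W = p.C10 * x + p.C20 * x * x
    return W if W.ndim else float(W)


def uniaxial_first_invariant(stretch):
    """I1 = lambda^2 + 2/lambda for incompressible uniaxial extension."""
    lam = np.asarray(stretch, dtype=float)
    return lam * lam + 2.0 / lam


def uniaxial_cauchy_stress(stretch, p: HyperelasticParams):
    """Uniaxial Cauchy stress [MPa] of the incompressible Raghavan–Vorp solid.

    Closed form obtained from W by the standard incompressible uniaxial
    reduction (lateral stretches lambda^-1/2, pressure eliminated by the
    traction-free lateral faces):

        sigma = 2 (lambda^2 - 1/lambda) [C10 + 2 C20 (I1 - 3)]
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    I1 = lam * lam + 2.0 / lam
    sig = 2.0 * (lam * lam - 1.0 / lam) * (p.C10 + 2.0 * p.C20 * (I1 - 3.0))
    return sig if sig.ndim else float(sig)


def scale_flap_stiffness(p: HyperelasticParams, ratio: float) -> HyperelasticParams:
    """Flap constants at a given flap-to-wall stiffness ratio (both constants scale)."""
    if not ratio > 0:
        raise ValueError(f"stiffness ratio must be positive, got {ratio}")
    return HyperelasticParams(C10=p.C10 * ratio, C20=p.C20 * ratio)


def small_strain_modulus(p: HyperelasticParams) -> float:
    """Equivalent small-strain Young's modulus E = 6 C10 [MPa].

    d(sigma)/d(lambda) at lambda = 1 of the incompressible uniaxial closed
    form; used to size the flap shell's membrane and bending stiffness.
    """
    return 6.0 * p.C10
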