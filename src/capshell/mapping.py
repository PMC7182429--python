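"""Mappings between coarse-grained potential parameters, dimensional elastic
constants, and the scaled theory parameters (lam, dmu, gamma).

Three descriptions of the same shell are connected here:

* the capsomer-level pair potential (Mie exponents m > n, preferred
  interaction angle nu, angular width alpha, binding energy eps0, diameter
  sigma, free concentration c1),
* continuum elastic constants (2-D Young's modulus Y, bending modulus
  kappa, spontaneous radius R0, line tension Lambda, area per subunit a1),
* the dimensionless triple (lam, dmu, gamma) that the phase diagram lives
  on.

For experimental capsids, AFM-derived mechanics (3-D Young's modulus E,
shell thickness h, outer diameter) are reduced to the same triple with
Y = E*h and the thin-shell FvK number gamma = 12 (1 - nu_p^2) (R/h)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .theory import ScaledParameters

__all__ = [
    "KBT_298K",
    "PotentialParameters",
    "ElasticConstants",
    "CapsidDescriptor",
    "potential_to_elastic",
    "potential_to_scaled",
    "capsid_descriptor_to_scaled",
    "capsomer_diameter",
    "spring_constant_to_E",
    "E_to_spring_constant",
]

#: Boltzmann constant times 298 K, in joules.
KBT_298K = 4.11e-21

# Caspar-Klug triangulation numbers T = h^2 + h*k + k^2
_VALID_T = sorted({h * h + h * k + k * k
                   for h in range(0, 12) for k in range(0, 12)} - {0})


@dataclass(frozen=True)
class PotentialParameters:
    """Coarse-grained capsomer interaction constants (reduced units).

    ``eps0`` and ``sigma`` carry the energy and length scale; ``conc`` and
    ``c_star`` (same units as each other) set the chemical potential through
    dmu = kT ln(conc/c_star).
    """

    m: int = 24
    n: int = 12
    nu: float = 1.45
    alpha: float = 0.1
    kt: float = 1.5
    eps0: float = 1.0
    sigma: float = 1.0
    conc: float | None = None
    c_star: float | None = None

    def __post_init__(self):
        if not self.m > self.n > 0:
            raise ValueError("Mie exponents must satisfy m > n > 0")
        if self.alpha <= 0:
            raise ValueError("angular width alpha must be > 0")
        if self.eps0 <= 0 or self.sigma <= 0:
            raise ValueError("eps0 and sigma must be > 0")


@dataclass(frozen=True)
class ElasticConstants:
    """Dimensional elasticity set bridging experiment, theory and simulation."""

    Y: float          # 2-D Young's modulus
    kappa: float      # bending modulus
    R0: float         # spontaneous curvature radius
    Lambda: float     # line tension
    a1: float         # area per subunit
    dmu_dim: float | None = None   # chemical potential difference

    def __post_init__(self):
        for name in ("Y", "kappa", "R0", "Lambda", "a1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_scaled(self) -> ScaledParameters:
        """Assemble (lam, dmu, gamma) from their defining ratios."""
        dmu = 0.0 if self.dmu_dim is None else self.dmu_dim / (self.Y * self.a1)
        return ScaledParameters(
            lam=self.Lambda / (self.R0 * self.Y),
            dmu=dmu,
            gamma=self.Y * self.R0 ** 2 / self.kappa,
        )


@dataclass(frozen=True)
class CapsidDescriptor:
    """Experimental capsid geometry and mechanics (AFM-derived geometry and moduli)."""

    T_number: int
    diameter: float       # outer diameter, nm
    h: float              # shell thickness, nm
    E: float              # 3-D Young's modulus, GPa
    nu_p: float = 0.3     # 3-D Poisson ratio
    eps0_kT: float = 10.0  # binding energy per capsomer contact, kB*T units

    def __post_init__(self):
        if self.T_number not in _VALID_T:
            raise ValueError(
                f"T={self.T_number} is not a Caspar-Klug triangulation number")
        if self.diameter <= 0 or self.h <= 0 or self.E <= 0:
            raise ValueError("diameter, thickness and modulus must be > 0")


# --------------------------------------------------------------------------
# coarse-grained model -> elasticity
# --------------------------------------------------------------------------

def potential_to_elastic(pp: PotentialParameters, kBT=None) -> ElasticConstants:
    """Elastic constants of a shell assembled from the coarse-grained model.

    Y = 2 n m eps0 / (sqrt(3) sigma^2), kappa = 3 sqrt(3) eps0 / (8 alpha^2),
    R0 = sigma / (2 |cos nu|), Lambda = 2 eps0 / (sqrt(3) sigma),
    a1 = pi sigma^2 / 4.

    Two equivalent conventions exist for the preferred angle: nu slightly
    below pi/2 with the orientation vectors pointing into the shell, or
    nu above pi/2 with outward orientations (where R0 = -sigma/(2 cos nu)).
    Both are accepted; nu = pi/2 exactly means a flat sheet (R0 infinite)
    and is rejected.
    """
    cn = math.cos(pp.nu)
    if abs(cn) < 1e-12:
        raise ValueError("nu = pi/2 gives a flat sheet (no spontaneous "
                         "curvature): R0 diverges")
    dmu_dim = None
    if pp.conc is not None and pp.c_star is not None:
        if kBT is None:
            # reduced units: T = kT/eps0 = 0.1 by the simulation convention
            kBT = 0.1 * pp.eps0
        dmu_dim = kBT * math.log(pp.conc / pp.c_star)
    return ElasticConstants(
        Y=2.0 * pp.n * pp.m * pp.eps0 / (math.sqrt(3.0) * pp.sigma ** 2),
        kappa=3.0 * math.sqrt(3.0) * pp.eps0 / (8.0 * pp.alpha ** 2),
        R0=pp.sigma / (2.0 * abs(cn)),
        Lambda=2.0 * pp.eps0 / (math.sqrt(3.0) * pp.sigma),
        a1=math.pi * pp.sigma ** 2 / 4.0,
        dmu_dim=dmu_dim,
    )


def potential_to_scaled(pp: PotentialParameters, kBT=None) -> ScaledParameters:
    """Scaled assembly parameters of the coarse-grained model.

    gamma = 4 n m alpha^2 / (9 cos^2 nu), lam = 2 |cos nu| / (n m), and
    dmu = (2 sqrt(3) / (pi n m)) kT ln(c1/c*) / eps0.
    """
    cn = math.cos(pp.nu)
    if abs(cn) < 1e-12:
        raise ValueError("nu = pi/2 gives a flat sheet (no spontaneous "
                         "curvature): the FvK number diverges")
    dmu = 0.0
    if pp.conc is not None and pp.c_star is not None:
        if kBT is None:
            kBT = 0.1 * pp.eps0
        dmu = (2.0 * math.sqrt(3.0) / (math.pi * pp.n * pp.m)
               * kBT * math.log(pp.conc / pp.c_star) / pp.eps0)
    return ScaledParameters(
        lam=2.0 * abs(cn) / (pp.n * pp.m),
        dmu=dmu,
        gamma=4.0 * pp.n * pp.m * pp.alpha ** 2 / (9.0 * cn * cn),
    )


# --------------------------------------------------------------------------
# experimental descriptors -> scaled parameters
# --------------------------------------------------------------------------

def capsomer_diameter(radius, T_number):
    """Effective capsomer diameter from capsid radius and T number.

    A T-shell packs 12 pentamers and 10(T-1) hexamers on the sphere;
    equating the covered area gives
    sigma = R / sqrt(2 (T + cot(pi/5)/sqrt(3) - 1)).
    """
    if T_number not in _VALID_T:
        raise ValueError(
            f"T={T_number} is not a Caspar-Klug triangulation number")
    return radius / math.sqrt(
        2.0 * (T_number + 1.0 / (math.sqrt(3.0) * math.tan(math.pi / 5.0)) - 1.0))


def capsid_descriptor_to_scaled(cd: CapsidDescriptor, kBT=KBT_298K) -> dict:
    """Scaled-parameter estimate {sigma, Y, lam, gamma} from capsid mechanics.

    Y = E*h (N/m for E in GPa and h in nm); Lambda = 2 eps0/(sqrt(3) sigma);
    lam = Lambda/(Y R) identifying R0 with the outer radius;
    gamma = 12 (1 - nu_p^2) (R/h)^2.
    """
    R = cd.diameter / 2.0                     # nm
    Y = cd.E * cd.h                           # GPa*nm = N/m
    sigma = capsomer_diameter(R, cd.T_number)  # nm
    eps0 = cd.eps0_kT * kBT                   # J
    Lambda = 2.0 * eps0 / (math.sqrt(3.0) * sigma * 1e-9)   # N
    lam = Lambda / (Y * R * 1e-9)
    gamma = 12.0 * (1.0 - cd.nu_p ** 2) * (R / cd.h) ** 2
    return {"sigma": sigma, "Y": Y, "lam": lam, "gamma": gamma}


def spring_constant_to_E(k_spring, h, R):
    """3-D Young's modulus from an AFM spring constant, thin-shell formula.

    Inverts k = 2.25 E h^2 / R.  With k in N/m and h, R in nm, E is in GPa.
    """
    if k_spring <= 0 or h <= 0 or R <= 0:
        raise ValueError("all inputs must be > 0")
    return k_spring * R / (2.25 * h * h)


def E_to_spring_constant(E, h, R):
    """Thin-shell AFM spring constant k = 2.25 E h^2 / R (E GPa, h/R nm -> N/m)."""
    return 2.25 * E * h * h / R
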