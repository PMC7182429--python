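"""Scaled free energies of formation for partial and closed capsid structures.

The assembly of an empty viral shell is described by classical nucleation
theory with elastic contributions: a partial shell of area S gains bulk
energy -S*dmu/a1, pays a rim penalty Lambda*l(S), and stores stretching and
bending energy because a hexagonal protein crystal cannot wrap a sphere
without strain.  Once energies are scaled by the characteristic elastic
energy 4*pi*R0^2*Y, every candidate structure (defect-free spherical cap,
cap with one or many 5-fold disclinations, ribbon, closed belt, cylinder)
depends on only three dimensionless numbers:

``lam``
    scaled line tension, Lambda/(R0*Y),
``dmu``
    scaled chemical potential, dmu/(Y*a1), set by the free-subunit
    concentration,
``gamma``
    Foeppl-von Karman number, Y*R0^2/kappa, the ratio of stretching to
    bending stiffness.

Sizes are expressed as x = rho0/R0, where rho0 = sqrt(S/pi) is the
flat-equivalent patch radius, and r = R/R0 is the actual shell radius in
units of the spontaneous one.  A spherical structure closes at x = 2*r
(area pi*x^2 = 4*pi*r^2).

Disclination energetics are computed from thin-plate elasticity on a
circular domain: the in-plane energy of a set of disclinations of charge
pi/3 interacting with each other and with the Gaussian-curvature
background follows from the biharmonic Green's function of the clamped
unit disk (Boggio's formula), with the spherical patch mapped onto the
disk by the area-preserving projection.  See ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

__all__ = [
    "DEFECT_ONSET",
    "ScaledParameters",
    "ShellSize",
    "Structure",
    "StructureEnergy",
    "NucleationEstimate",
    "dg_cap_bending",
    "dg_cap_one_defect_bending",
    "dg_shell_n_defects",
    "dg_ribbon_bending",
    "dg_belt",
    "dg_cylinder",
    "dg_cap_general",
    "dg_cap_one_defect_general",
    "optimal_cap_radius",
    "nucleation_estimate",
    "clamped_disk_kernel",
    "disclination_terms",
    "defect_profile",
]

#: Patch size (in units of the shell radius, x/r) above which a central
#: 5-fold disclination lowers the energy of a spherical cap.
DEFECT_ONSET = math.sqrt(2.0 / 3.0)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

class Structure(Enum):
    """Candidate assembly products, in tie-breaking order."""

    CAP_DEFECTLESS = "cap_defectless"
    CAP_ONE_DEFECT = "cap_one_defect"
    SHELL_N_DEFECTS = "shell_n_defects"
    RIBBON = "ribbon"
    BELT = "belt"
    CYLINDER = "cylinder"
    DISASSEMBLED = "disassembled"


@dataclass(frozen=True)
class ScaledParameters:
    """The (lam, dmu, gamma) triple that fully determines the assembly fate."""

    lam: float
    dmu: float
    gamma: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.lam) and np.isfinite(self.dmu)
                and np.isfinite(self.gamma)):
            raise ValueError("scaled parameters must be finite")
        if self.lam < 0:
            raise ValueError(f"scaled line tension must be >= 0, got {self.lam}")
        if self.gamma < 0:
            raise ValueError(f"FvK number must be >= 0, got {self.gamma}")


@dataclass
class ShellSize:
    """Size variables of a structure at (or away from) its energy minimum."""

    x: float
    r: float = 1.0
    w: float | None = None
    n_def: int = 0

    def __post_init__(self):
        if self.x < 0:
            raise ValueError("patch size x must be >= 0")
        if self.r <= 0:
            raise ValueError("scaled radius r must be > 0")


@dataclass
class StructureEnergy:
    """A structure label with its optimal size and minimized scaled energy."""

    structure: Structure
    size: ShellSize
    dg: float
    unbounded: bool = False


@dataclass(frozen=True)
class NucleationEstimate:
    """Elastic-free CNT estimate of the critical cap size and barrier."""

    x_star: float
    dg_star: float


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("patch size x must be >= 0")
    return x


def _bending(x, r, gamma):
    """Scaled generalized-Helfrich bending energy of a spherical patch.

    (kappa/2) * sum of (c_i - 1/R0)^2 over both principal curvatures,
    integrated over the patch area and scaled by 4*pi*R0^2*Y, gives
    x^2 (1/r - 1)^2 / (4*gamma).
    """
    if gamma == 0.0:
        return 0.0
    return x * x * (1.0 / r - 1.0) ** 2 / (4.0 * gamma)


# --------------------------------------------------------------------------
# bending-dominated structures (r pinned to 1)
# --------------------------------------------------------------------------

def dg_cap_bending(x, p: ScaledParameters):
    """Defect-free spherical cap at the spontaneous curvature.

    Bulk gain, rim penalty (flat-perimeter approximation) and the in-plane
    stretching energy of a crystalline circular domain on a sphere.
    """
    x = _check_x(x)
    return -0.25 * p.dmu * x**2 + 0.5 * p.lam * x + x**6 / 1536.0


def dg_cap_one_defect_bending(x, p: ScaledParameters):
    """Spherical cap with one pentagonal disclination at its center.

    The added term (x^2/1152)(1 - (3/2)x^2) is negative -- the defect pays
    off -- only for x >= sqrt(2/3).
    """
    x = _check_x(x)
    return dg_cap_bending(x, p) + (x**2 / 1152.0) * (1.0 - 1.5 * x**2)


def dg_ribbon_bending(x, w, p: ScaledParameters, *, check_belt=True):
    """Open rectangular ribbon of width ``w`` growing on the sphere.

    The ribbon has area pi*x^2 = l*w; its derived length l = pi*x^2/w must
    stay below 2*pi, beyond which the closed belt applies.
    """
    x = _check_x(x)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("ribbon width w must be > 0")
    if check_belt and np.any(np.pi * x**2 / w > 2.0 * np.pi * (1.0 + 1e-12)):
        raise BeltRegime("ribbon length l = pi x^2 / w exceeds 2 pi; "
                         "use dg_belt for the closed structure")
    return (-0.25 * p.dmu * x**2 + 0.5 * p.lam * x**2 / w
            + 0.5 * p.lam * w / np.pi + (9.0 / 20480.0) * x**2 * w**4)


class BeltRegime(ValueError):
    """Raised when an open ribbon has grown past closure (l > 2 pi)."""


def dg_belt(x, p: ScaledParameters, r=1.0):
    """Closed belt (ribbon wrapped around a full circumference).

    Algebraically the open ribbon at w = x^2/2 and l = 2*pi, except that
    the closed rim contributes lam*r instead of open side edges.
    """
    x = _check_x(x)
    if p.gamma == 0.0 and r != 1.0:
        raise ValueError("r must be 1 in the bending-dominated limit (gamma=0)")
    return (-0.25 * p.dmu * x**2 + p.lam * r
            + (9.0 / 327680.0) * x**10 / r**8 + _bending(x, r, p.gamma))


def dg_cylinder(x, p: ScaledParameters, r=1.0):
    """Cylinder of radius r*R0: no stretching, bending on one curvature only.

    Grows unboundedly (dg -> -inf with size) when dmu > 1/(2*gamma).
    """
    if p.gamma == 0.0:
        raise ValueError("cylinders are suppressed in the bending-dominated "
                         "limit (gamma=0): bending cost diverges on the scale "
                         "of the elastic energy")
    x = _check_x(x)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    return (-0.25 * p.dmu * x**2 + p.lam * r
            + x * x * (1.0 + (1.0 / r - 1.0) ** 2) / (8.0 * p.gamma))


# --------------------------------------------------------------------------
# general-FvK structures
# --------------------------------------------------------------------------

def dg_cap_general(x, p: ScaledParameters, r=1.0):
    """Defect-free spherical cap of radius r*R0 at arbitrary FvK number."""
    x = _check_x(x)
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be > 0")
    if p.gamma == 0.0 and not np.allclose(r, 1.0):
        raise ValueError("r must be 1 in the bending-dominated limit (gamma=0)")
    return (-0.25 * p.dmu * x**2 + 0.5 * p.lam * x
            + x**6 / (1536.0 * np.asarray(r, dtype=float)**4)
            + _bending(x, r, p.gamma))


def dg_cap_one_defect_general(x, p: ScaledParameters, r=1.0):
    """Cap of radius r*R0 with one central disclination; onset at x/r = sqrt(2/3)."""
    x = _check_x(x)
    return (dg_cap_general(x, p, r)
            + (x**2 / 1152.0) * (1.0 - 1.5 * x**2 / np.asarray(r, dtype=float)**2))


def optimal_cap_radius(x, gamma):
    """Optimal radius of a defect-free cap: the root r >= 1 of r^2(r-1) = gamma x^4/192.

    The left side is strictly increasing for r >= 1, so the root is unique;
    it is found in closed form (Cardano) and polished with one Newton step.
    """
    x = _check_x(x)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    c = gamma * x**4 / 192.0
    # depressed cubic t^3 + p t + q with r = t + 1/3
    q = -(2.0 / 27.0 + c)
    disc = q * q / 4.0 - 1.0 / 729.0   # (q/2)^2 + (p/3)^3 with p = -1/3
    sq = np.sqrt(np.maximum(disc, 0.0))
    t = np.cbrt(-q / 2.0 + sq) + np.cbrt(-q / 2.0 - sq)
    r = t + 1.0 / 3.0
    # one Newton polish against round-off for tiny c
    f = r * r * (r - 1.0) - c
    df = 3.0 * r * r - 2.0 * r
    r = np.where(df > 0, r - f / np.where(df > 0, df, 1.0), r)
    return np.maximum(r, 1.0) if np.ndim(r) else float(max(r, 1.0))


def nucleation_estimate(p: ScaledParameters) -> NucleationEstimate:
    """CNT critical size and barrier of the initial cap, neglecting elasticity.

    x* = lam/dmu and dg* = lam^2/(4 dmu); accurate whenever the stretching
    term at x* is small against the barrier.
    """
    if p.dmu <= 0:
        raise ValueError("no nucleation barrier: assembly is not favored for dmu <= 0")
    return NucleationEstimate(x_star=p.lam / p.dmu,
                              dg_star=p.lam**2 / (4.0 * p.dmu))


# --------------------------------------------------------------------------
# disclination energetics on the (partial) shell
# --------------------------------------------------------------------------
#
# The spherical patch of area pi x^2 on a sphere of scaled radius r is mapped
# area-preservingly onto a flat disk; disclinations of charge pi/3 then
# interact through the biharmonic Green's function of the clamped unit disk,
#
#   ghat(z, w) = |z-w|^2 ln(|z-w|^2 / |1 - conj(z) w|^2) + (1-|z|^2)(1-|w|^2),
#
# which reproduces the printed self-energy x^2/1152, the curvature screening
# -(3/2) x^2/r^2 and the background term x^6/(1536 r^4) exactly.  Scaled
# energies:  self+screening per defect (x^2/1152)(1-beta^2)^2 (1-(3/2)x^2/r^2)
# and (x^2/576) ghat per pair.  Positions minimize the total; the optimum is
# always of the form "optional central defect + one symmetric ring + excess
# defects parked at the rim (where the kernel vanishes)".

def clamped_disk_kernel(z, w):
    """Biharmonic Green's function kernel of the clamped unit disk (x 16 pi).

    Vanishes when either argument reaches the rim |z| = 1.
    """
    z = np.asarray(z, dtype=complex)
    w = np.asarray(w, dtype=complex)
    u2 = np.abs(z - w) ** 2
    v2 = np.abs(1.0 - np.conj(z) * w) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(u2 > 0, u2 * np.log(np.where(u2 > 0, u2, 1.0) / v2), 0.0)
    return logterm + (1.0 - np.abs(z) ** 2) * (1.0 - np.abs(w) ** 2)


def _ring_layout(c, k, b):
    """Positions of c (0/1) central defects plus a ring of k at radius b."""
    z = [0.0 + 0.0j] * c
    z += [b * np.exp(2j * np.pi * i / k) for i in range(k)]
    return np.array(z, dtype=complex)


def _ring_energy(c, k, b, a_self):
    """Position-dependent part of the defect energy, D-units.

    D = a_self * sum_i (1-beta_i^2)^2 + sum_{i<j} ghat(z_i, z_j), with
    a_self = (1 - (3/2) s^2)/2 for s = x/r.  Closed form for the symmetric
    center + ring layout.
    """
    e = 0.0
    f_ring = (1.0 - b * b) ** 2
    e += a_self * (c * 1.0 + k * f_ring)
    if c and k:
        # center-ring pairs: ghat(0, b) = b^2 ln b^2 + (1 - b^2)
        g0 = b * b * math.log(b * b) + (1.0 - b * b) if b > 0 else 1.0
        e += k * g0
    if k > 1:
        d = np.arange(1, k)
        cosd = np.cos(2.0 * np.pi * d / k)
        u2 = 2.0 * b * b * (1.0 - cosd)
        v2 = 1.0 - 2.0 * b * b * cosd + b**4
        ghat = np.where(u2 > 0, u2 * np.log(np.maximum(u2, 1e-300) / v2), 0.0) \
            + f_ring
        # k unordered pairs for every separation d counted twice (d, k-d)
        e += 0.5 * k * ghat.sum()
    return e


def _optimal_D(n, s):
    """Minimum defect energy D(n, s) over relaxed symmetric arrangements.

    D multiplies x^2/576 in the free energy.  Parking a defect exactly at
    the rim contributes zero, so D <= 0 always.
    """
    a_self = 0.5 * (1.0 - 1.5 * s * s)
    best = 0.0
    for c in (0, 1):
        if c == 1:
            best = min(best, a_self)  # central defect only
        for k in range(1, n - c + 1):
            res = minimize_scalar(lambda b: _ring_energy(c, k, b, a_self),
                                  bounds=(1e-4, 1.0 - 1e-6), method="bounded",
                                  options={"xatol": 1e-10})
            best = min(best, res.fun)
    return best


_S_GRID = np.linspace(0.0, 2.0, 161)


@lru_cache(maxsize=None)
def defect_profile(n_def: int) -> PchipInterpolator:
    """Cached interpolant of D(n, s) on s = x/r in [0, 2].

    For n_def = 1 the defect is pinned at the cap center and
    D = (1 - (3/2) s^2)/2 exactly (no relaxation), so that the one-defect
    cap reduces identically to the printed single-disclination energy.
    """
    if not 1 <= n_def <= 12:
        raise ValueError("disclination count must be between 1 and 12 "
                         "(a closed icosahedral shell carries exactly 12)")
    if n_def == 1:
        return PchipInterpolator(_S_GRID, 0.5 * (1.0 - 1.5 * _S_GRID**2))
    vals = np.array([_optimal_D(n_def, s) for s in _S_GRID])
    return PchipInterpolator(_S_GRID, vals)


def dg_shell_n_defects(x, n_def, p: ScaledParameters, r=1.0):
    """Spherical shell of radius r*R0 carrying ``n_def`` 5-fold disclinations.

    Base cap energy plus the disclination self-energies (gs1) and pairwise
    interactions (gs2) at their relaxed symmetric arrangement.  Reduces to
    the one-central-defect energy for n_def = 1 and closes at x = 2*r.
    """
    n_def = int(n_def)
    if not 1 <= n_def <= 12:
        raise ValueError("disclination count must be between 1 and 12 "
                         "(a closed icosahedral shell carries exactly 12)")
    x = _check_x(x)
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be > 0")
    if np.any(x > 2.0 * np.asarray(r) * (1 + 1e-9)):
        raise ValueError("spherical patch closes at x = 2 r")
    s = np.clip(x / r, 0.0, 2.0)
    if n_def == 1:
        return dg_cap_one_defect_general(x, p, r)
    D = defect_profile(n_def)(s)
    return dg_cap_general(x, p, r) + x * x / 576.0 * D


def disclination_terms(x, n_def, r=1.0):
    """Return (gs1, gs2): defect self-energies and pairwise interaction.

    Recomputed exactly (not from the cached table) at the relaxed optimal
    arrangement; ``gs1 + gs2`` agrees with the table route to interpolation
    accuracy.  For n_def = 1 the defect sits at the center and gs2 = 0.
    """
    x = float(x)
    if x == 0:
        return 0.0, 0.0
    s = min(x / r, 2.0)
    a_self = 0.5 * (1.0 - 1.5 * s * s)
    if n_def == 1:
        return (x * x / 1152.0) * (1.0 - 1.5 * s * s), 0.0
    # re-run the ansatz search, keeping the winning layout
    best = (0.0, (0, 0, 0.0))
    for c in (0, 1):
        if c == 1 and a_self < best[0]:
            best = (a_self, (1, 0, 0.0))
        for k in range(1, n_def - c + 1):
            res = minimize_scalar(lambda b: _ring_energy(c, k, b, a_self),
                                  bounds=(1e-4, 1.0 - 1e-6), method="bounded",
                                  options={"xatol": 1e-10})
            if res.fun < best[0]:
                best = (res.fun, (c, k, res.x))
    c, k, b = best[1]
    z = _ring_layout(c, k, b)
    fsum = float(np.sum((1.0 - np.abs(z) ** 2) ** 2))
    gs1 = (x * x / 1152.0) * (1.0 - 1.5 * s * s) * fsum
    gsum = 0.0
    for i in range(len(z)):
        for j in range(i + 1, len(z)):
            gsum += float(clamped_disk_kernel(z[i], z[j]))
    gs2 = x * x / 576.0 * gsum
    return gs1, gs2
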