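"""Brownian-dynamics engine for the coarse-grained capsomer model.

Capsomers are spheres carrying an orientation unit vector Omega.  A pair
interacts through the product of a Mie potential (binding + excluded
volume), two angular Gaussians favoring a preferred protein-protein
contact angle nu (which encodes the spontaneous curvature), and a torsion
factor distinguishing the inner and outer shell surfaces:

    V = V_Mie * V_ang * V_tor,
    V_Mie(r)  = eps n/(m-n) [ (s/r)^m - (m/n)(s/r)^n ],
    V_ang     = exp(-(theta_ij - nu)^2 / 2 alpha^2)
              * exp(-(theta_ji - nu)^2 / 2 alpha^2),
    V_tor     = exp(-kt (1 - cos xi)^2),

with theta_ij the angle between Omega_i and the center-to-center unit
vector, and xi the angle between the planes spanned by that vector and the
two orientations.  By default the angular and torsion factors modulate
only the attractive part of the Mie potential (the repulsive core stays
orientation-independent, so misaligned capsomers still exclude volume); a
``strict_product`` mode modulates the full Mie term instead.

Dynamics are overdamped with a stochastic Euler integrator in reduced
units (sigma = 1, eps0 = 1, translational diffusion D = 1): positions move
by (F/T) dt plus Gaussian noise of variance 2 dt per coordinate, and
orientations rotate in the tangent space of the unit sphere with
rotational diffusion Dr = 3 (stick-sphere ratio 3 D / sigma^2).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .mapping import PotentialParameters

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "pair_energy",
    "forces_and_torques",
    "total_energy",
    "bd_step",
    "build_seed_cap",
    "run_assembly",
    "NUMBA_ENABLED",
]

_MIN_SEP = 0.5       # below this separation (units of sigma) forces are clamped
_FORCE_CLAMP = 1e4
_EPS = 1e-12


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for a seeded assembly simulation (reduced units)."""

    pp: PotentialParameters = field(default_factory=PotentialParameters)
    N_total: int = 60
    density: float = 0.02        # number density, sigma^-3
    T_red: float = 0.1           # kT/eps0; 0.1 means a 10 kT binding energy
    n_steps: int = 10000
    seed_size: int = 19
    cutoff: float = 2.5
    dt: float = 5e-5
    Dr: float = 3.0              # rotational diffusion, units D/sigma^2
    strict_product: bool = False
    snapshot_every: int = 0      # 0 -> n_steps // 10

    def __post_init__(self):
        if self.N_total < self.seed_size:
            raise ValueError("N_total must be >= seed_size")
        if self.T_red <= 0:
            raise ValueError("reduced temperature must be > 0")


@dataclass
class SimulationState:
    """Positions, orientations and bookkeeping of all capsomers."""

    positions: np.ndarray        # (N, 3), units of sigma
    orientations: np.ndarray     # (N, 3), unit vectors
    box: float
    time_step: float = 5e-5
    rng_seed: int = 0
    step_count: int = 0

    def copy(self) -> "SimulationState":
        return SimulationState(self.positions.copy(), self.orientations.copy(),
                               self.box, self.time_step, self.rng_seed,
                               self.step_count)


# --------------------------------------------------------------------------
# pair interaction
# --------------------------------------------------------------------------

def _mie(r, m, n, eps, sig):
    sr = sig / r
    return eps * n / (m - n) * (sr**m - (m / n) * sr**n)


def pair_energy(r_vec, Omega_i, Omega_j, pp: PotentialParameters,
                strict_product=False):
    """Raw pair energy (no cutoff shift) of two capsomers.

    ``r_vec`` points from capsomer i to capsomer j.  At contact
    (r = sigma) with both angles at nu and zero torsion the energy is
    exactly -eps0.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    u = r_vec / r
    ci = float(np.dot(Omega_i, u))
    cj = float(np.dot(Omega_j, -u))
    th_i = math.acos(max(-1.0, min(1.0, ci)))
    th_j = math.acos(max(-1.0, min(1.0, cj)))
    fa = math.exp(-((th_i - pp.nu) ** 2) / (2 * pp.alpha**2)) \
        * math.exp(-((th_j - pp.nu) ** 2) / (2 * pp.alpha**2))
    pi_ = Omega_i - ci * u
    pj_ = Omega_j + cj * u
    npi, npj = np.linalg.norm(pi_), np.linalg.norm(pj_)
    cosxi = 1.0 if npi < _EPS or npj < _EPS else float(np.dot(pi_, pj_) / (npi * npj))
    cosxi = max(-1.0, min(1.0, cosxi))
    ftor = math.exp(-pp.kt * (1.0 - cosxi) ** 2)
    vmie = _mie(r, pp.m, pp.n, pp.eps0, pp.sigma)
    if strict_product:
        return vmie * fa * ftor
    if r < pp.sigma:
        vrep, vatt = vmie + pp.eps0, -pp.eps0
    else:
        vrep, vatt = 0.0, vmie
    return vrep + vatt * fa * ftor


# --------------------------------------------------------------------------
# force/torque kernel (pure python; numba-jitted when available)
# --------------------------------------------------------------------------

def _kernel(pos, ori, box, m, n, eps, sig, nu, alpha, kt, rc, shift,
            strict, F, G):
    """Accumulate forces and orientation gradients; returns total energy."""
    N = pos.shape[0]
    c2 = rc * rc
    energy = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if box > 0.0:
                dx -= box * round(dx / box)
                dy -= box * round(dy / box)
                dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= c2 or r2 <= 0.0:
                continue
            r = math.sqrt(r2)
            ux, uy, uz = dx / r, dy / r, dz / r
            sr = sig / r
            srn = sr**n
            srm = sr**m
            vm = eps * n / (m - n) * (srm - (m / n) * srn)
            dvm = eps * n / (m - n) * (-m * srm + m * srn) / r
            if strict:
                vrep, dvrep = 0.0, 0.0
                w, dw = vm - shift, dvm
            elif r < sig:
                vrep, dvrep = vm + eps, dvm
                w, dw = -eps - shift, 0.0
            else:
                vrep, dvrep = 0.0, 0.0
                w, dw = vm - shift, dvm
            ci = ori[i, 0] * ux + ori[i, 1] * uy + ori[i, 2] * uz
            cj = -(ori[j, 0] * ux + ori[j, 1] * uy + ori[j, 2] * uz)
            ci = max(-1.0, min(1.0, ci))
            cj = max(-1.0, min(1.0, cj))
            thi = math.acos(ci)
            thj = math.acos(cj)
            fi = math.exp(-((thi - nu) ** 2) / (2.0 * alpha * alpha))
            fj = math.exp(-((thj - nu) ** 2) / (2.0 * alpha * alpha))
            sini = math.sqrt(max(1.0 - ci * ci, 1e-16))
            sinj = math.sqrt(max(1.0 - cj * cj, 1e-16))
            dfi = fi * (thi - nu) / (alpha * alpha * sini)
            dfj = fj * (thj - nu) / (alpha * alpha * sinj)
            # in-plane components of the orientations
            pix = ori[i, 0] - ci * ux
            piy = ori[i, 1] - ci * uy
            piz = ori[i, 2] - ci * uz
            pjx = ori[j, 0] + cj * ux
            pjy = ori[j, 1] + cj * uy
            pjz = ori[j, 2] + cj * uz
            npi = math.sqrt(pix * pix + piy * piy + piz * piz)
            npj = math.sqrt(pjx * pjx + pjy * pjy + pjz * pjz)
            degen = npi < 1e-8 or npj < 1e-8
            if degen:
                cosxi = 1.0
                ftor = 1.0
                dtor = 0.0
            else:
                nix, niy, niz = pix / npi, piy / npi, piz / npi
                njx, njy, njz = pjx / npj, pjy / npj, pjz / npj
                cosxi = nix * njx + niy * njy + niz * njz
                cosxi = max(-1.0, min(1.0, cosxi))
                ftor = math.exp(-kt * (1.0 - cosxi) ** 2)
                dtor = ftor * 2.0 * kt * (1.0 - cosxi)
            ang = fi * fj * ftor
            energy += vrep + w * ang
            # radial part
            gr = dvrep + dw * ang
            gx = gr * ux
            gy = gr * uy
            gz = gr * uz
            # angular parts through ci, cj
            a_i = w * dfi * fj * ftor
            a_j = w * fi * dfj * ftor
            gx += a_i * pix / r - a_j * pjx / r
            gy += a_i * piy / r - a_j * pjy / r
            gz += a_i * piz / r - a_j * pjz / r
            # torsion part
            if not degen:
                t = w * fi * fj * dtor
                qix = (njx - cosxi * nix) / npi
                qiy = (njy - cosxi * niy) / npi
                qiz = (njz - cosxi * niz) / npi
                qjx = (nix - cosxi * njx) / npj
                qjy = (niy - cosxi * njy) / npj
                qjz = (niz - cosxi * njz) / npj
                gx += t * (-ci * qix + cj * qjx) / r
                gy += t * (-ci * qiy + cj * qjy) / r
                gz += t * (-ci * qiz + cj * qjz) / r
            # clamp deep overlaps
            if r < _MIN_SEP:
                gn = math.sqrt(gx * gx + gy * gy + gz * gz)
                if gn > _FORCE_CLAMP:
                    sc = _FORCE_CLAMP / gn
                    gx *= sc
                    gy *= sc
                    gz *= sc
            # force on i is +dV/dr_vec, on j the opposite
            F[i, 0] += gx
            F[i, 1] += gy
            F[i, 2] += gz
            F[j, 0] -= gx
            F[j, 1] -= gy
            F[j, 2] -= gz
            # orientation gradients (negative -> aligning generalized force)
            oi = w * dfi * fj * ftor
            oj = w * fi * dfj * ftor
            G[i, 0] -= oi * ux
            G[i, 1] -= oi * uy
            G[i, 2] -= oi * uz
            G[j, 0] += oj * ux
            G[j, 1] += oj * uy
            G[j, 2] += oj * uz
            if not degen:
                t = w * fi * fj * dtor
                G[i, 0] -= t * qix
                G[i, 1] -= t * qiy
                G[i, 2] -= t * qiz
                G[j, 0] -= t * qjx
                G[j, 1] -= t * qjy
                G[j, 2] -= t * qjz
    return energy


try:  # optional numba acceleration of the O(N^2) pair loop
    import numba

    _kernel_fast = numba.njit(cache=True, fastmath=False)(_kernel)
    NUMBA_ENABLED = True
except ImportError:  # pragma: no cover - numba is normally present
    _kernel_fast = _kernel
    NUMBA_ENABLED = False


def _evaluate(state: SimulationState, config: SimulationConfig, fast=True):
    pp = config.pp
    N = len(state.positions)
    F = np.zeros((N, 3))
    G = np.zeros((N, 3))
    shift = _mie(config.cutoff * pp.sigma, pp.m, pp.n, pp.eps0, pp.sigma)
    kern = _kernel_fast if fast else _kernel
    E = kern(state.positions, state.orientations, float(state.box),
             float(pp.m), float(pp.n), pp.eps0, pp.sigma, pp.nu, pp.alpha,
             pp.kt, config.cutoff * pp.sigma, shift,
             config.strict_product, F, G)
    return E, F, G


def forces_and_torques(state: SimulationState, config: SimulationConfig):
    """Forces and tangent-projected orientation torques on every capsomer.

    Returns (F, G): F is the negative position gradient of the total pair
    energy; G the negative orientation gradient projected onto the tangent
    space of the unit sphere (so G . Omega = 0).
    """
    _, F, G = _evaluate(state, config)
    proj = np.einsum("ij,ij->i", G, state.orientations)
    G = G - proj[:, None] * state.orientations
    return F, G


def total_energy(state: SimulationState, config: SimulationConfig) -> float:
    """Total (cutoff-shifted) pair energy of the configuration."""
    E, _, _ = _evaluate(state, config)
    return float(E)


# --------------------------------------------------------------------------
# integrator
# --------------------------------------------------------------------------

def bd_step(state: SimulationState, config: SimulationConfig,
            rng: np.random.Generator) -> SimulationState:
    """One overdamped Euler step (in place); returns the state.

    Reduced units: D = 1 so the translational mobility is 1/T_red, the
    noise variance 2 dt per coordinate; rotational diffusion Dr applies to
    the orientation vectors, which are renormalized every step.
    """
    dt = config.dt
    F, G = forces_and_torques(state, config)
    mu_t = 1.0 / config.T_red
    mu_r = config.Dr / config.T_red
    disp = mu_t * F * dt
    maxd = float(np.max(np.abs(disp))) if len(disp) else 0.0
    if maxd > 0.25:
        warnings.warn(
            f"BD displacement {maxd:.3g} sigma in one step exceeds 0.25 sigma; "
            "reduce dt or check for overlapping capsomers", stacklevel=2)
    if config.T_red > 0:
        disp = disp + math.sqrt(2.0 * dt) * rng.standard_normal(disp.shape)
    state.positions += disp
    if state.box > 0:
        state.positions %= state.box
    dori = mu_r * G * dt
    if config.T_red > 0:
        eta = math.sqrt(2.0 * config.Dr * dt) * rng.standard_normal(dori.shape)
        eta -= np.einsum("ij,ij->i", eta, state.orientations)[:, None] \
            * state.orientations
        dori = dori + eta
    state.orientations += dori
    state.orientations /= np.linalg.norm(state.orientations, axis=1,
                                         keepdims=True)
    state.step_count += 1
    return state


# --------------------------------------------------------------------------
# initial configurations
# --------------------------------------------------------------------------

def build_seed_cap(pp: PotentialParameters, seed_size: int = 19):
    """Hexagonally packed cap of capsomers on the spontaneous-curvature sphere.

    Points of a flat hexagonal lattice (spacing sigma) are wrapped onto a
    sphere of radius R0 = sigma/(2|cos nu|) by the exponential map;
    orientations point along the outward radial.  Returns (positions,
    orientations) with the sphere center at the origin and the cap at the
    north pole.
    """
    if seed_size < 7:
        raise ValueError("seed must contain at least a capsomer and its ring "
                         "(seed_size >= 7)")
    cn = math.cos(pp.nu)
    if abs(cn) < 1e-6:
        raise ValueError("nu too close to pi/2: spontaneous radius diverges, "
                         "no spherical seed can be built")
    R0 = pp.sigma / (2.0 * abs(cn))
    # nu below pi/2: orientations point into the sphere; above: outward
    ori_sign = -1.0 if cn > 0 else 1.0
    # hexagonal lattice points sorted by distance (then angle, for determinism)
    pts = []
    k = int(math.ceil(math.sqrt(seed_size))) + 2
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            x = pp.sigma * (i + 0.5 * j)
            y = pp.sigma * (math.sqrt(3.0) / 2.0) * j
            pts.append((math.hypot(x, y), math.atan2(y, x), x, y))
    pts.sort(key=lambda t: (round(t[0], 9), round(t[1], 9)))
    pos = np.empty((seed_size, 3))
    ori = np.empty((seed_size, 3))
    for idx in range(seed_size):
        d, phi = pts[idx][0], pts[idx][1]
        th = d / R0
        n_vec = np.array([math.sin(th) * math.cos(phi),
                          math.sin(th) * math.sin(phi),
                          math.cos(th)])
        pos[idx] = R0 * n_vec
        ori[idx] = ori_sign * n_vec
    return pos, ori


def _place_free(rng, pos_existing, n_free, box, min_sep, max_tries):
    out = []
    tries = 0
    occupied = list(pos_existing)
    while len(out) < n_free:
        cand = rng.uniform(0.0, box, size=3)
        d = np.array(occupied) - cand
        d -= box * np.round(d / box)
        if np.all(np.einsum("ij,ij->i", d, d) > min_sep * min_sep):
            out.append(cand)
            occupied.append(cand)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_free} capsomers at density with "
                f"min separation {min_sep}; lower the density")
    return np.array(out)


def run_assembly(config: SimulationConfig, seed: int = 0,
                 progress_log_every: int = 0):
    """Seeded assembly run: cap seed + random free capsomers, Euler BD.

    Returns ``(trajectory, final_state)``; the trajectory is a list of
    state snapshots including the initial and final configurations.
    Deterministic for a given ``seed``.
    """
    pp = config.pp
    rng = np.random.default_rng(seed)
    box = (config.N_total / config.density) ** (1.0 / 3.0)
    cap_pos, cap_ori = build_seed_cap(pp, config.seed_size)
    # center the cap's centroid in the box
    cap_pos = cap_pos - cap_pos.mean(axis=0) + box / 2.0
    n_free = config.N_total - config.seed_size
    if n_free > 0:
        free_pos = _place_free(rng, cap_pos, n_free, box,
                               min_sep=0.9 * pp.sigma,
                               max_tries=2000 * max(n_free, 1))
        free_ori = rng.standard_normal((n_free, 3))
        free_ori /= np.linalg.norm(free_ori, axis=1, keepdims=True)
        pos = np.vstack([cap_pos, free_pos])
        ori = np.vstack([cap_ori, free_ori])
    else:
        pos, ori = cap_pos, cap_ori
    state = SimulationState(positions=pos, orientations=ori, box=box,
                            time_step=config.dt, rng_seed=seed)
    every = config.snapshot_every or max(config.n_steps // 10, 1)
    traj = [state.copy()]
    for step in range(config.n_steps):
        bd_step(state, config, rng)
        if (step + 1) % every == 0:
            traj.append(state.copy())
        if progress_log_every and (step + 1) % progress_log_every == 0:
            logger.info("step %d / %d, E = %.4f", step + 1, config.n_steps,
                        total_energy(state, config))
    if traj[-1].step_count != state.step_count:
        traj.append(state.copy())
    return traj, state
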