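# Methods

## Model

A partial capsid of area S = pi rho0^2 growing from a solution of
capsomers is described by classical nucleation theory with elastic
contributions:

    dG = -(S/a1) dmu + Lambda * l(S) + G_stretch + G_bend.

The bulk term rewards adding subunits (dmu = kT ln(c1/c*) > 0 drives
assembly), the rim term penalizes the open edge, and the elastic terms
penalize the strain a hexagonally ordered 2-D crystal accumulates on a
curved surface.  Scaling energies by 4 pi R0^2 Y (Y the 2-D Young's
modulus, R0 the spontaneous curvature radius) and sizes by
x = rho0/R0, r = R/R0 leaves exactly three dimensionless controls:

* `lam = Lambda/(R0 Y)` - scaled line tension,
* `dmu~ = dmu/(Y a1)` - scaled chemical potential,
* `gamma = Y R0^2/kappa` - Foeppl-von Karman number (stretching vs
  bending stiffness).

Candidate structures and their scaled formation energies (bending-
dominated limit, r = 1; the general-`gamma` forms add the
generalized-Helfrich bending term `x^2 (1/r - 1)^2 / (4 gamma)` and
divide stretching terms by the appropriate powers of r):

| structure           | energy                                                        |
|---------------------|---------------------------------------------------------------|
| defect-free cap     | `-(dmu~/4) x^2 + (lam/2) x + x^6/1536`                        |
| cap, 1 disclination | cap + `(x^2/1152)(1 - (3/2) x^2)`                             |
| shell, n discl.     | cap + `gs1 + gs2` (below)                                     |
| ribbon (width w)    | `-(dmu~/4) x^2 + (lam/2)(x^2/w) + (lam/2pi) w + (9/20480) x^2 w^4` |
| closed belt         | `-(dmu~/4) x^2 + lam r + (9/327680) x^10 / r^8`               |
| cylinder            | `-(dmu~/4) x^2 + lam r + x^2 (1 + (1/r-1)^2)/(8 gamma)`       |

A spherical patch closes at x = 2r (area = full sphere).  The defect-free
cap's optimal radius solves `r^2 (r-1) = gamma x^4 / 192` (unique root
r >= 1, found by Cardano's formula plus one Newton polish).  The cylinder
has no stretching cost and grows without bound when `dmu~ > 1/(2 gamma)`.
The rim term uses the flat-disk perimeter `2 pi rho0` throughout (the
approximation underlying the cap formulas); at closure this leaves a
residual `lam * r`, which is retained for consistency with the partial-cap
branch of the same family.

## Disclination energetics

The in-plane elasticity of the defective cap is evaluated in the
flat-metric approximation that also underlies the x^6/1536 background
term: the patch is mapped area-preservingly onto a disk
(beta = (2r/x) sin(theta/2) for a point at polar angle theta), and
disclinations of charge pi/3 interact with each other and with the
Gaussian-curvature background through the biharmonic Green's function of
the clamped unit disk (Boggio's formula),

    ghat(z, w) = |z-w|^2 ln(|z-w|^2/|1 - conj(z) w|^2)
                 + (1-|z|^2)(1-|w|^2).

This single kernel reproduces, exactly, the background energy
x^6/(1536 r^4), the central-defect self-energy x^2/1152 (the flat-disk
disclination energy s^2 Y rho^2/(32 pi) with s = pi/3), and the
curvature-screening factor -(3/2) x^2/r^2.  For a defect at fractional
radius beta:

    gs1 = sum_i (x^2/1152) (1 - beta_i^2)^2 (1 - (3/2) x^2/r^2)
    gs2 = (x^2/576) sum_{i<j} ghat(z_i, z_j).

The kernel vanishes on the rim, so a disclination parked at the boundary
costs (and screens) nothing.

**Defect arrangement.**  A single disclination is kept at the cap center
(its energetically preferred position to a very good approximation).  For
n >= 2 the positions are *relaxed*: the energy is minimized over defect
positions at every (n, x/r).  Unconstrained 24-parameter minimization is
reproduced exactly (checked for n = 2..12 across the size range) by a
"center + one symmetric ring + rim-parked excess" ansatz, which is what
the implementation uses, tabulated per n on a dense x/r grid and
interpolated monotonically (PCHIP).  At closure the relaxed optimum is a
central defect plus a hexagonal ring at beta = 0.545 with the remaining
five defects at the (cost-free) rim, giving a closed-shell elastic energy
of 0.001457 (units of 4 pi R0^2 Y).  Two consequences anchor the phase
diagram:

* the belt/defect-shell frontier at gamma = 0 lands at dmu~ = 0.00201,
  independent of lam (0.00201 at lam = 1e-4, 0.00201 at 5e-4);
* the critical FvK number 1/(2 x 0.00201) = 248 at which the cylinder
  runaway threshold meets the frontier.

A pinned icosahedral-projection arrangement instead gives a closed-shell
energy of 0.00167 and a frontier of 0.00234; the exact closed-sphere
(spherical-harmonic) evaluation of twelve icosahedral disclinations gives
0.00210 and a frontier of 0.0028.  Both are retained as cross-checks in
the test suite; the relaxed flat-disk model is the implementation.

**Known consequence.**  Because the relaxed multi-defect shell can always
imitate (or undercut) the single-central-defect cap, the narrow
"frustrated cap with one disclination" wedge of the bending-dominated
phase diagram closes: near the belt/cap/shell triple point
(lam ~ 5e-4, dmu~ ~ 0.002) the one-defect cap loses to the closed shell
by margins of order 1e-5.  Constraining the arrangement (defects pinned
at icosahedral sites) reopens the wedge but moves the frontier and the
critical FvK number by 15-20%.  The package keeps the thermodynamically
consistent relaxed model; the one-defect structure remains available and
is reported as a near-degenerate runner-up in that region.

## Phase classification

Per point, every structure is minimized over its size variables: dense
vectorized scans (the landscape has a barrier-then-well shape that traps
local minimizers) followed by deterministic zoom rounds; x in (0, 2r] for
spherical structures, x <= sqrt(2 pi) r for the belt (full wrap), r in
[0.3, 3] by nested scanning where no stationarity condition exists, and
the Cardano root for the defect-free cap.  Disassembled means every
minimum is >= 0; exact ties report the earlier structure in the fixed
enum order and set a coexistence flag; within the n-defect family ties
resolve to the largest n (closing a sphere requires twelve disclinations).
`critical_gamma_no_spheres` uses the analytic criterion
`1/(2 gamma) = frontier` with the bending-dominated frontier; with full
radius relaxation the belt gains more than the shell at large gamma, so
shells actually disappear slightly earlier (~gamma = 211) and grids above
the returned value are always shell-free.

## Parameter mappings

From the coarse-grained potential: Y = 2 n m eps0/(sqrt(3) sigma^2),
kappa = 3 sqrt(3) eps0/(8 alpha^2), R0 = sigma/(2 |cos nu|),
Lambda = 2 eps0/(sqrt(3) sigma), a1 = pi sigma^2/4 (the subunit's
projected disk; this convention is forced by the identity
dmu~ = (2 sqrt(3)/(pi n m)) dmu/eps0 and is verified by a round-trip
test).  Two sign conventions for nu are accepted (orientations inward
with nu < pi/2, or outward with nu > pi/2); nu = pi/2 means a flat sheet
and is rejected.  For experimental capsids: Y = E h; capsomer diameter
sigma = R / sqrt(2 (T + cot(pi/5)/sqrt(3) - 1)); eps0 = 10 kT with
kT = 4.11e-21 J (298 K; the lambda estimates shift by under 2% across any
reasonable lab temperature); R0 identified with the outer radius;
gamma = 12 (1 - nu_p^2)(R/h)^2 with nu_p = 0.3.

## Simulator

Capsomers are spheres with an orientation unit vector.  Pair energy
V = V_Mie * V_ang * V_tor (see `capshell.bd`); by default the angular and
torsion factors modulate only the attractive branch of the Mie term, so
the excluded-volume core is orientation-independent (a literal product
would switch repulsion off at unfavorable angles); `strict_product=True`
gives the literal form.  Forces and orientation torques are analytic
gradients (verified against central differences to ~1e-9 relative away
from the hard core; inside the steep core finite differences themselves
lose accuracy).  Integration is overdamped Euler in reduced units
(sigma = eps0 = D = 1): mobility 1/T_red, translational noise variance
2 dt per coordinate, rotational diffusion Dr = 3 (stick-sphere ratio
3 D/sigma^2, a convention - the model does not fix it), orientations
renormalized every step.  Defaults: dt = 5e-5, cutoff 2.5 sigma with
energy shift, kt = 1.5, T_red = 0.1 (a 10 kT contact).  The O(N^2) pair
loop is numba-jitted when numba is importable, with a pure-Python
fallback tested for bit-level agreement; at the N <= 400 of seeded runs
no neighbor list is needed.

Seeded runs start from a 19-capsomer hexagonal cap wrapped onto the
spontaneous sphere (nearest neighbors within 5% of sigma) plus free
capsomers placed uniformly without overlap; runs are bit-reproducible
given the seed.

## What the synthetic runs do and do not show

The published protocol (2e9 steps, N = 200-400, sweeping concentration)
maps simulation outcomes onto the theoretical diagram.  Desk-scale tests
use N <= 60 and ~1e5 steps: enough to verify seed growth at high
concentration, and seed dissolution when starved - the latter at
T_red = 0.25, because at T_red = 0.1 each rim capsomer holds 20-30 kT of
contacts and dissolution is astronomically slow at short times.  These
runs demonstrate the assembly/no-assembly contrast across the drive
threshold; they do not reach shell closure, do not probe kinetic trapping
at high concentration, and their fixed particle number lets the effective
chemical potential drift as the cluster grows (a reservoir would not).
Shape thresholds in `capshell.analysis` (sphere-fit residual < 0.12,
boundary gap > 100 degrees, etc.) are calibrated on the geometric fixture
generators, not on experimental data.

## Numerical choices

* Defect-profile table: 161 points on x/r in [0, 2] per n, bounded Brent
  (xatol 1e-10) per ring radius, monotone cubic interpolation; the
  interpolation error reaches the energies at below 1e-8.
* Zoom minimizers: 241 (1-D) or 121x41 (2-D) points, 3 rounds; winner
  energies are stable to better than 1e-8 against refinement.
* Boundary tracing: 121-point geometric scan in dmu~, Brent refinement;
  among sign changes the deepest crossing with both structures assembled
  is reported (near-zero crossings inside the disassembled margin are
  artifacts of the x -> 0 limit).
* Degenerate inputs: gamma = 0 pins r = 1 everywhere and excludes the
  cylinder; x = 0 returns 0 (open structures) or lam r (closed rims);
  overlapping capsomers (r < 0.5 sigma) get clamped forces.

## Limitations

Small-curvature, flat-metric elasticity (exact rim length and spherical-
metric defect interactions would shift nucleation barriers but not the
stable-structure map); no kinetics beyond overdamped relaxation (no
nucleation rates, no kinetic trapping); single capsomer species; no
genome/cargo co-assembly; triangulation numbers of assembled shells are
not assigned.
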