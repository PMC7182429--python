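"""Brownian-dynamics engine: pair physics, gradients, integrator, assembly."""

import math
import warnings

import numpy as np
import pytest

from capshell.analysis import find_clusters
from capshell.bd import (
    NUMBA_ENABLED,
    SimulationConfig,
    SimulationState,
    _evaluate,
    bd_step,
    build_seed_cap,
    forces_and_torques,
    pair_energy,
    run_assembly,
    total_energy,
)
from capshell.mapping import PotentialParameters


def _aligned_orientations(pp, dphi=0.0, dtheta_i=0.0):
    """Orientations at theta_ij = theta_ji = nu (+offset), torsion dphi,
    for a pair separated along +x."""
    ti, tj = pp.nu + dtheta_i, pp.nu
    Oi = np.array([math.cos(ti), math.sin(ti), 0.0])
    Oj = np.array([-math.cos(tj), math.sin(tj) * math.cos(dphi),
                   math.sin(tj) * math.sin(dphi)])
    return Oi, Oj


class TestPairEnergy:
    def test_contact_minimum_is_minus_eps(self, cg_potential):
        Oi, Oj = _aligned_orientations(cg_potential)
        V = pair_energy([1.0, 0, 0], Oi, Oj, cg_potential)
        assert V == pytest.approx(-cg_potential.eps0, rel=1e-12)

    def test_angular_gaussian_one_width_off(self, cg_potential):
        Oi, Oj = _aligned_orientations(cg_potential,
                                       dtheta_i=cg_potential.alpha)
        V = pair_energy([1.0, 0, 0], Oi, Oj, cg_potential)
        assert V == pytest.approx(-math.exp(-0.5), rel=1e-10)

    def test_torsion_penalty(self, cg_potential):
        Oi, Oj = _aligned_orientations(cg_potential, dphi=math.pi / 2)
        V = pair_energy([1.0, 0, 0], Oi, Oj, cg_potential)
        assert V == pytest.approx(
            -math.exp(-cg_potential.kt), rel=1e-10)

    def test_decay_to_zero(self, cg_potential):
        Oi, Oj = _aligned_orientations(cg_potential)
        assert abs(pair_energy([40.0, 0, 0], Oi, Oj, cg_potential)) < 1e-15

    def test_zero_separation_singular(self, cg_potential):
        with pytest.raises(ValueError):
            pair_energy([0.0, 0, 0], *_aligned_orientations(cg_potential),
                        cg_potential)

    def test_repulsive_core_orientation_independent(self, cg_potential):
        # default mode: a misaligned pair still excludes volume
        Oi = np.array([0.0, 0.0, 1.0])
        Oj = np.array([0.0, 1.0, 0.0])
        V = pair_energy([0.8, 0, 0], Oi, Oj, cg_potential)
        assert V > 1.0
        V_strict = pair_energy([0.8, 0, 0], Oi, Oj, cg_potential,
                               strict_product=True)
        assert V_strict < V   # strict product switches the core off too


class TestForces:
    def test_gradients_match_finite_differences(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=2, seed_size=2,
                               n_steps=1)
        rng = np.random.default_rng(5)
        h = 1e-6
        for _ in range(50):
            d = rng.uniform(1.0, 1.8)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            pos = np.array([[0.0, 0, 0], d * v])
            ori = rng.standard_normal((2, 3))
            ori /= np.linalg.norm(ori, axis=1, keepdims=True)
            st = SimulationState(pos, ori, box=0.0)
            _, F, G = _evaluate(st, cfg, fast=False)
            Fn = np.zeros_like(F)
            Gn = np.zeros_like(G)
            for i in range(2):
                for k in range(3):
                    for arr, out in (("positions", Fn), ("orientations", Gn)):
                        s2, s3 = st.copy(), st.copy()
                        getattr(s2, arr)[i, k] += h
                        getattr(s3, arr)[i, k] -= h
                        out[i, k] = -(_evaluate(s2, cfg, fast=False)[0]
                                      - _evaluate(s3, cfg, fast=False)[0]) / (2 * h)
            scale = max(np.max(np.abs(Fn)), np.max(np.abs(Gn)), 1e-8)
            assert np.max(np.abs(F - Fn)) / scale < 1e-6
            assert np.max(np.abs(G - Gn)) / scale < 1e-6

    def test_zero_at_pair_minimum(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=2, seed_size=2,
                               n_steps=1)
        Oi, Oj = _aligned_orientations(cg_potential)
        st = SimulationState(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                             np.vstack([Oi, Oj]), box=0.0)
        F, G = forces_and_torques(st, cfg)
        assert np.max(np.abs(F)) < 1e-8
        assert np.max(np.abs(G)) < 1e-8

    def test_isolated_capsomer_feels_nothing(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=1, seed_size=1,
                               n_steps=1)
        st = SimulationState(np.zeros((1, 3)), np.array([[0, 0, 1.0]]), box=0.0)
        F, G = forces_and_torques(st, cfg)
        assert np.all(F == 0) and np.all(G == 0)

    def test_newtons_third_law(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=12, seed_size=7,
                               n_steps=1)
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 4.0, (12, 3))
        ori = rng.standard_normal((12, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        st = SimulationState(pos, ori, box=0.0)
        F, _ = forces_and_torques(st, cfg)
        # per-pair cancellation is exact; the total only carries summation
        # round-off relative to the (clamped, still huge) overlap forces
        assert np.max(np.abs(F.sum(axis=0))) < 1e-10 * max(
            1.0, float(np.max(np.abs(F))))

    @pytest.mark.skipif(not NUMBA_ENABLED, reason="numba not installed")
    def test_jitted_kernel_matches_python(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=15, seed_size=7,
                               n_steps=1)
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 5.0, (15, 3))
        ori = rng.standard_normal((15, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        st = SimulationState(pos, ori, box=5.0)
        Ef, Ff, Gf = _evaluate(st, cfg, fast=True)
        Ep, Fp, Gp = _evaluate(st, cfg, fast=False)
        assert Ef == pytest.approx(Ep, rel=1e-12)
        assert np.allclose(Ff, Fp, atol=1e-12)
        assert np.allclose(Gf, Gp, atol=1e-12)


class TestIntegrator:
    def test_zero_temperature_zero_force_is_identity(self, cg_potential,
                                                     zero_noise):
        cfg = SimulationConfig(pp=cg_potential, N_total=1, seed_size=1,
                               n_steps=1)
        st = SimulationState(np.array([[1.0, 2.0, 3.0]]),
                             np.array([[0, 0, 1.0]]), box=10.0)
        before = st.positions.copy()
        bd_step(st, cfg, zero_noise)
        assert np.allclose(st.positions, before)

    def test_free_diffusion_einstein_relation(self, cg_potential):
        # many independent particles, windowed displacements: the summed
        # MSD over 10^4 total steps must equal 6 D t within 5 percent
        n, nw, wlen, dt = 150, 10, 1000, 1e-3
        cfg = SimulationConfig(pp=cg_potential, N_total=n, seed_size=7,
                               n_steps=1, dt=dt)
        pos = 10.0 * np.indices((6, 5, 5)).reshape(3, -1).T[:n].astype(float)
        ori = np.tile([0.0, 0, 1.0], (n, 1))
        st = SimulationState(pos.copy(), ori, box=0.0, time_step=dt)
        rng = np.random.default_rng(42)
        msd_sum = 0.0
        for _ in range(nw):
            start = st.positions.copy()
            for _ in range(wlen):
                bd_step(st, cfg, rng)
            msd_sum += np.mean(np.sum((st.positions - start) ** 2, axis=1))
        expected = 6.0 * 1.0 * (nw * wlen * dt)
        assert msd_sum == pytest.approx(expected, rel=0.05)

    def test_zero_temperature_descent_is_monotone(self, cg_potential,
                                                  zero_noise):
        pos, ori = build_seed_cap(cg_potential, 19)
        pos[0] += 0.08   # perturb one capsomer
        cfg = SimulationConfig(pp=cg_potential, N_total=19, seed_size=19,
                               n_steps=1, dt=2e-5)
        st = SimulationState(pos, ori, box=0.0)
        prev = total_energy(st, cfg)
        for k in range(1000):
            bd_step(st, cfg, zero_noise)
            if k % 50 == 0:
                e = total_energy(st, cfg)
                assert e <= prev + 1e-10
                prev = e

    def test_perturbed_dimer_relaxes_to_contact(self, cg_potential,
                                                zero_noise):
        Oi, Oj = _aligned_orientations(cg_potential)
        st = SimulationState(np.array([[0.0, 0, 0], [1.3, 0.05, 0]]),
                             np.vstack([Oi, Oj]), box=0.0)
        cfg = SimulationConfig(pp=cg_potential, N_total=2, seed_size=2,
                               n_steps=1, dt=2e-5)
        for _ in range(20000):
            bd_step(st, cfg, zero_noise)
        sep = np.linalg.norm(st.positions[1] - st.positions[0])
        assert sep == pytest.approx(cg_potential.sigma, abs=1e-4)
        assert total_energy(st, cfg) == pytest.approx(-1.0, abs=1e-3)

    def test_orientations_stay_normalized(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=19, seed_size=19,
                               n_steps=1, dt=5e-5)
        pos, ori = build_seed_cap(cg_potential, 19)
        st = SimulationState(pos, ori, box=0.0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            bd_step(st, cfg, rng)
        norms = np.linalg.norm(st.orientations, axis=1)
        assert np.max(np.abs(norms - 1.0)) < 1e-12

    def test_large_step_warns(self, cg_potential, zero_noise):
        cfg = SimulationConfig(pp=cg_potential, N_total=2, seed_size=2,
                               n_steps=1, dt=5e-3)
        st = SimulationState(np.array([[0.0, 0, 0], [0.8, 0, 0]]),
                             np.array([[0, 0, 1.0], [0, 0, 1.0]]), box=0.0)
        with pytest.warns(UserWarning, match="exceeds 0.25 sigma"):
            bd_step(st, cfg, zero_noise)

    def test_dimer_bond_length_distribution(self, cg_potential):
        # equilibrium separation distribution at T_red = 0.1 peaks at the
        # contact distance; oracle: mode of r^2 exp(-V(r)/T)
        cfg = SimulationConfig(pp=cg_potential, N_total=2, seed_size=2,
                               n_steps=1, dt=5e-5, Dr=0.0)
        Oi, Oj = _aligned_orientations(cg_potential)
        st = SimulationState(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                             np.vstack([Oi, Oj]), box=0.0)
        rng = np.random.default_rng(9)
        seps = []
        for k in range(60000):
            bd_step(st, cfg, rng)
            if k % 20 == 0:
                seps.append(np.linalg.norm(st.positions[1] - st.positions[0]))
        hist, edges = np.histogram(seps, bins=np.arange(0.9, 1.12, 0.01))
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        rr = np.linspace(0.9, 1.2, 4001)
        pp = cg_potential
        vmie = (pp.eps0 * pp.n / (pp.m - pp.n)
                * ((pp.sigma / rr) ** pp.m - pp.m / pp.n * (pp.sigma / rr) ** pp.n))
        boltz = rr**2 * np.exp(-vmie / 0.1)
        oracle = rr[np.argmax(boltz)]
        assert mode == pytest.approx(oracle, rel=0.02)


class TestSeedCap:
    def test_geometry(self, cg_potential):
        pos, ori = build_seed_cap(cg_potential, 19)
        R0 = cg_potential.sigma / (2 * abs(math.cos(cg_potential.nu)))
        radial = np.linalg.norm(pos, axis=1)
        assert np.all(np.abs(radial - R0) / R0 < 0.02)
        from scipy.spatial import cKDTree
        nn = cKDTree(pos).query(pos, k=2)[0][:, 1]
        assert np.all(np.abs(nn - cg_potential.sigma) < 0.05)

    def test_flat_limit_rejected(self):
        with pytest.raises(ValueError):
            build_seed_cap(PotentialParameters(nu=math.pi / 2 + 1e-9), 19)
        with pytest.raises(ValueError):
            build_seed_cap(PotentialParameters(), 5)

    def test_energy_per_bond_near_binding_energy(self, cg_potential,
                                                 zero_noise):
        pos, ori = build_seed_cap(cg_potential, 19)
        cfg = SimulationConfig(pp=cg_potential, N_total=19, seed_size=19,
                               n_steps=1, dt=2e-5)
        st = SimulationState(pos.copy(), ori.copy(), box=0.0)
        for _ in range(3000):
            bd_step(st, cfg, zero_noise)
        from scipy.spatial import cKDTree
        bonds = len(cKDTree(st.positions).query_pairs(1.2))
        per_bond = total_energy(st, cfg) / bonds
        assert per_bond == pytest.approx(-cg_potential.eps0, rel=0.10)


class TestAssemblyRuns:
    def test_replay_is_bit_identical(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=30, density=0.02,
                               n_steps=500, dt=5e-5)
        _, f1 = run_assembly(cfg, seed=123)
        _, f2 = run_assembly(cfg, seed=123)
        assert np.array_equal(f1.positions, f2.positions)
        assert np.array_equal(f1.orientations, f2.orientations)

    def test_overcrowded_placement_fails(self, cg_potential):
        cfg = SimulationConfig(pp=cg_potential, N_total=60, density=1.5,
                               n_steps=1)
        with pytest.raises(RuntimeError):
            run_assembly(cfg, seed=0)

    def test_seed_grows_at_high_concentration(self, cg_potential):
        # scaled-down qualitative check of the assembly branch
        grew = 0
        for seed in (1, 2, 3):
            cfg = SimulationConfig(pp=cg_potential, N_total=60, density=0.05,
                                   T_red=0.1, n_steps=120000, dt=5e-5)
            _, final = run_assembly(cfg, seed=seed)
            if find_clusters(final).cluster_sizes[0] > 19:
                grew += 1
        assert grew >= 2

    def test_seed_shrinks_when_starved(self, cg_potential):
        # no free capsomers and weakened binding (dissolution at the study
        # temperature is astronomically slow; T_red = 0.25 accelerates it)
        shrank = 0
        for seed in (1, 2, 3):
            cfg = SimulationConfig(pp=cg_potential, N_total=19, density=0.002,
                                   T_red=0.25, n_steps=120000, dt=5e-5)
            _, final = run_assembly(cfg, seed=seed)
            if find_clusters(final).cluster_sizes[0] < 19:
                shrank += 1
        assert shrank >= 2
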