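"""1D chain model: construction, energies, Euler buckling limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mtshell import filament1d as F1
from mtshell import quasistatic as Q


class TestBuildChain:
    def test_kappa_from_rigidity(self):
        ch = F1.build_chain(B=4e6, L=4100.0, N=100)
        assert ch.kappa == pytest.approx(4e6 * 100 / 4100.0)
        assert ch.kappa == pytest.approx(9.76e4, rel=1e-3)

    def test_zero_rigidity(self):
        assert F1.build_chain(B=0.0, L=100.0, N=8).kappa == 0.0

    def test_kappa_linear_in_N(self):
        k1 = F1.build_chain(B=2e6, L=1000.0, N=20).kappa
        k2 = F1.build_chain(B=2e6, L=1000.0, N=40).kappa
        assert k2 == pytest.approx(2 * k1)

    def test_too_few_particles(self):
        with pytest.raises(F1.TooFewParticlesError):
            F1.build_chain(B=1e6, L=100.0, N=3)

    def test_rest_configuration_zero_energy(self):
        ch = F1.build_chain(B=4e6, L=4100.0, N=32)
        e = F1.chain_energy(ch, ch.positions0)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in e.values())


class TestEulerBucklingForce:
    @pytest.mark.parametrize(
        "B,L,expected,rtol",
        [
            (4e6, 4100.0, 2.3, 0.025),       # flagellum-scale reference value
            (1e6, 1000.0, math.pi**2, 1e-12),
            (12e6, 7100.0, 2.35, 0.002),
        ],
    )
    def test_values(self, B, L, expected, rtol):
        assert F1.euler_buckling_force(B, L) == pytest.approx(expected, rel=rtol)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            F1.euler_buckling_force(1.0, 0.0)


class TestChainEnergy:
    def test_single_stretched_segment(self):
        ch = F1.build_chain(B=1e6, L=300.0, N=4, beads=False)
        ch.pair_k[:] = 2.0  # k = 2 pN/nm, stretch one segment by 1 nm
        pos = ch.positions0.copy()
        pos[3, 0] += 1.0
        assert F1.chain_energy(ch, pos)["stretch"] == pytest.approx(1.0)

    def test_arc_energy_continuum_limit(self):
        # chain bent into a circular arc of radius rho: bend energy
        # approaches B*L/(2 rho^2) as N grows
        B, L, rho, N = 4e6, 4000.0, 10000.0, 400
        ch = F1.build_chain(B=B, L=L, N=N, beads=False)
        theta = (np.arange(N) * ch.l0) / rho
        pos = np.zeros((N, 3))
        pos[:, 0] = rho * np.sin(theta)
        pos[:, 1] = rho * (1 - np.cos(theta))
        e = F1.chain_energy(ch, pos)
        assert e["bend"] == pytest.approx(0.5 * B * L / rho**2, rel=0.01)

    def test_coincident_points_rejected(self):
        from mtshell.network import GeometryError

        ch = F1.build_chain(B=1e6, L=300.0, N=4, beads=False)
        pos = ch.positions0.copy()
        pos[1] = pos[0]
        with pytest.raises(GeometryError):
            F1.chain_energy(ch, pos)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ch = F1.build_chain(B=4e6, L=1000.0, N=12)
        pos = ch.positions0 + rng.normal(0, 5.0, ch.positions0.shape)
        e0 = F1.chain_energy(ch, pos)
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        moved = pos @ rot.T + rng.normal(0, 100.0, 3)
        e1 = F1.chain_energy(ch, moved)
        for k in e0:
            assert e1[k] == pytest.approx(e0[k], rel=1e-8, abs=1e-8)


class TestBucklingBehavior:
    def test_euler_plateau_converges_with_N(self):
        """Pinned centerline-loaded chain: post-buckling force within 10%
        of pi^2 B / L^2, improving as N grows."""
        B, L = 4e6, 4100.0
        Fc = F1.euler_buckling_force(B, L)
        errs = []
        for N in (24, 64):
            ch = F1.build_chain(B, L, N=N, beads=False)
            ch.positions0 = F1.perturb_midpoint(ch)
            sched = Q.compression_schedule(L, 0.02, dx=16.0)
            traj = Q.run_protocol(
                ch, Q.ProtocolSpec(schedule=sched, dx=16.0, check_stability=True,
                                   store_positions=False))
            f = np.interp(-0.015, traj.strain[::-1], traj.force[::-1])
            errs.append(abs(f - Fc) / Fc)
        assert errs[-1] < 0.10
        assert errs[-1] <= errs[0] + 0.01

    def test_bead_loaded_monotone_and_extension_steeper(self):
        B, L = 4e6, 2000.0
        ch = F1.build_chain(B, L, N=24, b=500.0)
        sched = Q.compression_schedule(L, 0.3, dx=20.0, extension_strain=0.05)
        traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=sched, dx=20.0,
                                                 store_positions=False))
        comp = (traj.direction == 1) & (traj.strain <= 0)
        s_c = traj.strain[comp][np.argsort(traj.strain[comp])]
        f_c = traj.force[comp][np.argsort(traj.strain[comp])]
        # force magnitude grows monotonically with compression
        assert np.all(np.diff(f_c) <= 1e-6)
        ext = traj.strain > 1e-9
        s_e, f_e = traj.strain[ext], np.abs(traj.force[ext])
        assert np.all(np.diff(f_e[np.argsort(s_e)]) >= -1e-6)
        slope_c = abs(np.interp(-0.06, s_c, f_c) - np.interp(-0.02, s_c, f_c)) / 0.04
        slope_e = abs(
            np.interp(0.04, np.sort(s_e), f_e[np.argsort(s_e)])
            - np.interp(0.01, np.sort(s_e), f_e[np.argsort(s_e)])
        ) / 0.03
        assert slope_e > slope_c

    def test_stiff_constraint_energies_negligible(self):
        """Tether/stretch strain energies stay below 1% of bending energy
        during a compression run (the 'very stiff' constraint audit)."""
        ch = F1.build_chain(4e6, 2000.0, N=24, b=500.0)
        sched = Q.compression_schedule(2000.0, 0.3, dx=20.0)
        traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=sched, dx=20.0,
                                                 store_positions=False))
        bend = traj.energy_channel("axial_bend")[-1]
        constraint = traj.energy_channel("axial_stretch")[-1] + traj.energy_channel("bead")[-1]
        assert constraint < 0.01 * bend
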