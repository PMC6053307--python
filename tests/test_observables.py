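"""Strain, flatness/curvature profiles, kinks, critical moments, onset."""

import math

import numpy as np
import pytest

from mtshell import observables as O
from mtshell import params as P
from mtshell import shell3d
from mtshell.quasistatic import Trajectory


def make_traj(db, energies=None, force=None, max_transverse=None, meta=None):
    n = len(db)
    db = np.asarray(db, dtype=float)
    L = db[0]
    if energies is None:
        energies = np.zeros((n, 7))
    mt = np.zeros(n) if max_transverse is None else np.asarray(max_transverse, dtype=float)
    return Trajectory(
        db=db,
        strain=(db - L) / L,
        force=np.zeros(n) if force is None else np.asarray(force, dtype=float),
        energies=np.asarray(energies, dtype=float),
        max_transverse=mt,
        max_deflection=mt,
        direction=np.ones(n, dtype=int),
        converged=np.ones(n, dtype=bool),
        meta=meta or {},
    )


class TestStrain:
    @pytest.mark.parametrize("db,L,expected", [(100.0, 100.0, 0.0),
                                               (90.0, 100.0, -0.1),
                                               (50.0, 100.0, -0.5)])
    def test_values(self, db, L, expected):
        assert O.strain(db, L) == pytest.approx(expected)

    def test_positive_L_required(self):
        with pytest.raises(ValueError):
            O.strain(1.0, 0.0)


def ring_positions(lattice, semi_axes):
    """Replace every ring by an ellipse with the given semi-axes (y, z)."""
    pos = lattice.positions0.copy()
    ay, az = semi_axes
    theta = 2 * math.pi * np.arange(lattice.Np) / lattice.Np
    for j in range(lattice.Nr):
        sl = slice(j * lattice.Np, (j + 1) * lattice.Np)
        pos[sl, 1] = ay * np.cos(theta)
        pos[sl, 2] = az * np.sin(theta)
    return pos


class TestFlatnessProfile:
    def test_perfect_circle_zero(self, small_lattice):
        prof = O.flatness_profile(small_lattice.positions0, small_lattice)
        assert np.allclose(prof.e, 0.0, atol=1e-9)
        assert np.allclose(prof.a, small_lattice.macro.R, atol=1e-6)
        assert prof.s_hat[0] == 0.0 and prof.s_hat[-1] == 1.0

    def test_ellipse_18_6_gives_half(self, small_lattice):
        pos = ring_positions(small_lattice, (18.0, 6.0))
        prof = O.flatness_profile(pos, small_lattice)
        assert np.allclose(prof.e, 0.5, atol=1e-9)

    def test_collapsed_ring_flagged(self, small_lattice):
        pos = ring_positions(small_lattice, (18.0, 0.0))
        prof = O.flatness_profile(pos, small_lattice)
        assert np.all(prof.degenerate)
        assert np.allclose(prof.e, 1.0)

    def test_flatness_bounded(self, small_lattice, rng):
        pos = small_lattice.positions0 + rng.normal(0, 2.0, small_lattice.positions0.shape)
        prof = O.flatness_profile(pos, small_lattice)
        assert np.all((prof.e >= 0) & (prof.e <= 1))


class TestCurvatureProfile:
    def test_straight_is_zero(self, small_lattice):
        kappa = O.curvature_profile(small_lattice.positions0, small_lattice)
        assert np.allclose(kappa, 0.0, atol=1e-12)

    def test_circle_oracle(self, small_lattice):
        rho = 1000.0
        pos = shell3d.deform_arc(small_lattice, 1.0 / rho)
        kappa = O.curvature_profile(pos, small_lattice)
        assert np.allclose(kappa[1:-1], 1e-3, rtol=1e-3)


class TestDetectKinks:
    def make_profile(self, e):
        n = len(e)
        return O.CrossSectionProfile(
            s_hat=np.linspace(0, 1, n), e=np.asarray(e, dtype=float),
            a=12.0 * (1 - np.asarray(e)), curvature=np.zeros(n),
        )

    def test_flat_profile_no_kinks(self):
        _, pos = O.detect_kinks(self.make_profile(np.full(41, 0.02)))
        assert len(pos) == 0

    def test_single_inserted_spike_found(self):
        e = np.full(41, 0.02)
        e[20] = 0.6
        _, pos = O.detect_kinks(self.make_profile(e))
        assert len(pos) == 1
        assert pos[0] == pytest.approx(0.5)

    def test_edge_spikes_excluded(self):
        e = np.full(41, 0.02)
        e[1] = 0.7   # bead-attachment artifact, not a kink
        _, pos = O.detect_kinks(self.make_profile(e))
        assert len(pos) == 0

    def test_force_drop_corroboration(self):
        e = np.full(41, 0.02)
        e[20] = 0.6
        profs = [self.make_profile(np.full(41, 0.02))] * 3 + [self.make_profile(e)] * 2
        db = [100, 99, 98, 97, 96]
        force = [0.0, 1.0, 2.0, 1.8, 1.9]  # drop between steps 2 and 3
        step, pos = O.detect_kinks(profs, make_traj(db, force=force))
        assert step == 3
        assert pos[0] == pytest.approx(0.5)


class TestModifiedForce:
    def test_constant_energy_zero(self):
        traj = make_traj([100, 99, 98, 97], energies=np.full((4, 7), 3.0))
        assert np.allclose(O.modified_force(traj), 0.0)

    def test_quadratic_energy_linear_force(self):
        db = np.array([100.0, 98.0, 96.0, 94.0, 92.0])
        k = 0.5
        em = np.zeros((5, 7))
        em[:, 0] = 0.5 * k * (db - 100.0) ** 2
        fmod = O.modified_force(make_traj(db, energies=em))
        # -dE/ddb = -k(db-L) -> positive under compression
        assert np.allclose(fmod[1:-1], k * (100.0 - db)[1:-1], rtol=1e-12)

    def test_shear_and_lateral_excluded(self):
        db = np.array([100.0, 98.0, 96.0])
        em = np.zeros((3, 7))
        em[:, 4] = np.array([0.0, 5.0, 20.0])   # shear
        em[:, 6] = np.array([0.0, 1.0, 2.0])    # lateral penalty
        assert np.allclose(O.modified_force(make_traj(db, energies=em)), 0.0)

    def test_single_step_rejected(self):
        with pytest.raises(ValueError):
            O.modified_force(make_traj([100.0]))


class TestCriticalMoment:
    def test_predicted_value(self):
        m = P.MacroElastic(Ea=0.9e3, Ec=4.0, G=4e3, L=100.0)
        mb = O.critical_moment_predicted(m)
        assert mb == pytest.approx(2.7**2 * 12.0 * math.sqrt(900.0 * 4.0), rel=1e-12)
        assert mb == pytest.approx(5.25e3, rel=2e-3)

    def test_isotropic_brazier_factor(self):
        assert O.BRAZIER_FACTOR == pytest.approx(2 * math.sqrt(2) * math.pi / 9)
        assert O.BRAZIER_FACTOR == pytest.approx(0.98731, abs=1e-5)
        m = P.MacroElastic(Ea=500.0, Ec=500.0, G=1.0, L=100.0)
        mb = O.critical_moment_predicted(m, factor=O.BRAZIER_FACTOR)
        assert mb == pytest.approx(O.BRAZIER_FACTOR * 2.7**2 * 12.0 * 500.0)

    def test_zero_circumferential_modulus(self):
        m = P.MacroElastic(Ea=500.0, Ec=0.0, G=1.0, L=100.0)
        assert O.critical_moment_predicted(m) == 0.0

    def test_no_kink_flagged_nan(self):
        db = np.array([100.0, 99.0, 98.0])
        em = np.zeros((3, 7))
        traj = make_traj(db, energies=em, force=[0.0, 1.0, 2.0])
        assert math.isnan(O.critical_moment_observed(traj))

    def test_observed_is_fmod_times_amplitude_at_onset(self):
        # kink at step 3: MB uses the pre-drop state (step 2) with a
        # backward-difference modified force: -(e2 - e1)/(db2 - db1) = 3
        db = np.array([100.0, 98.0, 96.0, 94.0, 92.0])
        em = np.zeros((5, 7))
        em[:, 0] = 0.5 * (db - 100.0) ** 2
        traj = make_traj(db, energies=em, force=[0, 2, 4, 3, 3.2],
                         max_transverse=[0, 10, 20, 30, 40],
                         meta={"kink_step": 3})
        assert O.critical_moment_observed(traj) == pytest.approx(3.0 * 20.0)


class TestCriticalCurvature:
    def test_analytic_route(self):
        assert O.critical_curvature(MB=1000.0, B=10e6) == pytest.approx(0.1)
        assert O.critical_curvature(MB=2000.0, B=10e6) == pytest.approx(0.2)

    def test_requires_some_input(self):
        with pytest.raises(ValueError):
            O.critical_curvature()

    def test_simulation_route_uses_pre_kink_state(self, small_lattice):
        # kink detected at step 2: curvature read from step 1, the last
        # smooth state before the collapse spike
        lat = small_lattice
        db = np.array([200.0, 198.0, 196.0])
        traj = make_traj(db, force=[0.0, 1.0, 2.0], meta={"kink_step": 2})
        traj.positions = [lat.positions0,
                          shell3d.deform_arc(lat, 2e-4),
                          shell3d.deform_arc(lat, 2e-3)]
        out = O.critical_curvature(traj=traj, lattice=lat)
        assert out == pytest.approx(0.2, rel=1e-3)


class TestPlateauOnset:
    def test_linear_curve_not_found(self):
        s = -np.linspace(0, 0.3, 31)
        assert math.isnan(O.plateau_onset(s, 50 * -s))

    def test_piecewise_knee_located(self):
        s = -np.linspace(0, 0.3, 61)
        F = np.where(-s < 0.12, 50 * -s, 50 * 0.12)
        onset = O.plateau_onset(s, F)
        assert onset == pytest.approx(-0.12, abs=0.01)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            O.plateau_onset(np.array([0.0, -0.1]), np.array([0.0, 1.0]))
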