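"""Relaxation engine and protocol bookkeeping."""

import numpy as np
import pytest

from mtshell import filament1d as F1
from mtshell import quasistatic as Q


class TestRelax:
    def test_rest_configuration_unchanged(self, small_lattice):
        pos, rep = Q.relax(small_lattice, small_lattice.positions0)
        assert rep.converged and rep.n_iter == 0
        assert np.allclose(pos, small_lattice.positions0)

    def test_small_compression_matches_series_springs(self):
        """A straight pinned chain compressed slightly responds like
        N-1 springs in series: F = k/(N-1) * delta."""
        ch = F1.build_chain(B=1e6, L=900.0, N=10, beads=False)
        delta = 0.5
        pos = ch.positions0.copy()
        pos[-1, 0] -= delta
        ch2 = F1.build_chain(B=1e6, L=900.0, N=10, beads=False)
        relaxed, rep = Q.relax(ch2, pos)
        assert rep.converged
        from mtshell.network import total_energy_grad

        _, g, _ = total_energy_grad(ch2, relaxed)
        assert g[0, 0] == pytest.approx(ch2.k / 9 * delta, rel=1e-6)

    def test_tightening_tol_is_stable(self):
        ch = F1.build_chain(B=4e6, L=1000.0, N=16, b=300.0)
        sched = Q.compression_schedule(1000.0, 0.1, dx=20.0)
        f = {}
        for tol in (1e-3, 5e-4):
            traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=sched, dx=20.0, tol=tol,
                                                     store_positions=False))
            f[tol] = traj.force[-1]
        assert f[5e-4] == pytest.approx(f[1e-3], abs=2e-3)


class TestRunProtocol:
    def test_zero_step_schedule(self):
        ch = F1.build_chain(B=4e6, L=1000.0, N=12)
        traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=[ch.length], dx=1.0))
        assert traj.n_steps == 1
        assert traj.strain[0] == pytest.approx(0.0)
        assert traj.force[0] == pytest.approx(0.0, abs=1e-3)

    def test_force_zero_at_equilibrium_separation(self):
        ch = F1.build_chain(B=4e6, L=1000.0, N=16, b=300.0)
        sched = Q.compression_schedule(1000.0, 0.05, dx=10.0, extension_strain=0.05)
        traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=sched, dx=10.0,
                                                 store_positions=False))
        # the |force| minimum over a stretch+compress sweep locates db = L
        i = int(np.argmin(np.abs(traj.force)))
        assert abs(traj.db[i] - 1000.0) <= 10.0

    def test_energy_components_nonnegative(self):
        ch = F1.build_chain(B=4e6, L=1000.0, N=12)
        sched = Q.compression_schedule(1000.0, 0.1, dx=25.0)
        traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=sched, dx=25.0,
                                                 store_positions=False))
        assert np.all(traj.energies >= -1e-12)

    def test_strain_consistent_with_db(self):
        ch = F1.build_chain(B=4e6, L=1000.0, N=12)
        sched = Q.compression_schedule(1000.0, 0.1, dx=25.0)
        traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=sched, dx=25.0,
                                                 store_positions=False))
        assert np.allclose(traj.strain, (traj.db - ch.length) / ch.length)


class TestHysteresis:
    def test_identical_sweeps_zero_gap(self):
        db = np.array([100.0, 98, 96, 94, 96, 98, 100])
        traj = Q.Trajectory(
            db=db, strain=(db - 100) / 100,
            force=np.array([0.0, 1, 2, 3, 2, 1, 0]),
            energies=np.zeros((7, 7)), max_transverse=np.zeros(7),
            max_deflection=np.zeros(7),
            direction=np.array([1, 1, 1, 1, -1, -1, -1]),
            converged=np.ones(7, dtype=bool),
        )
        pre, post, grid = Q.hysteresis_gap(traj)
        assert pre == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(post)

    def test_missing_direction_rejected(self):
        db = np.array([100.0, 98, 96])
        traj = Q.Trajectory(
            db=db, strain=(db - 100) / 100, force=np.zeros(3),
            energies=np.zeros((3, 7)), max_transverse=np.zeros(3),
            max_deflection=np.zeros(3),
            direction=np.ones(3, dtype=int), converged=np.ones(3, dtype=bool),
        )
        with pytest.raises(Q.InsufficientDataError):
            Q.hysteresis_gap(traj)

    def test_split_at_kink_strain(self):
        db = np.array([100.0, 98, 96, 94, 96, 98, 100])
        traj = Q.Trajectory(
            db=db, strain=(db - 100) / 100,
            force=np.array([0.0, 1, 2, 3, 2.5, 1.2, 0.1]),
            energies=np.zeros((7, 7)), max_transverse=np.zeros(7),
            max_deflection=np.zeros(7),
            direction=np.array([1, 1, 1, 1, -1, -1, -1]),
            converged=np.ones(7, dtype=bool),
        )
        pre, post, grid = Q.hysteresis_gap(traj, kink_strain=-0.03)
        assert post >= pre
        assert pre <= 0.4  # interpolated forward/backward mismatch pre-kink

    def test_no_hysteresis_pre_kink_1d(self):
        """Forward/backward gap below 2% of peak force when converged —
        the quasistatic adequacy criterion."""
        ch = F1.build_chain(B=4e6, L=1500.0, N=20, b=400.0)
        sched = Q.compression_schedule(1500.0, 0.2, dx=25.0, backward=True)
        traj = Q.run_protocol(ch, Q.ProtocolSpec(schedule=sched, dx=25.0,
                                                 store_positions=False))
        pre, _, _ = Q.hysteresis_gap(traj)
        assert pre < 0.02 * traj.force.max()


class TestCompressionSchedule:
    def test_monotone_within_sweeps(self):
        s = Q.compression_schedule(1000.0, 0.2, dx=10.0, backward=True)
        n = len(s) // 2
        assert np.all(np.diff(s[: n + 1]) < 0)
        assert np.all(np.diff(s[n:]) > 0)

    def test_extension_passes_through_release(self):
        s = Q.compression_schedule(1000.0, 0.1, dx=10.0, extension_strain=0.05)
        assert s.max() == pytest.approx(1050.0, abs=10.0)
        assert abs(np.diff(s)).max() <= 10.0 + 1e-9
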