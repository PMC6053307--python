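"""3D shell lattice: topology, typed energies, channel separability."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mtshell import params as P
from mtshell import shell3d
from mtshell._kernels import CH_AX_BEND, CH_AX_STRETCH, CH_CIRC_BEND, CH_CIRC_STRETCH, CH_SHEAR


class TestBuildLattice:
    def test_particle_counting(self):
        m = P.MacroElastic(Ea=600.0, Ec=3.0, G=1.5e3, L=80.0, d=8.0)
        lat = shell3d.build_lattice(m)
        assert lat.Nr == 11
        assert lat.n_particles == 11 * 10 + 2

    def test_too_short(self):
        m = P.MacroElastic(Ea=600.0, Ec=3.0, G=1.5e3, L=30.0, d=8.0)
        with pytest.raises(shell3d.TooShortError):
            shell3d.build_lattice(m)

    def test_rest_energy_zero_all_channels(self, small_lattice):
        e = shell3d.shell_energy(small_lattice, small_lattice.positions0)
        for name, v in e.items():
            assert v == pytest.approx(0.0, abs=1e-9), name

    def test_circumferential_rest_angle_is_decagon_interior(self, small_lattice):
        phi0 = small_lattice.trip_phi0[small_lattice.trip_ch == CH_CIRC_BEND]
        assert np.allclose(phi0, 144.0 * math.pi / 180.0)

    def test_interior_particle_interaction_counts(self, small_lattice):
        lat = small_lattice
        j, mth = lat.Nr // 2, 3
        pidx = lat.particle(j, mth)
        pair_ch = lat.pair_ch
        in_pair = (lat.pairs == pidx).any(axis=1)
        assert (in_pair & (pair_ch == CH_AX_STRETCH)).sum() == 2
        assert (in_pair & (pair_ch == CH_CIRC_STRETCH)).sum() == 2
        center = lat.trips[:, 1] == pidx
        assert (center & (lat.trip_ch == CH_AX_BEND)).sum() == 1
        assert (center & (lat.trip_ch == CH_CIRC_BEND)).sum() == 1
        assert (center & (lat.trip_ch == CH_SHEAR)).sum() == 4

    def test_ring_topology_closes(self, small_lattice):
        lat = small_lattice
        circ = lat.pairs[lat.pair_ch == CH_CIRC_STRETCH]
        ring0 = circ[(circ < lat.Np).all(axis=1)]
        assert len(ring0) == lat.Np  # closed loop has Np edges


class TestShellEnergy:
    def test_uniform_axial_strain_closed_form(self, small_lattice):
        lat = small_lattice
        delta = 0.01
        e = shell3d.shell_energy(lat, shell3d.deform_axial_strain(lat, delta))
        expected = lat.Np * (lat.Nr - 1) * 0.5 * lat.micro.ka * (lat.macro.d * delta) ** 2
        assert e["axial_stretch"] == pytest.approx(expected, rel=1e-9)
        for name in ("circ_stretch", "axial_bend", "circ_bend", "shear"):
            assert e[name] == pytest.approx(0.0, abs=1e-12)

    def test_inflation_excites_only_circ_stretch(self, small_lattice):
        lat = small_lattice
        e = shell3d.shell_energy(lat, shell3d.deform_inflation(lat, 0.02))
        expected = lat.Np * lat.Nr * 0.5 * lat.micro.kc * (lat.macro.p * 0.02) ** 2
        assert e["circ_stretch"] == pytest.approx(expected, rel=1e-9)
        for name in ("axial_stretch", "axial_bend", "circ_bend", "shear"):
            assert e[name] == pytest.approx(0.0, abs=1e-10)

    def test_twist_excites_shear(self, small_lattice):
        lat = small_lattice
        e = shell3d.shell_energy(lat, shell3d.deform_twist(lat, 1e-3))
        assert e["shear"] > 0
        assert e["circ_stretch"] == pytest.approx(0.0, abs=1e-10)
        assert e["circ_bend"] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_rotation_invariance(self, small_lattice, rng):
        lat = small_lattice
        pos = lat.positions0 + rng.normal(0, 0.3, lat.positions0.shape)
        e0 = shell3d.shell_energy(lat, pos)
        rot = Rotation.from_rotvec([0.3, -0.8, 0.5]).as_matrix()
        e1 = shell3d.shell_energy(lat, pos @ rot.T + np.array([10.0, -30.0, 5.0]))
        for k in e0:
            if k == "lateral":
                continue  # the stabilization plane is deliberately not frame-invariant
            assert e1[k] == pytest.approx(e0[k], rel=1e-7, abs=1e-7)

    def test_degenerate_geometry_rejected(self, small_lattice):
        from mtshell.network import GeometryError

        pos = small_lattice.positions0.copy()
        pos[1] = pos[0]
        with pytest.raises(GeometryError):
            shell3d.shell_energy(small_lattice, pos)


class TestLateralStabilization:
    def test_in_plane_configuration_has_zero_penalty(self, small_lattice):
        e = shell3d.shell_energy(small_lattice, small_lattice.positions0)
        assert e["lateral"] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_plane_centroid_restored(self, small_lattice):
        from mtshell.network import total_energy_grad

        lat = small_lattice
        pos = lat.positions0.copy()
        ring = 3
        sl = slice(ring * lat.Np, (ring + 1) * lat.Np)
        pos[sl, 2] += 1.0  # whole-ring z shift = centroid displacement
        e, g, ech = total_energy_grad(lat, pos)
        assert ech[6] > 0
        # restoring force pushes the ring back toward z = 0
        assert g[sl, 2].sum() > 0

    def test_ovalization_not_penalized(self, small_lattice):
        # pure ovalization moves particles in z but keeps centroids in-plane
        lat = small_lattice
        e = shell3d.shell_energy(lat, shell3d.deform_ovalization(lat, 0.05))
        assert e["lateral"] == pytest.approx(0.0, abs=1e-9)


class TestBeamLimit:
    def test_bending_rigidity_matches_thin_shell(self):
        """Energy of an imposed circular arc (non-shear channels) equals
        B_eff·c²·L/2 with B_eff within 15% of pi·Ea·h·R³."""
        m = P.MacroElastic(Ea=0.9e3, Ec=400.0, G=4e3, L=320.0, d=8.0)
        lat = shell3d.build_lattice(m, P.macro_to_micro(m, P.calibrate_factors(m)),
                                    beads=False)
        c = 1e-5  # rad/nm, gentle arc
        e = shell3d.shell_energy(lat, shell3d.deform_arc(lat, c))
        bending = e["axial_stretch"] + e["axial_bend"]
        B_eff = 2.0 * bending / (c**2 * lat.length)
        assert B_eff == pytest.approx(m.bending_rigidity, rel=0.15)
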