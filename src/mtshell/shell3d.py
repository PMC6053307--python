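"""Discrete 3D spring-network cylinder model of a microtubule.

The filament is a planar spring network wrapped into a cylinder: ``Nr``
rings of ``Np`` particles (10 protofilaments by default) with radius R,
axial spacing d and circumferential spacing p = 2R sin(pi/Np).  Typed
interactions:

* axial springs (stiffness ka, rest d) between corresponding particles of
  neighboring rings;
* circumferential springs (kc, rest p) around each ring;
* axial bend triplets (kappa_a, rest angle pi) along each protofilament;
* circumferential bend triplets (kappa_c, rest angle = the regular-polygon
  interior angle, 144° for Np=10);
* shear triplets (kappa_s, rest angle pi/2) for every triplet of bonded
  neighbors not all axial or all circumferential — four per interior
  particle, one per quadrant;
* one optical bead per end, tethered to a single surface particle on the
  same protofilament (azimuth 0) by a stiff spring of rest length b plus a
  stiff angle constraint keeping the tether normal to the filament axis.

The orthotropic shell energy has no penalty for cross-sectional shearing,
which makes the lateral (out-of-plane) direction marginally unstable; a
stiff harmonic penalty on each ring-centroid z-coordinate keeps the
centerline in the x-y buckling plane while leaving within-ring z motion
(ovalization) free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import params as P
from ._kernels import (
    CH_AX_BEND,
    CH_AX_STRETCH,
    CH_BEAD,
    CH_CIRC_BEND,
    CH_CIRC_STRETCH,
    CH_SHEAR,
)
from .network import energy_breakdown, total_energy_grad

__all__ = [
    "ShellLattice",
    "build_lattice",
    "build_microtubule",
    "shell_energy",
    "ring_centroids",
    "deform_axial_strain",
    "deform_inflation",
    "deform_arc",
    "deform_ovalization",
    "deform_twist",
    "TooShortError",
]

#: lateral-stabilization stiffness as a multiple of ka
LATERAL_SCALE = 1e2


class TooShortError(ValueError):
    """Lattice would have fewer than the minimum number of rings."""


@dataclass
class ShellLattice:
    macro: P.MacroElastic
    micro: P.MicroSprings
    Nr: int
    Np: int
    length: float                 # (Nr-1)·d, equilibrium bead separation, nm
    positions0: np.ndarray        # (Nr*Np [+2], 3)
    pairs: np.ndarray
    pair_k: np.ndarray
    pair_r0: np.ndarray
    pair_ch: np.ndarray
    trips: np.ndarray
    trip_kappa: np.ndarray
    trip_phi0: np.ndarray
    trip_ch: np.ndarray
    ring_id: np.ndarray
    n_rings: int
    ring_size: int
    kz: float
    has_beads: bool
    anchor_idx: int = -1          # fixed bead (or end anchor particle)
    drive_idx: int = -1           # mobile bead
    attach_idx: tuple = (0, 0)    # surface particles the beads tether to
    fixed_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_particles(self) -> int:
        return self.positions0.shape[0]

    def particle(self, ring: int, m: int) -> int:
        return ring * self.Np + m


def build_lattice(
    macro: P.MacroElastic,
    micro: P.MicroSprings | None = None,
    beads: bool = True,
) -> ShellLattice:
    """Build the cylinder lattice for ``macro``; ``micro`` defaults to the
    uncalibrated thin-shell map of ``macro``.

    The ring count is Nr = round(L/d) + 1 and the effective filament length
    (Nr-1)·d is stored as ``lattice.length``; strains are defined against
    it.  Requires L >= 5 d.
    """
    if macro.L < 5 * macro.d:
        raise TooShortError(f"L = {macro.L} nm < 5 d = {5 * macro.d} nm")
    if micro is None:
        micro = P.macro_to_micro(macro)
    Nr = int(round(macro.L / macro.d)) + 1
    Np = macro.Np
    R, d = macro.R, macro.d
    n_fil = Nr * Np
    n = n_fil + (2 if beads else 0)

    pos = np.empty((n, 3))
    theta = 2.0 * math.pi * np.arange(Np) / Np
    for j in range(Nr):
        sl = slice(j * Np, (j + 1) * Np)
        pos[sl, 0] = j * d
        pos[sl, 1] = R * np.cos(theta)
        pos[sl, 2] = R * np.sin(theta)

    pairs, pk, pr0, pch = [], [], [], []
    trips, tk, tp0, tch = [], [], [], []
    idx = lambda j, m: j * Np + m % Np

    p = macro.p
    poly_angle = math.pi * (Np - 2) / Np
    for j in range(Nr):
        for m in range(Np):
            if j + 1 < Nr:
                pairs.append((idx(j, m), idx(j + 1, m)))
                pk.append(micro.ka)
                pr0.append(d)
                pch.append(CH_AX_STRETCH)
            pairs.append((idx(j, m), idx(j, m + 1)))
            pk.append(micro.kc)
            pr0.append(p)
            pch.append(CH_CIRC_STRETCH)
            if 0 < j < Nr - 1:
                trips.append((idx(j - 1, m), idx(j, m), idx(j + 1, m)))
                tk.append(micro.kappa_a)
                tp0.append(math.pi)
                tch.append(CH_AX_BEND)
            trips.append((idx(j, m - 1), idx(j, m), idx(j, m + 1)))
            tk.append(micro.kappa_c)
            tp0.append(poly_angle)
            tch.append(CH_CIRC_BEND)
            # shear: one triplet per (axial arm, circumferential arm) pair
            for ja in (j - 1, j + 1):
                if 0 <= ja < Nr:
                    for mc in (m - 1, m + 1):
                        trips.append((idx(ja, m), idx(j, m), idx(j, mc)))
                        tk.append(micro.kappa_s)
                        tp0.append(math.pi / 2.0)
                        tch.append(CH_SHEAR)

    anchor = drive = -1
    attach = (idx(0, 0), idx(Nr - 1, 0))
    if beads:
        anchor, drive = n_fil, n_fil + 1
        pos[anchor] = (0.0, R + macro.b, 0.0)
        pos[drive] = ((Nr - 1) * d, R + macro.b, 0.0)
        for bead, att, nb in (
            (anchor, attach[0], idx(1, 0)),
            (drive, attach[1], idx(Nr - 2, 0)),
        ):
            pairs.append((att, bead))
            pk.append(micro.kb)
            pr0.append(macro.b)
            pch.append(CH_BEAD)
            trips.append((bead, att, nb))
            tk.append(micro.kappa_b)
            tp0.append(math.pi / 2.0)
            tch.append(CH_BEAD)

    ring_id = np.full(n, -1, dtype=np.int64)
    ring_id[:n_fil] = np.repeat(np.arange(Nr), Np)

    fixed = np.array([anchor, drive], dtype=np.int64) if beads else np.empty(0, dtype=np.int64)
    return ShellLattice(
        macro=macro,
        micro=micro,
        Nr=Nr,
        Np=Np,
        length=(Nr - 1) * d,
        positions0=pos,
        pairs=np.array(pairs, dtype=np.int64),
        pair_k=np.array(pk),
        pair_r0=np.array(pr0),
        pair_ch=np.array(pch, dtype=np.int64),
        trips=np.array(trips, dtype=np.int64),
        trip_kappa=np.array(tk),
        trip_phi0=np.array(tp0),
        trip_ch=np.array(tch, dtype=np.int64),
        ring_id=ring_id,
        n_rings=Nr,
        ring_size=Np,
        kz=LATERAL_SCALE * micro.ka,
        has_beads=beads,
        anchor_idx=anchor,
        drive_idx=drive,
        attach_idx=attach,
        fixed_idx=fixed,
    )


def build_microtubule(macro: P.MacroElastic, calibrate: bool = True) -> ShellLattice:
    """Convenience builder: calibrate the channel factors on a short test
    lattice (same d, Np), then build the production lattice."""
    factors = P.calibrate_factors(macro) if calibrate else P.ChannelFactors()
    return build_lattice(macro, P.macro_to_micro(macro, factors))


def shell_energy(lattice: ShellLattice, positions: np.ndarray) -> dict[str, float]:
    """Per-channel energy breakdown (pN·nm) of a configuration."""
    return energy_breakdown(lattice, positions)


def shell_gradient(lattice: ShellLattice, positions: np.ndarray):
    """(total energy, per-particle gradient) of a configuration."""
    e, g, _ = total_energy_grad(lattice, positions)
    return e, g


def ring_centroids(lattice: ShellLattice, positions: np.ndarray) -> np.ndarray:
    """(Nr, 3) centerline points: centroid of each ring."""
    fil = positions[: lattice.Nr * lattice.Np]
    return fil.reshape(lattice.Nr, lattice.Np, 3).mean(axis=1)


# ---------------------------------------------------------------------------
# canonical homogeneous deformations (used by the calibration op and tests)

def _filament_view(lat: ShellLattice):
    return lat.positions0.copy(), lat.Nr * lat.Np


def deform_axial_strain(lat: ShellLattice, delta: float) -> np.ndarray:
    pos, nf = _filament_view(lat)
    pos[:nf, 0] *= 1.0 + delta
    return pos


def deform_inflation(lat: ShellLattice, delta: float) -> np.ndarray:
    pos, nf = _filament_view(lat)
    pos[:nf, 1:] *= 1.0 + delta
    return pos


def deform_arc(lat: ShellLattice, c: float) -> np.ndarray:
    """Bend the centerline into a circular arc of curvature c in the x-y
    plane, cross-sections rotated rigidly to stay normal to the arc."""
    pos, nf = _filament_view(lat)
    rho = 1.0 / c
    x, y = pos[:nf, 0].copy(), pos[:nf, 1].copy()
    alpha = x * c
    pos[:nf, 0] = (rho - y) * np.sin(alpha)
    pos[:nf, 1] = rho - (rho - y) * np.cos(alpha)
    return pos


def deform_ovalization(lat: ShellLattice, eps: float) -> np.ndarray:
    """Inextensional n=2 ovalization: u_r = eps·R cos2θ,
    u_t = -(eps·R/2) sin2θ (zero hoop strain to first order)."""
    pos, nf = _filament_view(lat)
    R = lat.macro.R
    theta = np.arctan2(pos[:nf, 2], pos[:nf, 1])
    r_new = R + eps * R * np.cos(2.0 * theta)
    th_new = theta - 0.5 * eps * np.sin(2.0 * theta)
    pos[:nf, 1] = r_new * np.cos(th_new)
    pos[:nf, 2] = r_new * np.sin(th_new)
    return pos


def deform_twist(lat: ShellLattice, gamma: float) -> np.ndarray:
    """Uniform twist with surface engineering shear angle gamma."""
    pos, nf = _filament_view(lat)
    R = lat.macro.R
    phi = gamma * pos[:nf, 0] / R
    y, z = pos[:nf, 1].copy(), pos[:nf, 2].copy()
    pos[:nf, 1] = y * np.cos(phi) - z * np.sin(phi)
    pos[:nf, 2] = y * np.sin(phi) + z * np.cos(phi)
    return pos
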