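"""Discrete 1D elastic chain model of a bacterial flagellum.

N point masses along the trap axis connected by very stiff linear springs
(the filament is essentially inextensible) with a harmonic bending energy
on every interior triplet, rest angle pi.  The triplet bend constant kappa
maps to the flexural rigidity B through kappa = B·N/L.  Optical beads are
point particles tethered to the end masses by a stiff spring of rest
length b (the bead radius) plus a stiff angle constraint with rest angle
pi/2 that keeps the bead normal to the filament at the attachment point.

Because the beads displace the load points off the centerline, the
bead-loaded chain buckles smoothly without any symmetry-breaking seed and
its force-strain curve rises monotonically on both sides of zero strain,
steeper in extension than in compression.  A pinned-centerline variant
(``beads=False``) reproduces classical Euler buckling at
Fc = pi²·B/L² and needs a small transverse seed displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import CH_AX_BEND, CH_AX_STRETCH, CH_BEAD
from .network import energy_breakdown

__all__ = [
    "Chain1D",
    "build_chain",
    "euler_buckling_force",
    "chain_energy",
    "perturb_midpoint",
    "TooFewParticlesError",
]

#: ratio of numerical-constraint stiffness to the bending-derived scale
STIFF_SCALE = 1e3


class TooFewParticlesError(ValueError):
    """A chain needs at least 4 masses."""


@dataclass
class Chain1D:
    N: int
    L: float
    B: float
    l0: float
    k: float
    kappa: float
    kb: float
    kappa_b: float
    b: float
    has_beads: bool
    positions0: np.ndarray
    pairs: np.ndarray
    pair_k: np.ndarray
    pair_r0: np.ndarray
    pair_ch: np.ndarray
    trips: np.ndarray
    trip_kappa: np.ndarray
    trip_phi0: np.ndarray
    trip_ch: np.ndarray
    ring_id: np.ndarray
    n_rings: int = 0
    ring_size: int = 1
    kz: float = 0.0
    anchor_idx: int = -1
    drive_idx: int = -1
    attach_idx: tuple = (0, 0)
    fixed_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def length(self) -> float:
        return self.L

    @property
    def n_particles(self) -> int:
        return self.positions0.shape[0]


def euler_buckling_force(B: float, L: float) -> float:
    """Classical pinned-end buckling force pi²·B/L² (pN for pN·nm² and nm)."""
    if B < 0 or L <= 0:
        raise ValueError("need B >= 0 and L > 0")
    return math.pi**2 * B / L**2


def build_chain(
    B: float,
    L: float,
    N: int,
    b: float = 500.0,
    beads: bool = True,
    stiff_scale: float = STIFF_SCALE,
) -> Chain1D:
    """Build a straight chain along +x with kappa = B·N/L.

    The stretch and constraint constants are numerical: k and kb are
    ``stiff_scale`` times the bending-derived stiffness scale kappa/l0²,
    kappa_b is ``stiff_scale`` times kappa, large enough that tether and
    segment strain energies stay a negligible fraction of the bending
    energy (audited post-hoc in the tests).
    """
    if N < 4:
        raise TooFewParticlesError(f"N = {N} < 4")
    if B < 0 or L <= 0 or b <= 0:
        raise ValueError("need B >= 0, L > 0, b > 0")
    l0 = L / (N - 1)
    kappa = B * N / L
    k = stiff_scale * max(kappa / l0**2, 1e-9)
    kb = k
    kappa_b = stiff_scale * max(kappa, 1e-9)

    n = N + (2 if beads else 0)
    pos = np.zeros((n, 3))
    pos[:N, 0] = np.arange(N) * l0

    pairs, pk, pr0, pch = [], [], [], []
    trips, tk, tp0, tch = [], [], [], []
    for i in range(N - 1):
        pairs.append((i, i + 1))
        pk.append(k)
        pr0.append(l0)
        pch.append(CH_AX_STRETCH)
    for i in range(1, N - 1):
        trips.append((i - 1, i, i + 1))
        tk.append(kappa)
        tp0.append(math.pi)
        tch.append(CH_AX_BEND)

    anchor = drive = -1
    if beads:
        anchor, drive = N, N + 1
        pos[anchor] = (0.0, b, 0.0)
        pos[drive] = (L, b, 0.0)
        for bead, att, nb in ((anchor, 0, 1), (drive, N - 1, N - 2)):
            pairs.append((att, bead))
            pk.append(kb)
            pr0.append(b)
            pch.append(CH_BEAD)
            trips.append((bead, att, nb))
            tk.append(kappa_b)
            tp0.append(math.pi / 2.0)
            tch.append(CH_BEAD)
        fixed = np.array([anchor, drive], dtype=np.int64)
    else:
        anchor, drive = 0, N - 1
        fixed = np.array([0, N - 1], dtype=np.int64)

    return Chain1D(
        N=N,
        L=L,
        B=B,
        l0=l0,
        k=k,
        kappa=kappa,
        kb=kb,
        kappa_b=kappa_b,
        b=b,
        has_beads=beads,
        positions0=pos,
        pairs=np.array(pairs, dtype=np.int64),
        pair_k=np.array(pk),
        pair_r0=np.array(pr0),
        pair_ch=np.array(pch, dtype=np.int64),
        trips=np.array(trips, dtype=np.int64),
        trip_kappa=np.array(tk),
        trip_phi0=np.array(tp0),
        trip_ch=np.array(tch, dtype=np.int64),
        ring_id=np.full(n, -1, dtype=np.int64),
        anchor_idx=anchor,
        drive_idx=drive,
        attach_idx=(0, N - 1),
        fixed_idx=fixed,
    )


def chain_energy(chain: Chain1D, positions: np.ndarray) -> dict[str, float]:
    """Energy breakdown {stretch, bend, bead} in pN·nm (each term >= 0)."""
    e = energy_breakdown(chain, positions)
    return {"stretch": e["axial_stretch"], "bend": e["axial_bend"], "bead": e["bead"]}


def perturb_midpoint(chain: Chain1D, amplitude: float | None = None) -> np.ndarray:
    """Rest positions with a transverse (+y) seed displacement at the
    midpoint, default 1e-3·L; used for the pinned-centerline Euler test
    where the load is exactly on-axis."""
    pos = chain.positions0.copy()
    pos[chain.N // 2, 1] += amplitude if amplitude is not None else 1e-3 * chain.L
    return pos
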