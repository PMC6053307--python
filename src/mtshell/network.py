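"""Shared spring-network plumbing used by the 1D chain and the 3D shell.

A "system" is any object exposing the kernel arrays (``pairs``, ``pair_k``,
``pair_r0``, ``pair_ch``, ``trips``, ``trip_kappa``, ``trip_phi0``,
``trip_ch``, ``ring_id``, ``n_rings``, ``ring_size``, ``kz``) plus rest
positions ``positions0``, the indices of the two bead/anchor particles
(``anchor_idx`` held fixed, ``drive_idx`` moved by the protocol), and the
equilibrium separation ``length``.  The trap axis is +x by convention.
"""

from __future__ import annotations

import numpy as np

from ._kernels import CHANNEL_NAMES, energy_grad

__all__ = ["GeometryError", "energy_breakdown", "total_energy_grad", "kernel_args"]


class GeometryError(ValueError):
    """Coincident bonded particles or a zero-length angle leg."""


def kernel_args(sys):
    return (
        sys.pairs,
        sys.pair_k,
        sys.pair_r0,
        sys.pair_ch,
        sys.trips,
        sys.trip_kappa,
        sys.trip_phi0,
        sys.trip_ch,
        sys.ring_id,
        sys.n_rings,
        sys.ring_size,
        sys.kz,
    )


def total_energy_grad(sys, pos: np.ndarray):
    """Total energy (pN·nm) and gradient (pN) of a configuration."""
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    if not np.all(np.isfinite(pos)):
        raise GeometryError("non-finite positions")
    energies, grad, err = energy_grad(pos, *kernel_args(sys))
    if err:
        raise GeometryError(
            "degenerate geometry: coincident bonded pair"
            if err == 1
            else "degenerate geometry: zero-length angle leg"
        )
    return float(energies.sum()), grad, energies


def energy_breakdown(sys, pos: np.ndarray) -> dict[str, float]:
    """Per-channel energies of a configuration, all >= 0, in pN·nm."""
    _, _, energies = total_energy_grad(sys, pos)
    return {name: float(e) for name, e in zip(CHANNEL_NAMES, energies)}
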