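"""Numba kernels for spring-network energies and analytic gradients.

Both the 1D chain and the 3D shell reduce to the same primitive interactions:
harmonic pair springs V = k/2 (l - l0)^2 and harmonic angle triplets
V = kappa/2 (phi - phi0)^2, tagged with a channel id so that energy
breakdowns (axial/circumferential stretch and bend, shear, bead, lateral)
can be reported per channel.

Channel ids (fixed across the package):
    0 axial stretch   1 circumferential stretch
    2 axial bend      3 circumferential bend
    4 shear           5 bead (tether + normal-angle)
    6 lateral stabilization penalty
"""

import numpy as np
from numba import njit

N_CHANNELS = 7
CH_AX_STRETCH = 0
CH_CIRC_STRETCH = 1
CH_AX_BEND = 2
CH_CIRC_BEND = 3
CH_SHEAR = 4
CH_BEAD = 5
CH_LATERAL = 6

CHANNEL_NAMES = (
    "axial_stretch",
    "circ_stretch",
    "axial_bend",
    "circ_bend",
    "shear",
    "bead",
    "lateral",
)


@njit(cache=True, fastmath=True)
def energy_grad(
    pos,            # (N, 3) float64
    pairs,          # (np_, 2) int64
    pair_k,         # (np_,) float64
    pair_r0,        # (np_,) float64
    pair_ch,        # (np_,) int64
    trips,          # (nt, 3) int64, angle at middle index
    trip_kappa,     # (nt,) float64
    trip_phi0,      # (nt,) float64
    trip_ch,        # (nt,) int64
    ring_id,        # (N,) int64, -1 for particles outside any ring
    n_rings,        # int
    ring_size,      # int (particles per ring)
    kz,             # lateral centroid-z penalty stiffness (0 disables)
):
    """Return (per-channel energies, gradient, error flag).

    error flag: 0 ok, 1 coincident bonded pair, 2 degenerate angle leg.
    """
    n = pos.shape[0]
    grad = np.zeros((n, 3))
    energies = np.zeros(N_CHANNELS)
    err = 0

    for a in range(pairs.shape[0]):
        i = pairs[a, 0]
        j = pairs[a, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            err = 1
            continue
        dl = r - pair_r0[a]
        k = pair_k[a]
        energies[pair_ch[a]] += 0.5 * k * dl * dl
        f = k * dl / r
        grad[j, 0] += f * dx
        grad[j, 1] += f * dy
        grad[j, 2] += f * dz
        grad[i, 0] -= f * dx
        grad[i, 1] -= f * dy
        grad[i, 2] -= f * dz

    for a in range(trips.shape[0]):
        i = trips[a, 0]
        j = trips[a, 1]
        k3 = trips[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k3, 0] - pos[j, 0]
        vy = pos[k3, 1] - pos[j, 1]
        vz = pos[k3, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            err = 2
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        phi = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        kap = trip_kappa[a]
        dphi = phi - trip_phi0[a]
        energies[trip_ch[a]] += 0.5 * kap * dphi * dphi
        # dE/dphi * dphi/dcos * dcos/dr
        pref = kap * dphi * (-1.0 / s)
        inv_uv = 1.0 / (nu * nv)
        inv_u2 = 1.0 / (nu * nu)
        inv_v2 = 1.0 / (nv * nv)
        gix = pref * (vx * inv_uv - c * ux * inv_u2)
        giy = pref * (vy * inv_uv - c * uy * inv_u2)
        giz = pref * (vz * inv_uv - c * uz * inv_u2)
        gkx = pref * (ux * inv_uv - c * vx * inv_v2)
        gky = pref * (uy * inv_uv - c * vy * inv_v2)
        gkz = pref * (uz * inv_uv - c * vz * inv_v2)
        grad[i, 0] += gix
        grad[i, 1] += giy
        grad[i, 2] += giz
        grad[k3, 0] += gkx
        grad[k3, 1] += gky
        grad[k3, 2] += gkz
        grad[j, 0] -= gix + gkx
        grad[j, 1] -= giy + gky
        grad[j, 2] -= giz + gkz

    if kz > 0.0 and n_rings > 0:
        inv_m = 1.0 / ring_size
        zc = np.zeros(n_rings)
        for a in range(n):
            r = ring_id[a]
            if r >= 0:
                zc[r] += pos[a, 2] * inv_m
        for r in range(n_rings):
            energies[CH_LATERAL] += 0.5 * kz * zc[r] * zc[r]
        for a in range(n):
            r = ring_id[a]
            if r >= 0:
                grad[a, 2] += kz * zc[r] * inv_m

    return energies, grad, err
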