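"""Damped-Newton energy minimizer with a sparse Hessian.

Quasistatic spring networks mix very stiff constraint springs (bead
tethers, inextensibility) with soft long-wavelength bending modes; the
resulting conditioning defeats first-order minimizers.  A Newton method
with the exact sparse Hessian is insensitive to it: pair-spring Hessian
blocks are analytic, angle-triplet blocks are obtained by central finite
differences of the analytic per-triplet gradient (error ~1e-8 of the
stiffness scale, far below the force tolerance).  Indefiniteness away
from a minimum is handled with a Levenberg-style diagonal shift chosen
adaptively so that every accepted step decreases the energy.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse
import scipy.sparse.linalg
from numba import njit

from .network import total_energy_grad


@njit(cache=True, fastmath=True)
def _pair_hess(pos, pairs, pair_k, pair_r0, rows, cols, vals, start):
    n = 0
    for a in range(pairs.shape[0]):
        i = pairs[a, 0]
        j = pairs[a, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < 1e-12:
            continue
        k = pair_k[a]
        c1 = k * pair_r0[a] / (r * r2)      # coefficient of rr^T correction
        c2 = k * (1.0 - pair_r0[a] / r)     # isotropic part
        d = (dx, dy, dz)
        for a1 in range(3):
            for a2 in range(3):
                h = c1 * d[a1] * d[a2]
                if a1 == a2:
                    h += c2
                p = start + n
                rows[p] = 3 * i + a1
                cols[p] = 3 * i + a2
                vals[p] = h
                rows[p + 1] = 3 * j + a1
                cols[p + 1] = 3 * j + a2
                vals[p + 1] = h
                rows[p + 2] = 3 * i + a1
                cols[p + 2] = 3 * j + a2
                vals[p + 2] = -h
                rows[p + 3] = 3 * j + a1
                cols[p + 3] = 3 * i + a2
                vals[p + 3] = -h
                n += 4
    return start + n


@njit(cache=True, fastmath=True, inline="always")
def _angle_grad9(x, kappa, phi0, out):
    """Gradient of the angle energy wrt the 9 coords (i, j, k)."""
    ux = x[0] - x[3]
    uy = x[1] - x[4]
    uz = x[2] - x[5]
    vx = x[6] - x[3]
    vy = x[7] - x[4]
    vz = x[8] - x[5]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    s = np.sqrt(1.0 - c * c)
    if s < 1e-8:
        s = 1e-8
    pref = kappa * (np.arccos(c) - phi0) * (-1.0 / s)
    inv_uv = 1.0 / (nu * nv)
    inv_u2 = 1.0 / (nu * nu)
    inv_v2 = 1.0 / (nv * nv)
    gix = pref * (vx * inv_uv - c * ux * inv_u2)
    giy = pref * (vy * inv_uv - c * uy * inv_u2)
    giz = pref * (vz * inv_uv - c * uz * inv_u2)
    gkx = pref * (ux * inv_uv - c * vx * inv_v2)
    gky = pref * (uy * inv_uv - c * vy * inv_v2)
    gkz = pref * (uz * inv_uv - c * vz * inv_v2)
    out[0] = gix
    out[1] = giy
    out[2] = giz
    out[3] = -(gix + gkx)
    out[4] = -(giy + gky)
    out[5] = -(giz + gkz)
    out[6] = gkx
    out[7] = gky
    out[8] = gkz


@njit(cache=True, fastmath=True)
def _trip_hess(pos, trips, trip_kappa, trip_phi0, rows, cols, vals, start):
    x = np.empty(9)
    gp = np.empty(9)
    gm = np.empty(9)
    n = 0
    for a in range(trips.shape[0]):
        i = trips[a, 0]
        j = trips[a, 1]
        k3 = trips[a, 2]
        for c in range(3):
            x[c] = pos[i, c]
            x[3 + c] = pos[j, c]
            x[6 + c] = pos[k3, c]
        # FD scale tied to the leg lengths
        l1 = np.sqrt((x[0] - x[3]) ** 2 + (x[1] - x[4]) ** 2 + (x[2] - x[5]) ** 2)
        l2 = np.sqrt((x[6] - x[3]) ** 2 + (x[7] - x[4]) ** 2 + (x[8] - x[5]) ** 2)
        h = 1e-5 * (l1 if l1 < l2 else l2)
        if h < 1e-9:
            continue
        kappa = trip_kappa[a]
        phi0 = trip_phi0[a]
        dofs = (3 * i, 3 * i + 1, 3 * i + 2, 3 * j, 3 * j + 1, 3 * j + 2,
                3 * k3, 3 * k3 + 1, 3 * k3 + 2)
        for col in range(9):
            xc = x[col]
            x[col] = xc + h
            _angle_grad9(x, kappa, phi0, gp)
            x[col] = xc - h
            _angle_grad9(x, kappa, phi0, gm)
            x[col] = xc
            for row in range(9):
                p = start + n
                rows[p] = dofs[row]
                cols[p] = dofs[col]
                vals[p] = (gp[row] - gm[row]) / (2.0 * h)
                n += 1
    return start + n


@njit(cache=True, fastmath=True)
def _lateral_hess(ring_id, n_particles, n_rings, ring_size, kz, rows, cols, vals, start):
    # E = kz/2 * sum_r (mean_z_r)^2 -> H(z_a, z_b) = kz / ring_size^2 for a,b in same ring
    n = 0
    if kz <= 0.0 or n_rings == 0:
        return start
    members = np.full((n_rings, ring_size), -1, dtype=np.int64)
    count = np.zeros(n_rings, dtype=np.int64)
    for a in range(n_particles):
        r = ring_id[a]
        if r >= 0:
            members[r, count[r]] = a
            count[r] += 1
    h = kz / (ring_size * ring_size)
    for r in range(n_rings):
        for a1 in range(count[r]):
            for a2 in range(count[r]):
                p = start + n
                rows[p] = 3 * members[r, a1] + 2
                cols[p] = 3 * members[r, a2] + 2
                vals[p] = h
                n += 1
    return start + n


@njit(cache=True)
def _scatter(vals, slot, out):
    for i in range(vals.shape[0]):
        s = slot[i]
        if s >= 0:
            out[s] += vals[i]


class _HessianWorkspace:
    """Caches the (fixed) sparsity pattern of the free-DOF Hessian so each
    assembly only recomputes values and scatters them into a CSC matrix."""

    def __init__(self, sys):
        n_entries = (
            36 * sys.pairs.shape[0]
            + 81 * sys.trips.shape[0]
            + sys.n_rings * sys.ring_size**2
        )
        self.rows = np.empty(n_entries, dtype=np.int64)
        self.cols = np.empty(n_entries, dtype=np.int64)
        self.vals = np.empty(n_entries)
        free = np.ones(sys.positions0.shape[0], dtype=bool)
        if len(sys.fixed_idx):
            free[sys.fixed_idx] = False
        self.free = free
        free_dof = np.repeat(free, 3)
        self.ndof_free = int(free_dof.sum())
        # one structural pass to freeze the entry ordering
        n = self._fill(sys, sys.positions0)
        self.n_entries = n
        dof_map = np.full(3 * sys.positions0.shape[0], -1, dtype=np.int64)
        dof_map[free_dof] = np.arange(self.ndof_free)
        r = dof_map[self.rows[:n]]
        c = dof_map[self.cols[:n]]
        keep = (r >= 0) & (c >= 0)
        order = np.lexsort((r[keep], c[keep]))
        rk, ck = r[keep][order], c[keep][order]
        newgrp = np.ones(len(order), dtype=bool)
        newgrp[1:] = (rk[1:] != rk[:-1]) | (ck[1:] != ck[:-1])
        slot_sorted = np.cumsum(newgrp) - 1
        nnz = int(slot_sorted[-1]) + 1 if len(order) else 0
        slot = np.full(n, -1, dtype=np.int64)
        kept_idx = np.nonzero(keep)[0]
        slot[kept_idx[order]] = slot_sorted
        self.slot = slot
        indices = rk[newgrp]
        cols_unique = ck[newgrp]
        indptr = np.zeros(self.ndof_free + 1, dtype=np.int64)
        np.add.at(indptr, cols_unique + 1, 1)
        indptr = np.cumsum(indptr)
        self.template = scipy.sparse.csc_matrix(
            (np.zeros(nnz), indices.astype(np.int32), indptr.astype(np.int32)),
            shape=(self.ndof_free, self.ndof_free),
        )
        self.diag_slots = None

    def _fill(self, sys, pos):
        n = _pair_hess(pos, sys.pairs, sys.pair_k, sys.pair_r0, self.rows, self.cols, self.vals, 0)
        n = _trip_hess(pos, sys.trips, sys.trip_kappa, sys.trip_phi0, self.rows, self.cols, self.vals, n)
        n = _lateral_hess(sys.ring_id, pos.shape[0], sys.n_rings, sys.ring_size, sys.kz,
                          self.rows, self.cols, self.vals, n)
        return n

    def assemble(self, sys, pos):
        """Free-DOF Hessian as CSC (shared storage: valid until next call)."""
        n = self._fill(sys, pos)
        data = np.zeros(self.template.nnz)
        _scatter(self.vals[:n], self.slot, data)
        self.template.data = data
        return self.template


def newton_minimize(sys, positions, tol=1e-3, max_iter=200, workspace=None):
    """Minimize the network energy over the free particles to max residual
    force <= tol (pN).  Returns (positions, n_iter, max_residual).
    """
    pos = np.array(positions, dtype=float)
    ws = workspace or _HessianWorkspace(sys)
    free = ws.free

    lam = 0.0
    e, g, _ = total_energy_grad(sys, pos)
    for it in range(max_iter):
        resid = np.sqrt((g[free] ** 2).sum(axis=1)).max() if free.any() else 0.0
        if resid <= tol:
            return pos, it, float(resid)
        H = ws.assemble(sys, pos)
        gf = g[free].ravel()
        diag = np.maximum(H.diagonal(), 1e-12)
        base = H.data.copy()
        accepted = False
        for _ in range(60):
            if lam > 0:
                H.data = base
                Hs = H + scipy.sparse.diags(lam * diag, format="csc")
            else:
                Hs = H
            try:
                step = scipy.sparse.linalg.splu(Hs).solve(-gf)
            except RuntimeError:
                step = None
            if step is not None and np.all(np.isfinite(step)) and step @ gf < 0:
                # backtracking line search along the (damped) Newton step
                alpha = 1.0
                for _ls in range(8):
                    trial = pos.copy()
                    trial[free] += alpha * step.reshape(-1, 3)
                    e_t, g_t, _ = total_energy_grad(sys, trial)
                    # strict decrease: never settle on a saddle from above
                    if np.isfinite(e_t) and e_t <= e + 1e-12 * max(abs(e), 1.0):
                        pos, e, g = trial, e_t, g_t
                        lam = lam * 0.25 if lam > 1e-8 else 0.0
                        accepted = True
                        break
                    alpha *= 0.25
                if accepted:
                    break
            lam = max(lam * 10.0, 1e-6)
        if not accepted:
            break
    resid = np.sqrt((g[free] ** 2).sum(axis=1)).max() if free.any() else 0.0
    return pos, max_iter if accepted else it, float(resid)


def lowest_eigenmode(sys, pos, workspace=None):
    """Smallest-eigenvalue mode of the free-DOF Hessian at ``pos``.

    Returns (eigenvalue, per-particle displacement field with zeros on the
    fixed particles).  Used to detect and escape saddle points at buckling
    bifurcations.
    """
    ws = workspace or _HessianWorkspace(sys)
    free = ws.free
    H = ws.assemble(sys, pos).copy()
    sigma = -1e-9 * max(float(np.median(np.abs(H.diagonal()))), 1.0)
    try:
        w, v = scipy.sparse.linalg.eigsh(H, k=1, sigma=sigma, which="LM")
    except RuntimeError:
        w, v = scipy.sparse.linalg.eigsh(H, k=1, which="SA")
    mode = np.zeros_like(pos)
    mode[free] = v[:, 0].reshape(-1, 3)
    return float(w[0]), mode


def relax_to_stable(sys, positions, tol=1e-3, max_iter=200, workspace=None,
                    kick_amp=None, max_escapes=40):
    """Minimize and, if the converged point has a negative Hessian mode
    (a saddle: e.g. the straight state of a centerline-loaded filament
    past the buckling load), kick along that mode and re-minimize until a
    stable minimum is reached.  Returns (positions, n_escapes, residual).
    """
    ws = workspace or _HessianWorkspace(sys)
    amp = kick_amp if kick_amp is not None else 1e-3 * getattr(sys, "length", 1.0)
    pos, _, resid = newton_minimize(sys, positions, tol, max_iter, ws)
    for esc in range(max_escapes):
        w, mode = lowest_eigenmode(sys, pos, ws)
        if w > -1e-10:
            return pos, esc, resid
        scale = np.abs(mode).max()
        pos = pos + (amp / scale) * mode
        pos, _, resid = newton_minimize(sys, pos, tol, max_iter, ws)
    return pos, max_escapes, resid
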