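"""Quasistatic overdamped trap-displacement protocol.

One bead (the anchor, playing the detection trap) is held fixed; the other
(the drive, playing the manipulation trap) is stepped along the trap axis
in small increments.  After every step the network is relaxed to mechanical
equilibrium — the contract is a converged force balance (max residual
force below ``tol`` on every free particle), delivered by a damped-Newton
minimizer over the free coordinates (:mod:`mtshell.minimize`), which is
equivalent to integrating the overdamped dynamics to stationarity.  The
measured force is the axial
component of the net constraint force on the anchor bead, signed positive
under compression.

The relaxation time of the physical overdamped dynamics scales as
gamma·L⁴/B; the protocol's validity is certified not by a particular
friction but by the absence of forward/backward hysteresis before any
kinking transition (see :func:`hysteresis_gap`).
"""

from __future__ import annotations

import sys as _sys
import time as _time
from dataclasses import dataclass, field

import numpy as np

from ._kernels import CHANNEL_NAMES
from .minimize import _HessianWorkspace, newton_minimize
from .network import total_energy_grad

__all__ = [
    "ProtocolSpec",
    "Trajectory",
    "RelaxReport",
    "relax",
    "measured_force",
    "max_transverse",
    "max_deflection",
    "run_protocol",
    "run_compression_to_kink",
    "hysteresis_gap",
    "compression_schedule",
    "RelaxationError",
    "InsufficientDataError",
]


#: max per-particle displacement (nm) of the last step for which the
#: secant predictor is still extrapolated
_PREDICTOR_CAP = 150.0


class RelaxationError(RuntimeError):
    """Relaxation failed to converge; carries the partial trajectory."""

    def __init__(self, msg, trajectory=None, step=None):
        super().__init__(msg)
        self.trajectory = trajectory
        self.step = step


class InsufficientDataError(ValueError):
    pass


@dataclass
class ProtocolSpec:
    """Trap-stepping protocol.

    ``schedule`` is the ordered list of target bead separations (nm),
    monotone within each sweep.  ``tol`` is the convergence threshold on
    the max residual force per free particle (pN); default two orders of
    magnitude below the pN-scale measured forces.  ``gamma`` (pN·s/nm) and
    the thermal flags only matter when seeded Langevin kicks are enabled
    for hysteresis studies.
    """

    schedule: np.ndarray
    dx: float = 8.0
    tol: float = 1e-3
    max_iter: int = 200
    gamma: float = 1e-6
    thermal: bool = False
    kT: float = 4.1  # pN·nm, room temperature
    n_kicks: int = 3
    kick_dt: float = 1e-4
    seed: int = 0
    on_failure: str = "abort"  # or "flag"
    store_positions: bool = True
    check_stability: bool = False  # escape saddle points via eigenmode kicks

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.dx <= 0 or self.tol <= 0:
            raise ValueError("dx and tol must be positive")


@dataclass
class RelaxReport:
    converged: bool
    max_residual: float
    n_iter: int
    energy: float


@dataclass
class Trajectory:
    """One row per protocol step: bead separation, strain, measured force
    (pN, positive in compression), per-channel energies (pN·nm), max
    transverse centerline displacement from the trap axis (nm), sweep
    direction (+1 compression/forward, -1 release/backward), convergence
    flag, and optional position snapshots."""

    db: np.ndarray
    strain: np.ndarray
    force: np.ndarray
    energies: np.ndarray            # (n_steps, n_channels)
    max_transverse: np.ndarray
    max_deflection: np.ndarray
    direction: np.ndarray
    converged: np.ndarray
    positions: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.db)

    def energy_channel(self, name: str) -> np.ndarray:
        return self.energies[:, CHANNEL_NAMES.index(name)]

    def to_dataframe(self):
        import pandas as pd

        d = {
            "db_nm": self.db,
            "strain": self.strain,
            "force_pN": self.force,
            "max_transverse_nm": self.max_transverse,
            "max_deflection_nm": self.max_deflection,
            "direction": self.direction,
            "converged": self.converged,
        }
        for i, name in enumerate(CHANNEL_NAMES):
            d[f"E_{name}_pNnm"] = self.energies[:, i]
        return pd.DataFrame(d)


def compression_schedule(
    L: float,
    max_strain: float,
    dx: float,
    backward: bool = False,
    extension_strain: float = 0.0,
) -> np.ndarray:
    """Bead-separation schedule from strain 0 down to ``-|max_strain|``
    (optionally back up, optionally on to ``+extension_strain``)."""
    lo = L * (1.0 - abs(max_strain))
    fwd = np.arange(L, lo - 1e-9, -dx)
    parts = [fwd]
    if backward or extension_strain > 0:
        # release sweep; also required before stepping into extension
        parts.append(fwd[-2::-1])
    if extension_strain > 0:
        hi = L * (1.0 + extension_strain)
        parts.append(np.arange(L + dx, hi + 1e-9, dx))
    return np.concatenate(parts)


def _max_residual(sys, grad):
    g = grad.copy()
    if len(sys.fixed_idx):
        g[sys.fixed_idx] = 0.0
    return float(np.sqrt((g**2).sum(axis=1)).max())


def relax(sys, positions, tol: float = 1e-3, max_iter: int = 200, workspace=None):
    """Minimize the network energy with the bead/anchor particles held
    fixed (damped Newton with a sparse Hessian; see :mod:`mtshell.minimize`);
    returns (positions, RelaxReport).  Non-convergence is flagged in the
    report, never silently accepted."""
    pos, nit, resid = newton_minimize(sys, positions, tol=tol, max_iter=max_iter,
                                      workspace=workspace)
    e, _, echan = total_energy_grad(sys, pos)
    if not np.isfinite(e):
        bad = [CHANNEL_NAMES[i] for i in range(len(echan)) if not np.isfinite(echan[i])]
        suspect = bad[0] if bad else CHANNEL_NAMES[int(np.argmax(echan))]
        raise RelaxationError(
            f"energy diverged during relaxation (suspected channel: {suspect})")
    return pos, RelaxReport(resid <= tol, resid, int(nit), float(e))


def measured_force(sys, positions) -> float:
    """Axial force the network exerts on the anchor bead, projected on the
    outward trap-axis direction: positive when the filament pushes the
    beads apart (compression)."""
    _, g, _ = total_energy_grad(sys, positions)
    # anchor sits at smaller x; outward is -x, force on bead is -grad
    return float(g[sys.anchor_idx, 0])


def _centerline(sys, positions):
    if getattr(sys, "n_rings", 0) > 0:
        nf = sys.n_rings * sys.ring_size
        return positions[:nf].reshape(sys.n_rings, sys.ring_size, 3).mean(axis=1)
    n = getattr(sys, "N", positions.shape[0])
    return positions[:n]


def max_transverse(sys, positions) -> float:
    """Maximum perpendicular distance of the centerline (ring centroids or
    chain masses) from the line joining the two bead/anchor particles."""
    pts = _centerline(sys, positions)
    a = positions[sys.anchor_idx]
    u = positions[sys.drive_idx] - a
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        return float(np.linalg.norm(pts - a, axis=1).max())
    u = u / nu
    rel = pts - a
    perp = rel - np.outer(rel @ u, u)
    return float(np.linalg.norm(perp, axis=1).max())


def max_deflection(sys, positions) -> float:
    """Maximum perpendicular distance of the centerline from the chord
    joining its own end points — the filament's buckling amplitude
    (deflection from rest), zero for the undeformed configuration."""
    pts = _centerline(sys, positions)
    u = pts[-1] - pts[0]
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        return 0.0
    u = u / nu
    rel = pts - pts[0]
    perp = rel - np.outer(rel @ u, u)
    return float(np.linalg.norm(perp, axis=1).max())


def _step_positions(sys, pos, db):
    """Place the drive bead at separation ``db`` along the trap axis."""
    pos = pos.copy()
    rest = sys.positions0
    pos[sys.drive_idx] = rest[sys.drive_idx] + np.array([db - sys.length, 0.0, 0.0])
    pos[sys.anchor_idx] = rest[sys.anchor_idx]
    return pos


def _thermal_kicks(sys, pos, spec, rng):
    free = np.ones(pos.shape[0], dtype=bool)
    free[sys.fixed_idx] = False
    sigma = np.sqrt(2.0 * spec.kT * spec.kick_dt / spec.gamma)
    for _ in range(spec.n_kicks):
        kicked = pos.copy()
        kicked[free] += rng.normal(0.0, sigma, size=(free.sum(), 3))
        pos, _ = relax(sys, kicked, spec.tol, spec.max_iter)
    return pos


def run_protocol(sys, spec: ProtocolSpec) -> Trajectory:
    """Execute the trap-stepping schedule and return the trajectory."""
    rng = np.random.default_rng(spec.seed)
    ws = _HessianWorkspace(sys)
    pos = sys.positions0.copy()
    prev_pos = None
    rows = {k: [] for k in ("db", "strain", "force", "emat", "mt", "defl", "dirn", "conv")}
    positions = []
    prev_db = sys.length
    db_hist = [sys.length]
    for i, db in enumerate(np.atleast_1d(spec.schedule)):
        # secant continuation predictor: extrapolate the previous relaxed
        # displacement, scaled to the upcoming step size
        if prev_pos is None or len(db_hist) < 2 or db_hist[-1] == db_hist[-2] \
                or np.abs(pos - prev_pos).max() > _PREDICTOR_CAP:
            guess = pos
        else:
            f = np.clip((db - db_hist[-1]) / (db_hist[-1] - db_hist[-2]), -2.0, 2.0)
            guess = pos + f * (pos - prev_pos)
        prev_pos = pos
        db_hist = [db_hist[-1], db]
        pos = _step_positions(sys, guess, db)
        if spec.check_stability:
            from .minimize import relax_to_stable

            pos, _, resid = relax_to_stable(sys, pos, spec.tol, spec.max_iter, ws)
            rep = RelaxReport(resid <= spec.tol, resid, -1, 0.0)
        else:
            pos, rep = relax(sys, pos, spec.tol, spec.max_iter, workspace=ws)
            for _ in range(3):
                if rep.converged:
                    break
                pos, rep = relax(sys, pos, spec.tol, spec.max_iter, workspace=ws)
        if spec.thermal:
            pos = _thermal_kicks(sys, pos, spec, rng)
        if not rep.converged and spec.on_failure == "abort":
            traj = _collect(rows, positions, sys, spec)
            raise RelaxationError(
                f"relaxation did not converge at step {i} (db={db:.1f} nm, "
                f"residual {rep.max_residual:.2e} pN)",
                trajectory=traj,
                step=i,
            )
        e, g, echan = total_energy_grad(sys, pos)
        rows["db"].append(db)
        rows["strain"].append((db - sys.length) / sys.length)
        rows["force"].append(float(g[sys.anchor_idx, 0]))
        rows["emat"].append(echan.copy())
        rows["mt"].append(max_transverse(sys, pos))
        rows["defl"].append(max_deflection(sys, pos))
        rows["dirn"].append(-1 if db > prev_db else 1)
        rows["conv"].append(rep.converged)
        if spec.store_positions:
            positions.append(pos.copy())
        prev_db = db
    return _collect(rows, positions, sys, spec)


def _collect(rows, positions, sys, spec) -> Trajectory:
    return Trajectory(
        db=np.array(rows["db"]),
        strain=np.array(rows["strain"]),
        force=np.array(rows["force"]),
        energies=np.array(rows["emat"]) if rows["emat"] else np.empty((0, len(CHANNEL_NAMES))),
        max_transverse=np.array(rows["mt"]),
        max_deflection=np.array(rows["defl"]),
        direction=np.array(rows["dirn"], dtype=int),
        converged=np.array(rows["conv"], dtype=bool),
        positions=positions,
        meta={"L": sys.length, "tol": spec.tol, "dx": spec.dx},
    )


def run_compression_to_kink(
    sys,
    coarse_dx: float = 40.0,
    fine_dx: float = 8.0,
    max_strain: float = 0.3,
    tol: float = 1e-3,
    max_iter: int = 600,
    drop_frac: float = 0.01,
    flatness_min: float = 0.3,
    extra_steps: int = 2,
    refine_frac: float = 0.333,
    ramp_dx: float = 5.0,
    seed: int = 0,
    verbose: bool = False,
) -> Trajectory:
    """Compress until the first kink (cross-sectional collapse) and a few
    steps beyond.

    The trap step adapts to the solver effort: it starts at ``ramp_dx``
    (the early post-buckling branch is strongly nonlinear in the soft
    pivot/bow mode), grows geometrically towards ``coarse_dx`` while
    continuation converges quickly, shrinks when it does not, and drops to
    ``fine_dx`` once the interior flatness has built up beyond
    ``refine_frac``·``flatness_min`` (ovalization approaching collapse).  A kink is declared when the force drops by more than
    ``drop_frac`` between consecutive compressive steps while the interior
    flatness exceeds ``flatness_min``; the run stops ``extra_steps`` later
    (so centered force derivatives exist at the kink step), or at
    ``max_strain`` with a ``no_kink`` flag.
    """
    from .observables import flatness_profile, flatness_spikes  # local import to avoid a cycle

    spec = ProtocolSpec(schedule=np.array([sys.length]), dx=fine_dx, tol=tol,
                        max_iter=max_iter, seed=seed)
    ws = _HessianWorkspace(sys)
    pos = sys.positions0.copy()
    prev_pos = None
    rows = {k: [] for k in ("db", "strain", "force", "emat", "mt", "defl", "dirn", "conv")}
    positions = []
    db = sys.length
    dx = ramp_dx
    fine = False
    kink_step = None
    steps_after = 0
    i = 0
    while True:
        if i > 0:
            db -= fine_dx if fine else dx
        if (sys.length - db) / sys.length > max_strain:
            break
        if prev_pos is None or len(rows["db"]) < 2 or rows["db"][-1] == rows["db"][-2] \
                or np.abs(pos - prev_pos).max() > _PREDICTOR_CAP:
            # no extrapolation across a collapse event: a kink step moves
            # particles by hundreds of nm and must not be doubled
            guess = pos
        else:
            f = np.clip((db - rows["db"][-1]) / (rows["db"][-1] - rows["db"][-2]), -4.0, 4.0)
            guess = pos + f * (pos - prev_pos)
        prev_pos = pos
        pos = _step_positions(sys, guess, db)
        t0 = _time.time()
        pos, rep = relax(sys, pos, tol, max_iter, workspace=ws)
        for _ in range(3):
            if rep.converged:
                break
            pos, rep = relax(sys, pos, tol, max_iter, workspace=ws)
        e, g, echan = total_energy_grad(sys, pos)
        f = float(g[sys.anchor_idx, 0])
        if verbose:
            print(
                f"step {i} db={db:.1f} strain={(db - sys.length) / sys.length:+.4f} "
                f"F={f:.3f} resid={rep.max_residual:.1e} dx={dx:.1f} fine={fine} "
                f"t={_time.time() - t0:.1f}s",
                file=_sys.stderr, flush=True,
            )
        rows["db"].append(db)
        rows["strain"].append((db - sys.length) / sys.length)
        rows["force"].append(f)
        rows["emat"].append(echan.copy())
        rows["mt"].append(max_transverse(sys, pos))
        rows["defl"].append(max_deflection(sys, pos))
        rows["dirn"].append(1)
        rows["conv"].append(rep.converged)
        positions.append(pos.copy())
        # adapt the continuation step to the observed solver effort
        if not fine:
            if rep.n_iter <= 20:
                dx = min(dx * 1.5, coarse_dx)
            elif rep.n_iter > 80:
                dx = max(dx * 0.5, ramp_dx)
        forces = rows["force"]
        if getattr(sys, "n_rings", 0) > 0:
            prof = flatness_profile(pos, sys)
            interior = (prof.s_hat >= 0.05) & (prof.s_hat <= 0.95)
            e_int = float(prof.e[interior].max())
            spikes, _ = flatness_spikes(prof, e_min=flatness_min)
        else:
            e_int = 0.0  # 1D chain has no cross-section
            spikes = []
        # interior ovalization building up signals the approach to the
        # kink: refine the trap step before the collapse
        if not fine and e_int > refine_frac * flatness_min:
            fine = True
        if kink_step is None and i >= 1 and forces[-2] > 0:
            if forces[-1] < forces[-2] * (1.0 - drop_frac) and len(spikes):
                kink_step = i
        if kink_step is not None:
            steps_after += 1
            if steps_after > extra_steps:
                break
        i += 1
    traj = _collect(rows, positions, sys, spec)
    traj.meta["kink_step"] = kink_step
    traj.meta["no_kink"] = kink_step is None
    return traj


def hysteresis_gap(traj: Trajectory, kink_strain: float | None = None):
    """Max |F_forward - F_backward| over the shared strain grid, split at
    ``kink_strain`` into pre-kink (less compressive) and post-kink parts.

    Returns (pre_gap, post_gap, grid); post_gap is nan when no kink strain
    is supplied or no grid point lies beyond it.
    """
    fwd = traj.direction == 1
    bwd = traj.direction == -1
    if not fwd.any() or not bwd.any():
        raise InsufficientDataError("trajectory must contain both sweep directions")
    sf = traj.strain[fwd]
    sb = traj.strain[bwd]
    lo = max(sf.min(), sb.min())
    hi = min(sf.max(), sb.max())
    grid = np.linspace(lo, hi, 101)
    of, ob = np.argsort(sf), np.argsort(sb)
    Ff = np.interp(grid, sf[of], traj.force[fwd][of])
    Fb = np.interp(grid, sb[ob], traj.force[bwd][ob])
    gap = np.abs(Ff - Fb)
    if kink_strain is None:
        return float(gap.max()), float("nan"), grid
    pre = grid > kink_strain
    post = ~pre
    pre_gap = float(gap[pre].max()) if pre.any() else float("nan")
    post_gap = float(gap[post].max()) if post.any() else float("nan")
    return pre_gap, post_gap, grid
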