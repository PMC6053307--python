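"""Derived quantities: strain, cross-section flatness, centerline
curvature, kink detection, the shear-agnostic modified force, critical
bending moments, critical curvature, and plateau onset.

The central observable is the cross-sectional flatness e = (R - a)/R,
where a is the semi-minor axis of the deformed ring; e = 0 is a circular
cross-section, e -> 1 a fully collapsed one.  Brazier ovalization makes e
grow with bending curvature until a critical bending moment MB, at which
the section collapses locally (a kink): a spike in the flatness and
curvature profiles together with a small drop in the buckling force.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import CH_LATERAL, CH_SHEAR

__all__ = [
    "strain",
    "CrossSectionProfile",
    "BucklingSummary",
    "flatness_profile",
    "curvature_profile",
    "flatness_spikes",
    "detect_kinks",
    "modified_force",
    "critical_moment_observed",
    "critical_moment_predicted",
    "critical_curvature",
    "plateau_onset",
    "summarize_buckling",
]

#: isotropic Brazier prefactor 2*sqrt(2)*pi/9
BRAZIER_FACTOR = 2.0 * math.sqrt(2.0) * math.pi / 9.0


def strain(db: float, L: float):
    """Dimensionless strain (db - L)/L; negative in compression."""
    if np.any(np.asarray(L) <= 0):
        raise ValueError("L must be positive")
    return (np.asarray(db) - L) / L


@dataclass
class CrossSectionProfile:
    """Per-ring flatness and centerline curvature along the filament."""

    s_hat: np.ndarray          # normalized arclength in [0, 1]
    e: np.ndarray              # flatness, in [0, 1]
    a: np.ndarray              # semi-minor axis, nm
    curvature: np.ndarray      # centerline curvature, rad/nm
    degenerate: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


@dataclass
class BucklingSummary:
    MB_observed: float           # pN·nm (nan if no kink)
    MB_predicted: float          # pN·nm
    critical_curvature: float    # rad/μm (nan if no kink)
    plateau_onset_strain: float  # dimensionless (nan if not found)
    kink_positions: np.ndarray   # s_hat of flatness spikes at first kink
    kink_step: int | None = None


def _centerline(positions, lattice):
    nf = lattice.Nr * lattice.Np
    return positions[:nf].reshape(lattice.Nr, lattice.Np, 3).mean(axis=1)


def flatness_profile(positions, lattice) -> CrossSectionProfile:
    """Flatness e = (R - a)/R per ring.

    Each ring is projected onto the plane normal to the local centerline
    tangent; the semi-minor axis a is estimated from the second moments of
    the projected points as the minor half-axis of the equal-area ellipse
    (a = sqrt(2·lambda_min), exact for points uniformly distributed in
    angle).  A collinear (collapsed) ring reports e = 1 with a degenerate
    flag.
    """
    Nr, Np = lattice.Nr, lattice.Np
    if Np < 3:
        raise ValueError("need >= 3 particles per ring")
    R = lattice.macro.R
    cent = _centerline(positions, lattice)
    rings = positions[: Nr * Np].reshape(Nr, Np, 3)
    tang = np.empty_like(cent)
    tang[1:-1] = cent[2:] - cent[:-2]
    tang[0] = cent[1] - cent[0]
    tang[-1] = cent[-1] - cent[-2]
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    e = np.empty(Nr)
    a = np.empty(Nr)
    degen = np.zeros(Nr, dtype=bool)
    for j in range(Nr):
        rel = rings[j] - cent[j]
        rel = rel - np.outer(rel @ tang[j], tang[j])
        cov = rel.T @ rel / Np
        lam = np.linalg.eigvalsh(cov)  # ascending; lam[0] ~ 0 (tangent dir)
        lam_min = max(lam[1], 0.0)
        a[j] = math.sqrt(2.0 * lam_min)
        if a[j] < 1e-6 * R:
            degen[j] = True
            e[j] = 1.0
        else:
            e[j] = min(max((R - a[j]) / R, 0.0), 1.0)

    seg = np.linalg.norm(np.diff(cent, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_hat = s / s[-1] if s[-1] > 0 else s
    return CrossSectionProfile(
        s_hat=s_hat, e=e, a=a, curvature=curvature_profile(positions, lattice), degenerate=degen
    )


def curvature_profile(positions, lattice) -> np.ndarray:
    """Discrete centerline curvature per ring (rad/nm): turning angle at
    each interior ring centroid divided by the mean adjacent segment
    length; zero at the ends and for a straight filament."""
    cent = _centerline(positions, lattice)
    if cent.shape[0] < 3:
        raise ValueError("need >= 3 rings")
    v1 = cent[1:-1] - cent[:-2]
    v2 = cent[2:] - cent[1:-1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("coincident ring centroids")
    c = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    kappa = np.zeros(cent.shape[0])
    kappa[1:-1] = np.arccos(c) / (0.5 * (n1 + n2))
    return kappa


def flatness_spikes(
    profile: CrossSectionProfile,
    e_min: float = 0.3,
    rel: float = 3.0,
    edge_margin: float = 0.05,
):
    """s_hat positions of local maxima of e exceeding
    max(e_min, rel × median e) — the 'spikes' that mark kinks.

    Rings within ``edge_margin`` of either end are excluded: kinks are
    interior events, while the single-particle bead tethers imprint a
    local, non-Brazier distortion on the few rings next to the
    attachment points."""
    e = profile.e
    thr = max(e_min, rel * float(np.median(e)))
    s = profile.s_hat
    idx = [
        j
        for j in range(1, len(e) - 1)
        if edge_margin <= s[j] <= 1.0 - edge_margin
        and e[j] >= e[j - 1]
        and e[j] >= e[j + 1]
        and e[j] > thr
    ]
    # collapse plateaus of equal neighboring maxima to a single spike
    out = []
    for j in idx:
        if not out or j - out[-1] > 1:
            out.append(j)
    return profile.s_hat[out], np.array(out, dtype=int)


def _force_drop_steps(traj, drop_frac: float):
    """Step indices where the force drops by > drop_frac while compression
    keeps increasing (sweep direction forward)."""
    out = []
    for i in range(1, traj.n_steps):
        if traj.direction[i] == 1 and traj.force[i - 1] > 0:
            if traj.force[i] < traj.force[i - 1] * (1.0 - drop_frac):
                out.append(i)
    return out


def detect_kinks(
    profiles,
    traj=None,
    drop_frac: float = 0.01,
    e_min: float = 0.3,
    rel: float = 3.0,
):
    """Find kinks: flatness spikes corroborated by a force-drop event.

    ``profiles`` is either a single :class:`CrossSectionProfile` (then the
    spike positions alone are returned, with step index None) or a list of
    per-step profiles aligned with ``traj``; then the first step showing
    both a force drop and a flatness spike is the first-kink step.

    Returns (first_kink_step or None, s_hat positions of the spikes at
    that step; empty array when no kink).
    """
    if isinstance(profiles, CrossSectionProfile):
        pos, _ = flatness_spikes(profiles, e_min, rel)
        return None, pos
    if traj is None:
        raise ValueError("need a trajectory when passing per-step profiles")
    for i in _force_drop_steps(traj, drop_frac):
        pos, _ = flatness_spikes(profiles[i], e_min, rel)
        if len(pos):
            return i, pos
    return None, np.array([])


def modified_force(traj) -> np.ndarray:
    """Shear-agnostic force: numerical derivative (centered differences on
    the bead-separation grid) of the total energy minus the shear energy
    (and minus the lateral stabilization penalty, a numerical device),
    signed like the measured force (positive in compression)."""
    if traj.n_steps < 2:
        raise ValueError("need at least two steps for a force derivative")
    e = traj.energies.sum(axis=1) - traj.energies[:, CH_SHEAR] - traj.energies[:, CH_LATERAL]
    return -np.gradient(e, traj.db)


def _nonshear_energy(traj):
    return traj.energies.sum(axis=1) - traj.energies[:, CH_SHEAR] - traj.energies[:, CH_LATERAL]


def _kink_index(traj, drop_frac):
    i = traj.meta.get("kink_step")
    if i is None:
        drops = _force_drop_steps(traj, drop_frac)
        i = drops[0] if drops else None
    return i


def critical_moment_observed(traj, at: str = "kink", drop_frac: float = 0.01) -> float:
    """MB from simulation: modified (shear-agnostic) force × max
    transverse centerline displacement.

    The displacement is the filament's deflection from its rest
    centerline (max perpendicular distance of ring centroids from the
    chord joining the end centroids), i.e. the lever arm the bow has
    acquired, not its offset from the bead-bead line.  With ``at='kink'``
    (primary) the moment is evaluated at the last state before the first
    kink's force drop — the onset of local collapse — using a backward
    difference for the modified force so that no post-collapse energies
    enter.  ``at='force_max'`` evaluates the
    centered-difference modified force at the measured-force maximum
    instead.  Returns nan when no kink was reached (not-applicable flag).
    """
    if at == "force_max":
        fmod = modified_force(traj)
        i = int(np.argmax(traj.force))
        return float(fmod[i] * traj.max_deflection[i])
    i = _kink_index(traj, drop_frac)
    if i is None:
        return float("nan")
    j = max(i - 1, 1)
    e = _nonshear_energy(traj)
    fmod = -(e[j] - e[j - 1]) / (traj.db[j] - traj.db[j - 1])
    return float(fmod * traj.max_deflection[j])


def critical_moment_predicted(macro, factor: float = 1.0) -> float:
    """Brazier critical moment for an orthotropic tube:
    MB = factor × h² R sqrt(Ea·Ec), in pN·nm.  With Ea = Ec = E and
    factor = 2√2π/9 this is the classical isotropic Brazier result."""
    return factor * macro.h**2 * macro.R * math.sqrt(macro.Ea * macro.Ec)


def critical_curvature(
    MB: float | None = None,
    B: float | None = None,
    traj=None,
    lattice=None,
    edge_margin: float = 0.05,
) -> float:
    """Critical centerline curvature for softening onset, in rad/μm.

    Analytic route (give MB in pN·nm and B in pN·nm²): MB/B.  Simulation
    route (give a kinked trajectory with stored positions and its
    lattice): the maximum discrete centerline curvature at the onset of
    the first kink — the last stored state before the force drop, where
    the centerline is still smooth (after the drop the curvature profile
    is dominated by the localized post-collapse spike).  Rings within
    ``edge_margin`` of either end are excluded: the single-particle bead
    tethers kink the centerline locally at the attachments.
    """
    if traj is not None and lattice is not None:
        i = _kink_index(traj, 0.01)
        if i is None:
            return float("nan")
        if not traj.positions:
            raise ValueError("trajectory has no stored positions")
        pos = traj.positions[max(i - 1, 0)]
        prof = flatness_profile(pos, lattice)
        interior = (prof.s_hat >= edge_margin) & (prof.s_hat <= 1.0 - edge_margin)
        return float(prof.curvature[interior].max() * 1e3)
    if MB is None or B is None:
        raise ValueError("need either (MB, B) or (traj, lattice)")
    return MB / B * 1e3


def plateau_onset(strain_arr, force=None, slope_frac: float = 0.1):
    """Compressive strain where the force-strain curve leaves the linear
    regime: first point at which the local slope dF/d|strain| falls below
    ``slope_frac`` of the initial linear slope.  Accepts a ForceStrainCurve
    (with .strain/.F_mean) or two arrays.  Returns nan when the curve never
    leaves the linear regime (not-found flag).
    """
    if force is None:
        force = strain_arr.F_mean
        strain_arr = strain_arr.strain
    strain_arr = np.asarray(strain_arr, dtype=float)
    force = np.asarray(force, dtype=float)
    comp = strain_arr <= 0
    s = -strain_arr[comp]
    F = force[comp]
    order = np.argsort(s)
    s, F = s[order], F[order]
    if len(s) < 4:
        raise ValueError("curve too short to locate a plateau onset")
    slope = np.gradient(F, s)
    n0 = max(3, len(s) // 4)
    init = float(np.median(slope[1:n0]))
    if init <= 0:
        return float("nan")
    below = slope < slope_frac * init
    for i in range(n0, len(s) - 1):
        # two consecutive sub-threshold points guard against noise dips
        if below[i] and below[i + 1]:
            return float(-s[i])
    if below[-1]:
        return float(-s[-1])
    return float("nan")


def summarize_buckling(traj, lattice, mb_factor: float = 1.0) -> BucklingSummary:
    """Bundle the buckling observables of a compression trajectory."""
    macro = lattice.macro
    kink_step = traj.meta.get("kink_step")
    kink_pos = np.array([])
    if kink_step is None and traj.positions:
        profiles = [flatness_profile(p, lattice) for p in traj.positions]
        kink_step, kink_pos = detect_kinks(profiles, traj)
    elif kink_step is not None and traj.positions:
        kink_pos, _ = flatness_spikes(flatness_profile(traj.positions[kink_step], lattice))
    mb_obs = critical_moment_observed(traj) if kink_step is not None else float("nan")
    crit = (
        critical_curvature(traj=traj, lattice=lattice)
        if kink_step is not None and traj.positions
        else float("nan")
    )
    try:
        onset = plateau_onset(traj.strain, traj.force)
    except ValueError:
        onset = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mb_pred = critical_moment_predicted(macro, mb_factor)
    return BucklingSummary(
        MB_observed=mb_obs,
        MB_predicted=mb_pred,
        critical_curvature=crit,
        plateau_onset_strain=onset,
        kink_positions=kink_pos,
        kink_step=kink_step,
    )
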