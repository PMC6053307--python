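"""Force-averaging preprocessing and model fitting.

The measurement chain of a two-trap buckling experiment produces raw
records of (trap separation, instantaneous force sample).  Preprocessing
follows the experimental procedure: project force samples onto the trap
axis, bin by trap separation, pool over runs, convert trap separation to
bead separation using the trap stiffnesses, locate the equilibrium length
from the force minimum, and express everything as a force-strain curve.
Fitting then matches simulated quasistatic curves — the 1D chain (single
parameter B) or the 3D shell (Ea, Ec, G) — to the measured curve by
weighted least squares.

Sign convention: measured force is positive in compression and negative
in tension, so ``beads_from_traps`` adds F/ko to the trap separation —
under compressive load the beads are pushed apart relative to their traps
(db > dt), under tension pulled together (db < dt).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.optimize

from . import filament1d, params as P, shell3d
from .quasistatic import ProtocolSpec, compression_schedule, run_protocol

__all__ = [
    "RawSamples",
    "ForceStrainCurve",
    "SimOptions1D",
    "SimOptions3D",
    "FitResult",
    "project_and_bin",
    "beads_from_traps",
    "equilibrium_length",
    "build_curve",
    "simulate_curve_1d",
    "simulate_curve_3d",
    "fit_1d",
    "fit_3d",
    "FitFailureError",
]

#: weighting floor (pN) to avoid zero-variance bins dominating the objective
STD_FLOOR = 0.02


class FitFailureError(RuntimeError):
    def __init__(self, msg, landscape=None):
        super().__init__(msg)
        self.landscape = landscape


@dataclass
class RawSamples:
    """Raw optical-trap records.

    ``data`` columns: ``dt_nm`` (trap separation), ``fx_pN`` (force sample
    along the trap axis), ``fy_pN`` (perpendicular component), ``run``
    (cycle id), ``direction`` (+1 compression sweep, -1 release), ``t_s``
    (timestamp).  ``ko_detection`` / ``ko_manipulation`` are the trap
    stiffnesses (pN/nm).
    """

    data: pd.DataFrame
    ko_detection: float
    ko_manipulation: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.data) == 0:
            raise ValueError("empty raw-sample table")
        missing = {"dt_nm", "fx_pN"} - set(self.data.columns)
        if missing:
            raise ValueError(f"raw-sample table missing columns {sorted(missing)}")


@dataclass
class ForceStrainCurve:
    """Binned force-strain curve: per bin the strain, mean force (pN,
    positive in compression), std and sample count; ``L`` is the effective
    filament length (equilibrium bead separation, nm)."""

    strain: np.ndarray
    F_mean: np.ndarray
    F_std: np.ndarray
    n: np.ndarray
    L: float
    db: np.ndarray | None = None
    direction: np.ndarray | None = None

    def __post_init__(self):
        order = np.argsort(self.strain)
        for name in ("strain", "F_mean", "F_std", "n", "db", "direction"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v)[order])
        if self.L <= 0:
            raise ValueError("L must be positive")

    def to_dataframe(self):
        d = {"strain": self.strain, "F_mean_pN": self.F_mean,
             "F_std_pN": self.F_std, "n": self.n}
        if self.db is not None:
            d["db_nm"] = self.db
        return pd.DataFrame(d)


def project_and_bin(raw: RawSamples) -> pd.DataFrame:
    """Mean/std/count of the trap-axis force component per trap-separation
    bin, pooled over time and runs.  Returns columns
    (dt_nm, F_mean_pN, F_std_pN, n)."""
    g = raw.data.groupby("dt_nm")["fx_pN"]
    out = g.agg(F_mean_pN="mean", F_std_pN=lambda x: x.std(ddof=0), n="count").reset_index()
    return out.sort_values("dt_nm", ignore_index=True)


def beads_from_traps(dt, F, ko_detection: float, ko_manipulation: float):
    """Bead separation from trap separation, measured force (positive in
    compression) and trap stiffnesses: db = dt + F·(1/ko_d + 1/ko_m)."""
    if ko_detection <= 0 or ko_manipulation <= 0:
        raise ValueError("trap stiffnesses must be positive")
    return np.asarray(dt) + np.asarray(F) * (1.0 / ko_detection + 1.0 / ko_manipulation)


def equilibrium_length(db, F):
    """Equilibrium bead separation: location of the minimum of |F| with
    parabolic refinement over the three adjacent bins.

    Returns (L, at_boundary): ``at_boundary`` flags a minimum at the sweep
    edge, i.e. the sweep did not cross the equilibrium point.
    """
    db = np.asarray(db, dtype=float)
    a = np.abs(np.asarray(F, dtype=float))
    order = np.argsort(db)
    db, a = db[order], a[order]
    i = int(np.argmin(a))
    if i == 0 or i == len(db) - 1:
        return float(db[i]), True
    x0, x1, x2 = db[i - 1 : i + 2]
    y0, y1, y2 = a[i - 1 : i + 2]
    denom = (y0 - 2 * y1 + y2)
    if abs(denom) < 1e-30:
        return float(db[i]), False
    # vertex of the parabola through the three points (uniform-ish grid)
    L = x1 + 0.5 * (x0 - x2) * (y0 - y2) / (2 * denom) * (-1.0)
    lo, hi = min(x0, x2), max(x0, x2)
    return float(np.clip(L, lo, hi)), False


def build_curve(raw: RawSamples, L: float | None = None) -> ForceStrainCurve:
    """Full preprocessing pipeline: project + bin, trap->bead separation,
    equilibrium length from the force minimum (unless given), strain."""
    binned = project_and_bin(raw)
    db = beads_from_traps(binned["dt_nm"].to_numpy(), binned["F_mean_pN"].to_numpy(),
                          raw.ko_detection, raw.ko_manipulation)
    if L is None:
        L, at_boundary = equilibrium_length(db, binned["F_mean_pN"].to_numpy())
        if at_boundary:
            warnings.warn("force minimum at sweep boundary: equilibrium length "
                          "extrapolated from the edge bin", stacklevel=2)
    return ForceStrainCurve(
        strain=(db - L) / L,
        F_mean=binned["F_mean_pN"].to_numpy(),
        F_std=binned["F_std_pN"].to_numpy(),
        n=binned["n"].to_numpy(),
        L=float(L),
        db=db,
    )


# ---------------------------------------------------------------------------
# forward simulations onto a strain grid

@dataclass(frozen=True)
class SimOptions1D:
    N: int = 48
    b: float = 500.0
    dx_frac: float = 0.01      # protocol step as a fraction of L
    tol: float = 1e-3


@dataclass(frozen=True)
class SimOptions3D:
    d: float = 16.0
    b: float = 500.0
    R: float = 12.0
    h: float = 2.7
    h0: float = 1.6
    Np: int = 10
    dx_frac: float = 0.01
    tol: float = 1e-3
    calibrate: bool = True


def _run_sweeps(system, L, min_strain, max_strain, dx, tol):
    from .quasistatic import run_compression_to_kink

    parts = []
    if min_strain < 0:
        # effort-adaptive compression, stopping at the first kink (a
        # collapsed lattice no longer belongs to the smooth branch the
        # measured curve samples) and truncating any non-converged tail
        t = run_compression_to_kink(
            system, coarse_dx=dx, fine_dx=dx,
            max_strain=abs(min_strain) + 2 * dx / L, tol=tol,
            extra_steps=0, ramp_dx=min(4.0, dx))
        good = np.nonzero(~t.converged)[0]
        stop = good[0] if len(good) else t.n_steps
        if t.meta.get("kink_step") is not None:
            stop = min(stop, t.meta["kink_step"])
        parts.append((t.strain[:stop], t.force[:stop]))
    if max_strain > 0:
        hi = L * (1.0 + max_strain) + 2 * dx
        sched = np.arange(L, hi, dx)
        t = run_protocol(system, ProtocolSpec(schedule=sched, dx=dx, tol=tol,
                                              store_positions=False, on_failure="flag"))
        parts.append((t.strain, t.force))
    s = np.concatenate([p[0] for p in parts])
    f = np.concatenate([p[1] for p in parts])
    order = np.argsort(s)
    s, f = s[order], f[order]
    keep = np.concatenate([[True], np.diff(s) > 1e-12])
    return s[keep], f[keep]


def simulate_curve_1d(B, L, strain_grid, opts: SimOptions1D = SimOptions1D()):
    """Simulated bead-loaded chain force interpolated (monotone cubic)
    onto ``strain_grid``."""
    strain_grid = np.asarray(strain_grid)
    ch = filament1d.build_chain(B, L, opts.N, opts.b)
    dx = max(opts.dx_frac * L, 1.0)
    s, f = _run_sweeps(ch, ch.length, float(strain_grid.min()), float(strain_grid.max()),
                       dx, opts.tol)
    return _interp_with_nan(s, f, strain_grid)


def simulate_curve_3d(Ea, Ec, G, L, strain_grid, opts: SimOptions3D = SimOptions3D(),
                      factors=None):
    """Simulated 3D shell force interpolated onto ``strain_grid``.
    ``factors`` may carry pre-computed calibration factors to avoid
    re-calibrating at every objective evaluation."""
    strain_grid = np.asarray(strain_grid)
    macro = P.MacroElastic(Ea=Ea, Ec=Ec, G=G, L=L, h=opts.h, h0=opts.h0,
                           R=opts.R, d=opts.d, Np=opts.Np, b=opts.b)
    if factors is None and opts.calibrate:
        factors = P.calibrate_factors(macro)
    lat = shell3d.build_lattice(macro, P.macro_to_micro(macro, factors))
    dx = max(opts.dx_frac * L, 1.0)
    s, f = _run_sweeps(lat, lat.length, float(strain_grid.min()), float(strain_grid.max()),
                       dx, opts.tol)
    return _interp_with_nan(s, f, strain_grid)


@dataclass
class FitResult:
    params: dict
    sigma: dict
    residual: float
    n_eval: int
    F_fit: np.ndarray
    strain: np.ndarray
    warnings: list = field(default_factory=list)


def _interp_with_nan(s, f, grid):
    """Monotone-cubic interpolation; grid points outside the simulated
    strain range (e.g. beyond a candidate's kink) come back as nan."""
    out = scipy.interpolate.PchipInterpolator(s, f)(grid)
    out[(grid < s.min() - 1e-12) | (grid > s.max() + 1e-12)] = np.nan
    return out


def _chi2(curve: ForceStrainCurve, F_sim):
    w = np.maximum(curve.F_std, STD_FLOOR)
    r = (F_sim - curve.F_mean) / w
    bad = ~np.isfinite(r)
    # bins the candidate cannot reach (it collapsed first) are penalized
    # as if it predicted zero force there, plus a fixed surcharge
    r[bad] = np.abs(curve.F_mean[bad]) / w[bad] + 10.0
    return float(np.sum(r**2))


def fit_1d(
    curve: ForceStrainCurve,
    opts: SimOptions1D = SimOptions1D(),
    B_range=(0.5e6, 50e6),
    n_grid: int = 9,
    cache: dict | None = None,
) -> FitResult:
    """Estimate the flexural rigidity B (pN·nm²) by matching the simulated
    bead-loaded chain to the measured curve: coarse log-grid scan followed
    by golden-section refinement; 1-sigma interval from the local
    curvature of the chi² profile."""
    if np.sum(curve.strain < 0) < 5:
        raise FitFailureError("need >= 5 compressive bins to fit B")
    evals = {} if cache is None else cache
    grid_hist = []

    def objective(logB):
        key = round(float(logB), 10)
        if key not in evals:
            F = simulate_curve_1d(float(np.exp(logB)), curve.L, curve.strain, opts)
            evals[key] = (_chi2(curve, F), F)
        grid_hist.append((key, evals[key][0]))
        return evals[key][0]

    lo, hi = np.log(B_range[0]), np.log(B_range[1])
    grid = np.linspace(lo, hi, n_grid)
    chi = [objective(x) for x in grid]
    i = int(np.argmin(chi))
    if i == 0 or i == n_grid - 1:
        raise FitFailureError(
            "chi² minimum at the edge of the B range: cannot bracket",
            landscape=list(zip(np.exp(grid), chi)),
        )
    res = scipy.optimize.minimize_scalar(
        objective, bracket=None, bounds=(grid[i - 1], grid[i + 1]),
        method="bounded", options={"xatol": 1e-3},
    )
    logB = float(res.x)
    chi_min = objective(logB)
    # curvature of chi2 in B around the optimum -> 1 sigma (delta chi2 = 1)
    h = 0.05
    c_p, c_m = objective(logB + h), objective(logB - h)
    curv = (c_p - 2 * chi_min + c_m) / h**2
    B = float(np.exp(logB))
    sigma_logB = float(np.sqrt(2.0 / curv)) if curv > 0 else float("inf")
    F_fit = evals[round(logB, 10)][1]
    return FitResult(
        params={"B": B},
        sigma={"B": B * sigma_logB},
        residual=chi_min,
        n_eval=len(evals),
        F_fit=F_fit,
        strain=curve.strain.copy(),
    )


#: default fit bounds, pN/nm²
BOUNDS_3D = {"Ea": (0.1e3, 5e3), "Ec": (0.5, 100.0), "G": (0.1e3, 20e3)}


def fit_3d(
    curve: ForceStrainCurve,
    opts: SimOptions3D = SimOptions3D(),
    bounds: dict | None = None,
    x0: dict | None = None,
    maxfev: int = 60,
    cache: dict | None = None,
) -> FitResult:
    """Estimate (Ea, Ec, G) by derivative-free simplex over log-parameters
    within bounds, started from the best point of a coarse grid (or a
    supplied ``x0``).  Simulated curves are cached by parameter point.

    Emits an identifiability warning when the curve never leaves the
    linear regime: the plateau position is what pins down Ec.
    """
    from .observables import plateau_onset

    bounds = {**BOUNDS_3D, **(bounds or {})}
    warns = []
    try:
        onset = plateau_onset(curve.strain, curve.F_mean)
    except ValueError:
        onset = float("nan")
    if np.isnan(onset):
        msg = ("curve never leaves the linear regime: Ec is weakly "
               "identifiable (the plateau position constrains it)")
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)

    evals = {} if cache is None else cache
    names = ("Ea", "Ec", "G")
    lb = np.log([bounds[k][0] for k in names])
    ub = np.log([bounds[k][1] for k in names])
    # calibration factors are geometry-only at fixed d; compute once
    macro0 = P.MacroElastic(Ea=1e3, Ec=10.0, G=1e3, L=curve.L, h=opts.h, h0=opts.h0,
                            R=opts.R, d=opts.d, Np=opts.Np, b=opts.b)
    factors = P.calibrate_factors(macro0) if opts.calibrate else P.ChannelFactors()

    def objective(x):
        x = np.clip(x, lb, ub)
        key = tuple(np.round(x, 6))
        if key not in evals:
            Ea, Ec, G = np.exp(x)
            F = simulate_curve_3d(Ea, Ec, G, curve.L, curve.strain, opts, factors=factors)
            evals[key] = (_chi2(curve, F), F)
        return evals[key][0]

    if x0 is not None:
        start = np.log([x0[k] for k in names])
    else:
        axes = [np.linspace(l + 0.15 * (u - l), u - 0.15 * (u - l), 2)
                for l, u in zip(lb, ub)]
        pts = list(itertools.product(*axes))
        start = np.array(pts[int(np.argmin([objective(np.array(p)) for p in pts]))])

    res = scipy.optimize.minimize(
        objective, start, method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 5e-3, "fatol": 1e-3, "adaptive": True},
    )
    xopt = np.clip(res.x, lb, ub)
    chi_min = objective(xopt)
    pars = dict(zip(names, np.exp(xopt)))
    # per-parameter curvature of chi2 in log space -> 1 sigma intervals
    sig = {}
    for a, k in enumerate(names):
        h = 0.08
        xp, xm = xopt.copy(), xopt.copy()
        xp[a] += h
        xm[a] -= h
        curv = (objective(xp) - 2 * chi_min + objective(xm)) / h**2
        if curv <= 1e-9:
            msg = f"objective locally flat along {k}: weakly identifiable"
            warns.append(msg)
            sig[k] = float("inf")
        else:
            sig[k] = pars[k] * float(np.sqrt(2.0 / curv))
    F_fit = evals[tuple(np.round(xopt, 6))][1]
    return FitResult(
        params=pars,
        sigma=sig,
        residual=chi_min,
        n_eval=len(evals),
        F_fit=F_fit,
        strain=curve.strain.copy(),
        warnings=warns,
    )
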