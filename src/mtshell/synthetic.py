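"""Synthetic optical-trap experiments.

No public raw data exists for this kind of two-trap buckling measurement,
so the package carries a generator that emulates the measurement chain:
the manipulation trap steps by a few nm every 0.5-1 s; the detection-bead
position is read at 100 kHz and averaged in bins of 1000 samples to an
effective 100 Hz, giving 50-100 force samples per dwell; force = trap
stiffness × bead displacement; only the component parallel to the trap
axis is physical signal, the perpendicular component averages to zero.
Only the 100 Hz averaged samples are synthesized (the pipeline never
consumes the raw 100 kHz stream); their noise is white Gaussian, a
deliberate simplification of the colored QPD spectrum of a real
instrument.

Ground truth comes from the package's own forward models (1D chain or 3D
shell) run quasistatically; bead separation follows the trap separation
self-consistently through the trap-stiffness relation, so the full
preprocessing pipeline (projection, binning, trap-to-bead conversion,
equilibrium-length location) is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.optimize

from . import filament1d, params as P, shell3d
from .fitting import RawSamples
from .quasistatic import ProtocolSpec, compression_schedule, run_protocol

__all__ = ["ExperimentSpec", "generate_experiment", "package_fixture", "FIXTURES"]


@dataclass(frozen=True)
class ExperimentSpec:
    """Parameters of a synthetic two-trap experiment.

    ``model`` is ``"1d"`` (uses B) or ``"3d"`` (uses Ea/Ec/G).  Defaults
    follow the experimental protocol: 5 nm trap steps (allowed 2-20 nm),
    75 dwell samples per step at the effective 100 Hz rate (0.75 s dwell),
    trap stiffnesses of 0.05 pN/nm typical of ~1 μm silica beads in a
    moderate-power trap, and 0.1 pN white force noise per 100 Hz sample.
    The seed is mandatory: every record is reproducible.
    """

    seed: int
    model: str = "1d"
    B: float = 4.0e6            # pN·nm² (1D)
    Ea: float = 0.9e3           # pN/nm² (3D)
    Ec: float = 4.0
    G: float = 4.0e3
    L: float = 4100.0           # nm
    b: float = 500.0            # nm
    d: float = 16.0             # 3D axial coarse-graining, nm
    N: int = 48                 # 1D mass count
    ko_detection: float = 0.05  # pN/nm
    ko_manipulation: float = 0.05
    step_nm: float = 5.0
    dwell_samples: int = 75
    sigma_pN: float = 0.1
    n_cycles: int = 2
    max_strain: float = 0.4
    extension_strain: float = 0.05
    tol: float = 1e-3

    def __post_init__(self):
        if not (2.0 <= self.step_nm <= 20.0):
            raise ValueError("trap step outside the experimental 2-20 nm range")
        if self.model not in ("1d", "3d"):
            raise ValueError("model must be '1d' or '3d'")
        if self.dwell_samples < 1 or self.sigma_pN < 0 or self.n_cycles < 1:
            raise ValueError("invalid dwell/noise/cycle settings")


def _truth_interpolant(spec: ExperimentSpec):
    """Quasistatic ground-truth force as a function of bead separation."""
    if spec.model == "1d":
        sysm = filament1d.build_chain(spec.B, spec.L, spec.N, spec.b)
        truth = {"model": "1d", "B": spec.B, "L": spec.L}
    else:
        macro = P.MacroElastic(Ea=spec.Ea, Ec=spec.Ec, G=spec.G, L=spec.L,
                               d=spec.d, b=spec.b)
        sysm = shell3d.build_microtubule(macro)
        truth = {"model": "3d", "Ea": spec.Ea, "Ec": spec.Ec, "G": spec.G, "L": spec.L}
    L = sysm.length
    dx = max(spec.step_nm, 0.005 * L)
    sched = compression_schedule(L, spec.max_strain, dx,
                                 extension_strain=spec.extension_strain)
    traj = run_protocol(sysm, ProtocolSpec(schedule=sched, dx=dx, tol=spec.tol,
                                           store_positions=False, on_failure="flag"))
    order = np.argsort(traj.db)
    db, f = traj.db[order], traj.force[order]
    keep = np.concatenate([[True], np.diff(db) > 1e-9])
    truth["L_eff"] = L
    return scipy.interpolate.PchipInterpolator(db[keep], f[keep]), L, truth


def generate_experiment(spec: ExperimentSpec) -> RawSamples:
    """Synthesize raw records for ``spec.n_cycles`` forward+backward
    sweeps.  For each scheduled trap separation dt the quasistatic force F
    and bead separation db satisfy db = dt + F·(1/ko_d + 1/ko_m) and
    F = F_truth(db) simultaneously; per-sample noise is Gaussian with a
    perpendicular component of the same amplitude (zero mean) so the
    projection step is exercised."""
    rng = np.random.default_rng(spec.seed)
    F_of_db, L, truth = _truth_interpolant(spec)
    c = 1.0 / spec.ko_detection + 1.0 / spec.ko_manipulation

    # trap schedule: start at zero force (dt = db = L), sweep inwards until
    # db reaches the target strain, then back; extension likewise
    db_lo = L * (1.0 - spec.max_strain)
    db_hi = L * (1.0 + spec.extension_strain)
    dt_lo = db_lo - c * float(F_of_db(db_lo))
    dt_hi = db_hi - c * float(F_of_db(db_hi))
    fwd = np.arange(L, dt_lo, -spec.step_nm)
    one_cycle = np.concatenate([fwd, fwd[-2::-1]])
    dirs_cycle = np.concatenate([np.ones(len(fwd), dtype=int),
                                 -np.ones(len(fwd) - 1, dtype=int)])
    if spec.extension_strain > 0:
        ext = np.arange(L + spec.step_nm, dt_hi, spec.step_nm)
        one_cycle = np.concatenate([one_cycle, ext, ext[-2::-1]])
        dirs_cycle = np.concatenate([dirs_cycle, -np.ones(len(ext), dtype=int),
                                     np.ones(len(ext) - 1, dtype=int)])

    rows = []
    t = 0.0
    dwell_t = spec.dwell_samples / 100.0
    for run in range(spec.n_cycles):
        for dt, dirn in zip(one_cycle, dirs_cycle):
            g = lambda db: db - dt - c * float(F_of_db(db))
            lo, hi = min(db_lo, dt) - 1.0, db_hi + abs(c) * 10.0 + 1.0
            try:
                db = scipy.optimize.brentq(g, lo, hi, xtol=1e-9)
            except ValueError:
                db = dt + c * float(F_of_db(np.clip(dt, db_lo, db_hi)))
            F = float(F_of_db(db))
            fx = F + rng.normal(0.0, spec.sigma_pN, spec.dwell_samples)
            fy = rng.normal(0.0, spec.sigma_pN, spec.dwell_samples)
            ts = t + np.arange(spec.dwell_samples) / 100.0
            rows.append(pd.DataFrame({
                "dt_nm": dt, "fx_pN": fx, "fy_pN": fy,
                "run": run, "direction": dirn, "t_s": ts,
            }))
            t += dwell_t
    data = pd.concat(rows, ignore_index=True)
    meta = {"seed": spec.seed, "truth": truth, "sigma_pN": spec.sigma_pN,
            "step_nm": spec.step_nm, "dwell_samples": spec.dwell_samples,
            "n_cycles": spec.n_cycles, "bead_radius_nm": spec.b}
    return RawSamples(data=data, ko_detection=spec.ko_detection,
                      ko_manipulation=spec.ko_manipulation, meta=meta)


#: deterministic bundled datasets, regenerable from their recorded seeds
FIXTURES = {
    # flagellum-like: straight bacterial filament, B = 4 pN·μm², L = 4.1 μm
    "flagellum_L4.1": ExperimentSpec(seed=20180601, model="1d", B=4.0e6, L=4100.0,
                                     N=48, max_strain=0.5, extension_strain=0.05),
    # microtubule-like: orthotropic shell at the fitted moduli of an
    # 8.3 μm filament (coarse axial spacing keeps generation tractable)
    "microtubule_L8.3": ExperimentSpec(seed=20180602, model="3d", Ea=0.9e3, Ec=4.0,
                                       G=4.0e3, L=8300.0, d=32.0, max_strain=0.15,
                                       extension_strain=0.02),
}


def package_fixture(name: str, **overrides) -> tuple[RawSamples, dict]:
    """Regenerate a bundled deterministic dataset by name.

    Returns (raw samples, manifest).  The manifest lists every true model
    parameter and the generator settings; the data regenerate
    byte-identically from the recorded seed.  ``overrides`` replace
    generator fields (e.g. a shorter L for quick tests) and are recorded
    in the manifest.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    spec = replace(FIXTURES[name], **overrides) if overrides else FIXTURES[name]
    raw = generate_experiment(spec)
    manifest = {"name": name, "overrides": overrides, **raw.meta}
    return raw, manifest
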