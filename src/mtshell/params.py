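"""Units, geometry, and the micro <-> macro elastic parameter map.

Internal unit system: lengths in nm, forces in pN, energies in pN·nm,
moduli in pN/nm² (1 GPa = 1000 pN/nm², 1 MPa = 1 pN/nm²).  This keeps the
microscopic spring constants O(1e0–1e4) and per-interaction energies near
unity for the deformations of interest.

The macroscopic description of a filament is an orthotropic cylindrical
shell: axial Young's modulus Ea, circumferential Young's modulus Ec, shear
modulus G, an equivalent wall thickness h (for stretching) and an effective
thickness h0 (for wall bending, dominated by the soft inter-protofilament
bridges).  The microscopic description is the set of spring/angle constants
of the discrete lattice.  The thin-shell map between the two carries
O(1) numerical prefactors that are not exact for a coarse 10-particle ring,
so each channel carries a dimensionless correction factor obtained by
calibration against canonical homogeneous deformations
(:func:`calibrate_factors`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GPA",
    "MPA",
    "UM",
    "PN_UM2",
    "MacroElastic",
    "MicroSprings",
    "ChannelFactors",
    "macro_to_micro",
    "micro_to_macro",
    "calibrate_factors",
    "InvalidParameterError",
]

#: pN/nm² per GPa
GPA = 1e3
#: pN/nm² per MPa
MPA = 1.0
#: nm per μm
UM = 1e3
#: pN·nm² per pN·μm²
PN_UM2 = 1e6


class InvalidParameterError(ValueError):
    """A modulus, length, or stiffness violates its positivity constraint."""


@dataclass(frozen=True)
class ChannelFactors:
    """Dimensionless per-channel corrections to the thin-shell formulas."""

    axial_stretch: float = 1.0
    axial_bend: float = 1.0
    circ_stretch: float = 1.0
    circ_bend: float = 1.0
    shear: float = 1.0

    def __post_init__(self):
        for name in ("axial_stretch", "axial_bend", "circ_stretch", "circ_bend", "shear"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"correction factor {name} must be positive")


@dataclass(frozen=True)
class MacroElastic:
    """Macroscopic description of a filament as an orthotropic shell.

    Parameters
    ----------
    Ea, Ec, G
        Axial / circumferential Young's moduli and shear modulus, pN/nm².
    L
        Filament length between the bead attachment points, nm.
    h, h0
        Equivalent (stretching) and effective (bending) wall thickness, nm.
    R
        Undeformed cross-section radius, nm.
    d
        Axial coarse-graining length (dimer spacing for real microtubules), nm.
    Np
        Particles per ring; the circumferential spacing p = 2R sin(pi/Np)
        is always derived from R and Np.
    b
        Optical bead radius, nm.
    nu_a, nu_c
        Poisson ratios; recorded for completeness but set to zero in all
        formulas (their contribution is neglected throughout).
    """

    Ea: float
    Ec: float
    G: float
    L: float
    h: float = 2.7
    h0: float = 1.6
    R: float = 12.0
    d: float = 8.0
    Np: int = 10
    b: float = 500.0
    nu_a: float = 0.0
    nu_c: float = 0.0

    def __post_init__(self):
        for name in ("Ea", "Ec", "G", "L", "h", "h0", "R", "d", "b"):
            v = getattr(self, name)
            if not (v >= 0) or (name not in ("Ea", "Ec", "G") and v <= 0):
                raise InvalidParameterError(f"{name} must be positive (got {v!r})")
        if self.Np < 3:
            raise InvalidParameterError("Np must be >= 3")

    @property
    def p(self) -> float:
        """Circumferential particle spacing 2R sin(pi/Np), nm."""
        return 2.0 * self.R * math.sin(math.pi / self.Np)

    @property
    def bending_rigidity(self) -> float:
        """Thin-shell beam bending rigidity pi·Ea·h·R³, pN·nm²."""
        return math.pi * self.Ea * self.h * self.R**3


@dataclass(frozen=True)
class MicroSprings:
    """Microscopic spring constants of the discrete shell lattice.

    Stretch constants in pN/nm, angle constants in pN·nm.  ``kb`` and
    ``kappa_b`` are the bead tether/normal-angle stiffnesses; they are
    numerical constraints (made stiff enough that the tether strain is
    negligible), not material parameters.
    """

    ka: float
    kappa_a: float
    kc: float
    kappa_c: float
    kappa_s: float
    kb: float
    kappa_b: float
    factors: ChannelFactors = field(default_factory=ChannelFactors)

    def __post_init__(self):
        for name in ("ka", "kappa_a", "kc", "kappa_c", "kappa_s", "kb", "kappa_b"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


#: ratio of bead-constraint stiffness to the stiffest physical constant
STIFF_SCALE = 1e3


def macro_to_micro(
    macro: MacroElastic,
    factors: ChannelFactors | None = None,
    stiff_scale: float = STIFF_SCALE,
) -> MicroSprings:
    """Map macroscopic shell moduli to lattice spring constants.

    The base thin-shell relations (Poisson terms neglected) are::

        ka      = Ea h p / d          kc      = Ec h d / p
        kappa_a = Ea h0³ p / (6 d)    kappa_c = Ec h0³ d / (6 p)
        kappa_s = 2 G h p d

    each multiplied by its channel correction factor.  The shear prefactor
    is read literally as 2·G·h·p·d; since the calibration factor multiplies
    it, the choice of prefactor convention is immaterial to calibrated
    models.  Bead constraint constants are set to ``stiff_scale`` times the
    largest physical constant of their kind.
    """
    f = factors or ChannelFactors()
    p, d, h, h03 = macro.p, macro.d, macro.h, macro.h0**3
    ka = f.axial_stretch * macro.Ea * h * p / d
    kappa_a = f.axial_bend * macro.Ea * h03 * p / (6.0 * d)
    kc = f.circ_stretch * macro.Ec * h * d / p
    kappa_c = f.circ_bend * macro.Ec * h03 * d / (6.0 * p)
    kappa_s = f.shear * 2.0 * macro.G * h * p * d
    kb = stiff_scale * max(ka, kc, 1e-9)
    kappa_b = stiff_scale * max(kappa_a, kappa_c, kappa_s, 1e-9)
    return MicroSprings(ka, kappa_a, kc, kappa_c, kappa_s, kb, kappa_b, f)


def micro_to_macro(micro: MicroSprings, geometry: MacroElastic) -> MacroElastic:
    """Invert :func:`macro_to_micro` (moduli from spring constants).

    ``geometry`` supplies h, h0, R, d, Np, L, b; its moduli are ignored.
    Raises :class:`InvalidParameterError` if every constant of a channel
    pair is zero (modulus undefined).
    """
    f = micro.factors
    p, d, h = geometry.p, geometry.d, geometry.h
    if micro.ka == 0 and micro.kc == 0 and micro.kappa_s == 0:
        raise InvalidParameterError("all spring constants zero: moduli undefined")
    Ea = micro.ka * d / (f.axial_stretch * h * p)
    Ec = micro.kc * p / (f.circ_stretch * h * d)
    G = micro.kappa_s / (f.shear * 2.0 * h * p * d)
    return replace(geometry, Ea=Ea, Ec=Ec, G=G)


def _continuum_energies(macro: MacroElastic, Nr: int, amp: float) -> dict[str, float]:
    """Continuum orthotropic-shell energies of the canonical deformations.

    Membrane energy density Eh/2·strain², wall bending density
    E h0³/12 · (curvature change)², shear density Gh/2·gamma²; Poisson
    couplings neglected.  ``amp`` is the dimensionless amplitude used for
    every deformation.  Each channel is compared over the axial extent its
    discrete interactions actually tile — (Nr-1)·d for the axial springs
    and shear quadrants, Nr·d for the per-ring circumferential terms,
    (Nr-2)·d for interior axial-bend triplets — which makes the factors
    intensive (independent of lattice length).
    """
    circ = 2.0 * math.pi * macro.R
    d = macro.d
    D_a = macro.Ea * macro.h0**3 / 12.0
    D_c = macro.Ec * macro.h0**3 / 12.0
    c = amp / macro.R  # axial curvature used for the arc deformation
    return {
        # uniform axial strain amp
        "axial_stretch": 0.5 * macro.Ea * macro.h * amp**2 * circ * (Nr - 1) * d,
        # uniform inflation R -> R(1+amp): hoop strain amp
        "circ_stretch": 0.5 * macro.Ec * macro.h * amp**2 * circ * Nr * d,
        # centerline arc of curvature c: every axial fiber bends by c
        "axial_bend": 0.5 * D_a * c**2 * circ * (Nr - 2) * d,
        # inextensional ovalization u_r = amp·R cos2θ: Δκ = 3 amp cos2θ / R
        "circ_bend": 0.5 * D_c * (9.0 * math.pi * amp**2 / macro.R) * Nr * d,
        # uniform twist with engineering shear angle amp
        "shear": 0.5 * macro.G * macro.h * amp**2 * circ * (Nr - 1) * d,
    }


def calibrate_factors(
    macro: MacroElastic,
    n_rings: int = 12,
    amp: float = 1e-3,
) -> ChannelFactors:
    """Determine per-channel correction factors by energy matching.

    For each channel a canonical homogeneous deformation is imposed on a
    short test lattice built with unit factors: uniform axial strain,
    uniform inflation, a circular-arc centerline, the inextensional n=2
    ovalization mode, and a uniform twist.  The factor for the channel is
    the ratio of the continuum orthotropic-shell energy of that deformation
    to the discrete channel energy.  Factors are independent of the moduli
    magnitudes and, beyond a minimal lattice size, of the lattice length.
    """
    from . import shell3d  # local import: shell3d depends on params

    if n_rings < 4:
        raise InvalidParameterError("calibration lattice needs >= 4 rings")
    test_macro = replace(macro, L=(n_rings - 1) * macro.d)
    micro1 = macro_to_micro(test_macro, ChannelFactors())
    lat = shell3d.build_lattice(test_macro, micro1, beads=False)
    cont = _continuum_energies(test_macro, lat.Nr, amp)

    deformed = {
        "axial_stretch": shell3d.deform_axial_strain(lat, amp),
        "circ_stretch": shell3d.deform_inflation(lat, amp),
        "axial_bend": shell3d.deform_arc(lat, amp / macro.R),
        "circ_bend": shell3d.deform_ovalization(lat, amp),
        "shear": shell3d.deform_twist(lat, amp),
    }
    out = {}
    for ch, pos in deformed.items():
        e = shell3d.shell_energy(lat, pos)[ch]
        if e <= 0:
            raise InvalidParameterError(f"zero discrete energy in channel {ch}: cannot calibrate")
        out[ch] = cont[ch] / e
    return ChannelFactors(**out)
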