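"""Tissue electrical properties of a myocardial slab with parallel fibers.

The myocardium is modelled as a bidomain continuum whose intra- and
extracellular conductivity tensors are transversely isotropic about the fiber
direction.  Fibers lie in the XY plane at a constant angle ``psi`` (degrees)
to the propagation direction X; the transmural direction is Z.  This module
builds everything the analytic electrogram solution needs from the six
conductivities and the fiber angle:

* rotated in-plane tensor components,
* lumped directional conductivities ``g_M`` (in-plane, direction of
  propagation) and ``g_zz`` (transmural),
* the anisotropy ratio ``eta = sqrt(g_M / g_zz)`` used to rescale the
  transmural coordinate,
* the homogenized conductivity ``g_tilde = (g_M + eta * g_B) / 2``,
* reflection/transmission factors of the mirror-image construction at the
  blood and torso interfaces,
* the monodomain conduction-velocity scaling ``v(psi)``.

Units package-wide: mm, ms, mV, S/m.  Conductivities enter the potentials
only through dimensionless ratios, so no unit conversion is needed; wave
speeds are accepted in m/s at the interfaces, which is numerically identical
to mm/ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "ConductivitySet",
    "SlabModel",
    "MirrorCoefficients",
    "MembraneStep",
    "MonodomainConstants",
    "rotate_conductivity",
    "lumped_properties",
    "mirror_coefficients",
    "rescale_z",
    "conduction_velocity",
    "DEFAULT_CONDUCTIVITIES",
    "DEFAULT_MEMBRANE",
    "DEFAULT_V_PARALLEL",
]


@dataclass(frozen=True)
class ConductivitySet:
    """Six conductivities of the three-layer volume conductor (S/m).

    ``g_i_*`` / ``g_e_*`` are the intra-/extracellular myocardial
    conductivities along (``l``) and across (``t``) the fibers; ``g_B`` and
    ``g_T`` are the isotropic blood-pool and torso conductivities.
    """

    g_i_l: float
    g_i_t: float
    g_e_l: float
    g_e_t: float
    g_B: float
    g_T: float

    def __post_init__(self) -> None:
        for name in ("g_i_l", "g_i_t", "g_e_l", "g_e_t", "g_B", "g_T"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"conductivity {name}={v!r} must be finite and > 0"
                )
        # Only positivity is mathematically required; longitudinal values
        # below transverse ones are physiologically unusual, so warn only.
        if self.g_i_l < self.g_i_t or self.g_e_l < self.g_e_t:
            warnings.warn(
                "longitudinal conductivity below transverse; proceeding",
                stacklevel=2,
            )


#: Bidomain conductivities used throughout as the reference parameter set,
#: with a blood/torso bath of 0.7 S/m.
DEFAULT_CONDUCTIVITIES = ConductivitySet(
    g_i_l=0.1527, g_i_t=0.0312, g_e_l=0.5485, g_e_t=0.3361, g_B=0.7, g_T=0.7
)


@dataclass(frozen=True)
class MembraneStep:
    """Transmembrane potential step carried by the depolarization front (mV)."""

    phi_max: float = 10.0
    phi_rest: float = -86.0

    def __post_init__(self) -> None:
        if not self.phi_max > self.phi_rest:
            raise InvalidParameterError("phi_max must exceed phi_rest")

    @property
    def delta(self) -> float:
        """Upstroke amplitude ``phi_max - phi_rest`` (mV)."""
        return self.phi_max - self.phi_rest


DEFAULT_MEMBRANE = MembraneStep()

#: Longitudinal conduction velocity (m/s == mm/ms) anchoring v(psi).
DEFAULT_V_PARALLEL = 0.42


@dataclass(frozen=True)
class MonodomainConstants:
    """Monodomain membrane constants.

    ``beta_M`` (surface-to-volume ratio, 1/m) and ``C_M`` (membrane
    capacitance, F/m^2) both cancel in the velocity ratio v(psi)/v(0), so
    only ``v_parallel`` is required for the velocity model; the other two are
    kept for completeness when an absolute diffusion constant is wanted.
    """

    v_parallel: float = DEFAULT_V_PARALLEL
    beta_M: float | None = None
    C_M: float | None = None

    def __post_init__(self) -> None:
        if not self.v_parallel > 0:
            raise InvalidParameterError("v_parallel must be > 0")
        for name in ("beta_M", "C_M"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidParameterError(f"{name} must be > 0 if given")


def rotate_conductivity(g_l: float, g_t: float, psi: float) -> dict[str, float]:
    """Rotate a transversely isotropic conductivity tensor by fiber angle psi.

    Parameters
    ----------
    g_l, g_t
        Longitudinal and transverse conductivities (S/m), both > 0.
    psi
        Fiber angle in degrees, in [0, 360).

    Returns
    -------
    dict
        Components ``g_xx``, ``g_yy``, ``g_xy``, ``g_zz`` (S/m) of the tensor
        in the propagation frame.  The in-plane trace ``g_xx + g_yy`` equals
        ``g_l + g_t`` for every angle.
    """
    if not (g_l > 0 and g_t > 0):
        raise InvalidParameterError("conductivities must be > 0")
    if not (0.0 <= psi < 360.0):
        raise InvalidParameterError(f"psi={psi!r} outside [0, 360) degrees")
    c = math.cos(math.radians(psi))
    s = math.sin(math.radians(psi))
    return {
        "g_xx": g_l * c * c + g_t * s * s,
        "g_yy": g_t * c * c + g_l * s * s,
        "g_xy": (g_l - g_t) * c * s,
        "g_zz": g_t,
    }


def lumped_properties(cs: ConductivitySet, psi: float) -> dict[str, float]:
    """Lumped directional conductivities and derived anisotropy quantities.

    Returns ``g_M = g_i,xx + g_e,xx`` (total in-plane conductivity in the
    propagation direction), ``g_zz = g_i,zz + g_e,zz`` (total transmural),
    ``eta = sqrt(g_M/g_zz)`` and the homogenized conductivity
    ``g_tilde = (g_M + eta*g_B)/2``.
    """
    gi = rotate_conductivity(cs.g_i_l, cs.g_i_t, psi)
    ge = rotate_conductivity(cs.g_e_l, cs.g_e_t, psi)
    g_M = gi["g_xx"] + ge["g_xx"]
    g_zz = gi["g_zz"] + ge["g_zz"]
    eta = math.sqrt(g_M / g_zz)
    return {
        "g_M": g_M,
        "g_zz": g_zz,
        "eta": eta,
        "g_tilde": 0.5 * (g_M + eta * cs.g_B),
        "g_i_xx": gi["g_xx"],
        "g_e_xx": ge["g_xx"],
    }


@dataclass(frozen=True)
class SlabModel:
    """Myocardial slab of thickness ``L`` between blood (z>0) and torso (z<-L).

    Parameters
    ----------
    conductivities
        The six-conductivity set.
    L
        Wall thickness in mm, > 0.
    psi
        Fiber angle in degrees, in [0, 90].
    """

    conductivities: ConductivitySet = DEFAULT_CONDUCTIVITIES
    L: float = 5.0
    psi: float = 0.0
    _props: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise InvalidParameterError("wall thickness L must be > 0")
        if not (0.0 <= self.psi <= 90.0):
            raise InvalidParameterError("psi must lie in [0, 90] degrees")
        object.__setattr__(
            self, "_props", lumped_properties(self.conductivities, self.psi)
        )

    @property
    def g_i_xx(self) -> float:
        return self._props["g_i_xx"]

    @property
    def g_e_xx(self) -> float:
        return self._props["g_e_xx"]

    @property
    def g_M(self) -> float:
        return self._props["g_M"]

    @property
    def g_zz(self) -> float:
        return self._props["g_zz"]

    @property
    def eta(self) -> float:
        return self._props["eta"]

    @property
    def g_tilde(self) -> float:
        return self._props["g_tilde"]

    @property
    def ell(self) -> float:
        """Rescaled (apparent) wall thickness ``eta * L`` in mm."""
        return self.eta * self.L


@dataclass(frozen=True)
class MirrorCoefficients:
    """Reflection (h/H) and transmission (v/V) factors of the image method.

    Lower-case members are the isotropic-myocardium factors, upper-case the
    anisotropic ones (transmural coordinate rescaled by eta).  Subscript B
    refers to the myocardium–blood interface, T to myocardium–torso.
    """

    hB: float
    hT: float
    vB: float
    vT: float
    HB: float
    HT: float
    VB: float
    VT: float


def mirror_coefficients(slab: SlabModel) -> MirrorCoefficients:
    """Image-source strength factors at the blood and torso interfaces.

    Isotropic: ``h* = (g_M - g*)/(g_M + g*)``, ``v* = 2 g*/(g_M + g*)``.
    Anisotropic: ``H* = (g_M - eta g*)/(g_M + eta g*)``,
    ``V* = 2 g*/(g_M + eta g*)``.  All reflection factors have modulus < 1
    for positive conductivities, so the mirror series converges geometrically.
    """
    gM, eta = slab.g_M, slab.eta
    gB = slab.conductivities.g_B
    gT = slab.conductivities.g_T
    return MirrorCoefficients(
        hB=(gM - gB) / (gM + gB),
        hT=(gM - gT) / (gM + gT),
        vB=2 * gB / (gM + gB),
        vT=2 * gT / (gM + gT),
        HB=(gM - eta * gB) / (gM + eta * gB),
        HT=(gM - eta * gT) / (gM + eta * gT),
        VB=2 * gB / (gM + eta * gB),
        VT=2 * gT / (gM + eta * gT),
    )


def rescale_z(z, slab: SlabModel):
    """Piecewise-linear transmural rescaling restoring isotropy in the wall.

    Z = z above the endocardium (z > 0), eta*z inside the wall
    (-L <= z <= 0) and z + L - eta*L beyond the epicardium (z < -L).
    Continuous and strictly increasing.  Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    eta, L = slab.eta, slab.L
    out = np.where(
        z > 0, z, np.where(z >= -L, eta * z, z + L - eta * L)
    )
    return float(out) if out.ndim == 0 else out


def conduction_velocity(
    cs: ConductivitySet, psi: float, v_parallel: float = DEFAULT_V_PARALLEL
) -> float:
    """Plane-wave conduction velocity at fiber angle psi (same units as input).

    The monodomain diffusion constant in the propagation direction is
    ``D = g_i,xx g_e,xx / (g_i,xx + g_e,xx)`` up to a membrane factor that
    cancels in the ratio; the velocity scales as ``sqrt(D)``, anchored at the
    measured longitudinal velocity ``v(0) = v_parallel``.
    """
    if not v_parallel > 0:
        raise InvalidParameterError("v_parallel must be > 0")

    def diffusion(angle: float) -> float:
        gi = rotate_conductivity(cs.g_i_l, cs.g_i_t, angle)["g_xx"]
        ge = rotate_conductivity(cs.g_e_l, cs.g_e_t, angle)["g_xx"]
        return gi * ge / (gi + ge)

    return v_parallel * math.sqrt(diffusion(psi) / diffusion(0.0))
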