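"""Composite one-dimensional potential for a bilayer-embedded gramicidin dimer.

The two conducting-channel subunits sit head-to-head, one per leaflet, and
interact through a Morse bond (finite dissociation energy ``D_e``, stiffness
``beta``).  Because the dimer's hydrophobic length ``l`` is shorter than the
bilayer hydrophobic thickness ``d``, the bilayer deforms locally; that
deformation costs elastic energy, summarized by a single phenomenological
Hookean coefficient ``H_B`` acting on the hydrophobic mismatch ``d - l``.  The
total potential along the subunit-separation coordinate ``r`` is

    V(r) = D_e * [(1 - exp(-beta*(r - r_e)))**2 - 1] + (H_B / 2) * (d - l(r))**2

with the axial coupling ``l(r) = l0 + s*(r - r_e)`` (unit slope ``s = 1`` by
default: each nanometre of extra subunit separation adds one nanometre of
hydrophobic length).  The Morse term is written with its minimum at ``-D_e``
and plateau at 0, so the dissociation energy reads directly as the well depth;
every reported kinetic quantity is an energy *difference* and hence
offset-invariant.

Energies are expressed in thermal units (kBT) and lengths in nanometres
unless converted through :class:`UnitSystem`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParameters",
    "UnitSystem",
    "hydrophobic_length",
    "morse_energy",
    "mismatch_energy",
    "total_potential",
    "potential_gradient",
    "potential_curvature",
    "beta_from_hooke",
    "reduced_unit_system",
    "to_reduced",
    "to_physical",
]


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the composite potential and its kinetics.

    Attributes
    ----------
    D_e : float
        Dissociation energy of the subunit-subunit Morse bond [kBT].
    r_e : float
        Equilibrium centre-of-mass separation of the two monomers [nm].
    beta : float
        Morse stiffness parameter [1/nm].
    l0 : float
        Equilibrium hydrophobic length of the dimer [nm].
    d : float
        Bilayer hydrophobic thickness [nm].  The mismatch ``d - l0`` may be
        of either sign.
    H_B : float
        Phenomenological membrane Hookean force coefficient [kBT/nm^2].
    A : float
        Arrhenius pre-exponential factor [1/time, reduced].
    kBT : float
        Thermal energy scale used in rate expressions, in the same energy
        unit as ``D_e`` (1.0 when energies are already thermal).
    coupling_slope : float
        Slope ``s`` of the axial coupling ``l(r) = l0 + s*(r - r_e)``.
        Default 1 (unit-slope coupling); exposed for sensitivity analyses.
    """

    D_e: float
    r_e: float
    beta: float
    l0: float
    d: float
    H_B: float
    A: float = 1.0
    kBT: float = 1.0
    coupling_slope: float = 1.0

    def __post_init__(self) -> None:
        for name in ("D_e", "r_e", "beta", "l0", "d", "A", "kBT"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")
        if not math.isfinite(self.H_B) or self.H_B < 0:
            raise ValueError(f"H_B must be finite and non-negative, got {self.H_B!r}")
        if not math.isfinite(self.coupling_slope) or self.coupling_slope <= 0:
            raise ValueError(
                f"coupling_slope must be a finite positive number, got {self.coupling_slope!r}"
            )

    @property
    def mismatch(self) -> float:
        """Hydrophobic mismatch ``d - l0`` at the equilibrium separation [nm]."""
        return self.d - self.l0

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class UnitSystem:
    """Scale factors mapping a parameter set to thermal/nanometre units.

    ``energy_scale`` converts one unit of energy to kBT; ``length_scale``
    converts one unit of length to nm.  Reduced units use
    ``energy_scale = kBT`` and ``length_scale = r_e``.
    """

    energy_label: str = "kBT"
    energy_scale: float = 1.0
    length_label: str = "nm"
    length_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("energy_scale", "length_scale"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")


def _validate_r(r):
    arr = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"separation r must be finite and positive, got {r!r}")
    return arr


def _as_input(value, r):
    # return a scalar when the caller passed a scalar
    return float(value) if np.isscalar(r) or np.ndim(r) == 0 else value


def hydrophobic_length(r, p: ModelParameters):
    """Dimer hydrophobic length ``l(r) = l0 + s*(r - r_e)`` [nm].

    Equals ``l0`` at the equilibrium separation and grows one nanometre per
    nanometre of extra axial separation (for the default unit slope), so the
    mismatch ``d - l(r)`` is exactly relieved at ``r = r_e + (d - l0)/s``.
    """
    arr = _validate_r(r)
    return _as_input(p.l0 + p.coupling_slope * (arr - p.r_e), r)


def morse_energy(r, p: ModelParameters):
    """Subunit-subunit Morse bond energy [kBT].

    ``D_e*[(1 - exp(-beta*(r - r_e)))**2 - 1]``: minimum ``-D_e`` at
    ``r = r_e``, plateau 0 as ``r -> inf``.
    """
    arr = _validate_r(r)
    u = np.exp(-p.beta * (arr - p.r_e))
    return _as_input(p.D_e * ((1.0 - u) ** 2 - 1.0), r)


def mismatch_energy(r, p: ModelParameters):
    """Harmonic bilayer-deformation energy ``(H_B/2)*(d - l(r))**2`` [kBT].

    Zero exactly where the mismatch is relieved; two-sided, i.e. overshoot
    ``l(r) > d`` is penalized identically to undershoot.
    """
    arr = _validate_r(r)
    residual = p.d - (p.l0 + p.coupling_slope * (arr - p.r_e))
    return _as_input(0.5 * p.H_B * residual**2, r)


def total_potential(r, p: ModelParameters):
    """Composite potential: Morse bond plus mismatch penalty [kBT]."""
    arr = _validate_r(r)
    u = np.exp(-p.beta * (arr - p.r_e))
    residual = p.d - (p.l0 + p.coupling_slope * (arr - p.r_e))
    return _as_input(p.D_e * ((1.0 - u) ** 2 - 1.0) + 0.5 * p.H_B * residual**2, r)


def potential_gradient(r, p: ModelParameters):
    """Analytic first derivative dV/dr [kBT/nm]."""
    arr = _validate_r(r)
    u = np.exp(-p.beta * (arr - p.r_e))
    residual = p.d - (p.l0 + p.coupling_slope * (arr - p.r_e))
    grad = 2.0 * p.D_e * p.beta * u * (1.0 - u) - p.H_B * p.coupling_slope * residual
    return _as_input(grad, r)


def potential_curvature(r, p: ModelParameters):
    """Analytic second derivative d2V/dr2 [kBT/nm^2].

    At ``r = r_e`` the Morse contribution is ``2*D_e*beta**2``; the mismatch
    term contributes a constant ``H_B*s**2``.
    """
    arr = _validate_r(r)
    u = np.exp(-p.beta * (arr - p.r_e))
    curv = 2.0 * p.D_e * p.beta**2 * u * (2.0 * u - 1.0) + p.H_B * p.coupling_slope**2
    return _as_input(curv, r)


def beta_from_hooke(k: float, D_e: float) -> float:
    """Morse stiffness equivalent to a Hookean constant ``k`` near ``r_e``.

    Matching the harmonic expansion of the Morse bond,
    ``V''(r_e) = 2*D_e*beta**2 = k``, gives ``beta = sqrt(k / (2*D_e))``.

    Parameters are ``k`` [kBT/nm^2] and ``D_e`` [kBT]; returns [1/nm].
    """
    if not math.isfinite(k) or k <= 0:
        raise ValueError(f"k must be a finite positive number, got {k!r}")
    if not math.isfinite(D_e) or D_e <= 0:
        raise ValueError(f"D_e must be a finite positive number, got {D_e!r}")
    return math.sqrt(k / (2.0 * D_e))


def reduced_unit_system(p: ModelParameters) -> UnitSystem:
    """Unit system in which ``p`` becomes reduced (energies in kBT units of
    ``p``, lengths in units of ``r_e``)."""
    return UnitSystem(
        energy_label="kBT", energy_scale=p.kBT, length_label="r_e", length_scale=p.r_e
    )


def to_reduced(p: ModelParameters) -> ModelParameters:
    """Rescale to reduced units: energies in units of ``p.kBT`` and lengths
    in units of ``p.r_e`` (so ``r_e = 1`` and ``kBT = 1`` afterwards).

    Use :func:`reduced_unit_system` on the original set to invert.
    """
    return to_physical(p, UnitSystem(energy_scale=1.0 / p.kBT, length_scale=1.0 / p.r_e))


def to_physical(p: ModelParameters, u: UnitSystem) -> ModelParameters:
    """Apply unit scale factors to a parameter set.

    Energies are multiplied by ``u.energy_scale``, lengths by
    ``u.length_scale``; derived fields follow their dimensions
    (``beta ~ 1/length``, ``H_B ~ energy/length^2``).  The pre-exponential
    ``A`` carries its own time unit and is untouched.  Barriers, reduced
    lifetimes and regime classifications are invariant under the round trip.
    """
    e, L = u.energy_scale, u.length_scale
    return ModelParameters(
        D_e=p.D_e * e,
        r_e=p.r_e * L,
        beta=p.beta / L,
        l0=p.l0 * L,
        d=p.d * L,
        H_B=p.H_B * e / L**2,
        A=p.A,
        kBT=p.kBT * e,
        coupling_slope=p.coupling_slope,
    )
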