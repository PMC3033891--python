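"""Transition-state kinetics of dimer dissociation.

Given a classified double-well landscape, the dissociation rate follows the
Arrhenius form ``k_diss = A * exp(-dV/kBT)`` with ``dV`` the barrier from the
dimer well to the transition state, and the mean channel lifetime is
``tau = 1/k_diss``, so ``ln(tau * A) = dV / kBT``.

The pre-exponential factor ``A`` is not constrained by the model; lifetimes
are therefore reported primarily as the dimensionless ``ln(tau * A)``, whose
trends with bilayer thickness and stiffness are A-independent.  The membrane
"disjoining force" — the harmonic pull the deformed bilayer exerts on the
dimer at its well — is ``H_B * (d - l(r_dim))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import RegimeError
from .model import ModelParameters, hydrophobic_length
from .stationary import PotentialLandscape

__all__ = [
    "KineticsSummary",
    "activation_barrier",
    "dissociation_rate",
    "mean_lifetime",
    "ln_reduced_lifetime",
    "distance_to_transition",
    "disjoining_force",
    "summarize",
]


@dataclass(frozen=True)
class KineticsSummary:
    """Kinetic observables for one landscape.

    ``barrier`` [kBT], ``rate`` [1/time], ``ln_lifetime`` = ln(tau*A)
    (dimensionless), ``distance_to_ts`` [nm], ``disjoining_force`` [kBT/nm],
    ``mismatch_at_dimer`` = d - l(r_dim) [nm].  Fields that the regime does
    not define are ``None``; in the ``barrierless`` regime the rate is a
    lower bound (``rate >= A``), flagged by ``rate_is_lower_bound``.
    """

    regime: str
    barrier: Optional[float]
    rate: Optional[float]
    ln_lifetime: Optional[float]
    distance_to_ts: Optional[float]
    disjoining_force: Optional[float]
    mismatch_at_dimer: Optional[float]
    rate_is_lower_bound: bool = False


def activation_barrier(L: PotentialLandscape) -> float:
    """Barrier ``V(r_ts) - V(r_dim)`` [kBT]; double-well regime only.

    Offset-invariant by construction (a difference of energies).
    """
    if L.regime != "double_well":
        raise RegimeError(
            f"activation barrier undefined in regime {L.regime!r} (no transition state)"
        )
    return L.transition_state.energy - L.dimer_well.energy


def dissociation_rate(barrier: float, p: ModelParameters) -> float:
    """Arrhenius rate ``A * exp(-barrier/kBT)`` [1/time]."""
    if barrier < 0:
        raise ValueError(f"barrier must be non-negative, got {barrier!r}")
    return p.A * math.exp(-barrier / p.kBT)


def mean_lifetime(rate: float) -> float:
    """Mean dimer lifetime ``tau = 1/rate``."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate!r}")
    return 1.0 / rate


def ln_reduced_lifetime(barrier: float, p: ModelParameters) -> float:
    """``ln(tau * A) = barrier/kBT - ln(A*1_A)`` — exactly ``barrier/kBT``
    in reduced time units, independent of the unassigned prefactor."""
    if barrier < 0:
        raise ValueError(f"barrier must be non-negative, got {barrier!r}")
    return barrier / p.kBT


def distance_to_transition(L: PotentialLandscape) -> float:
    """Separation increase ``r_ts - r_dim`` needed to reach the transition
    state [nm]; double-well regime only."""
    if L.regime != "double_well":
        raise RegimeError(
            f"distance to transition state undefined in regime {L.regime!r}"
        )
    return L.r_ts - L.r_dim


def disjoining_force(L: PotentialLandscape) -> float:
    """Membrane pull on the dimer at its well: ``H_B * (d - l(r_dim))``
    [kBT/nm].

    Equals minus the derivative of the mismatch term at ``r_dim`` divided by
    the coupling slope; zero when the mismatch is relieved or ``H_B = 0``.
    """
    if L.r_dim is None:
        raise RegimeError(f"no dimer well in regime {L.regime!r}")
    p = L.parameters
    return p.H_B * (p.d - hydrophobic_length(L.r_dim, p))


def summarize(L: PotentialLandscape) -> KineticsSummary:
    """Collect all kinetic observables defined by the landscape's regime."""
    p = L.parameters
    if L.regime == "double_well":
        dV = activation_barrier(L)
        return KineticsSummary(
            regime=L.regime,
            barrier=dV,
            rate=dissociation_rate(dV, p),
            ln_lifetime=ln_reduced_lifetime(dV, p),
            distance_to_ts=distance_to_transition(L),
            disjoining_force=disjoining_force(L),
            mismatch_at_dimer=p.d - hydrophobic_length(L.r_dim, p),
        )
    force = mismatch = None
    if L.r_dim is not None:
        force = disjoining_force(L)
        mismatch = p.d - hydrophobic_length(L.r_dim, p)
    if L.regime == "barrierless":
        # no barrier survives: dissociation is at least as fast as A
        return KineticsSummary(
            regime=L.regime,
            barrier=None,
            rate=p.A,
            ln_lifetime=None,
            distance_to_ts=None,
            disjoining_force=force,
            mismatch_at_dimer=mismatch,
            rate_is_lower_bound=True,
        )
    return KineticsSummary(
        regime=L.regime,
        barrier=None,
        rate=None,
        ln_lifetime=None,
        distance_to_ts=None,
        disjoining_force=force,
        mismatch_at_dimer=mismatch,
    )
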