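"""Seeded generator of randomized, physically sensible parameter sets.

Used by the property tests and the verification pipeline to sweep the model
over realistic corners of parameter space: bond depths of a few to a few
tens of kBT, Morse decay lengths small against the equilibrium separation,
mismatches of either sign, and bilayer stiffnesses capped so the elastic
energy at the dimer well never exceeds the bond depth.  Each set is
annotated with the landscape regime found by the derivative-free grid
oracle, so consumers can pick sets by regime without touching the
root-finding path under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParameters
from .stationary import oracle_regime

__all__ = ["AnnotatedParameters", "generate_fixture_parameters"]


@dataclass(frozen=True)
class AnnotatedParameters:
    """A sampled parameter set plus its oracle-classified regime."""

    params: ModelParameters
    expected_regime: str


def generate_fixture_parameters(seed: int, n: int) -> list[AnnotatedParameters]:
    """Draw ``n`` valid parameter sets, deterministic in ``seed``.

    Sampling ranges: D_e in [2, 30] kBT, beta*r_e in [2, 30], r_e in
    [0.8, 1.8] nm, l0 in [1.5, 3.0] nm, mismatch d - l0 in [-0.5, 1.5] nm,
    and H_B chosen so the mismatch energy at r = r_e lies in [0, D_e]
    (small mismatches are floored at 0.05 nm when inverting, so the cap
    stays finite).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out: list[AnnotatedParameters] = []
    for _ in range(n):
        r_e = rng.uniform(0.8, 1.8)
        D_e = rng.uniform(2.0, 30.0)
        beta = rng.uniform(2.0, 30.0) / r_e
        l0 = rng.uniform(1.5, 3.0)
        mismatch = rng.uniform(-0.5, 1.5)
        d = l0 + mismatch
        cap = 2.0 * D_e / max(abs(mismatch), 0.05) ** 2
        H_B = rng.uniform(0.0, 1.0) * cap
        p = ModelParameters(D_e=D_e, r_e=r_e, beta=beta, l0=l0, d=d, H_B=H_B)
        out.append(AnnotatedParameters(params=p, expected_regime=oracle_regime(p)))
    return out
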