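"""Stationary-point analysis of the one-dimensional dimer potential.

The composite potential is at most a double well along the separation
coordinate: a dimer well near ``r_e`` (the conducting channel), an interior
maximum (the transition state for dissociation) and a dissociated well near
the separation at which the hydrophobic mismatch is relieved.  Depending on
the mismatch and the bilayer stiffness either well — or the barrier between
them — may be absent, so the landscape carries an explicit regime label.

Roots of the analytic gradient are bracketed on a uniform grid and refined
with a bracket-preserving root finder; classification uses the analytic
curvature.  :func:`oracle_grid_search` provides a derivative-free check that
locates extrema purely from sampled potential values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import NumericalError
from .model import (
    ModelParameters,
    potential_curvature,
    potential_gradient,
    total_potential,
)

__all__ = [
    "StationaryPoint",
    "PotentialLandscape",
    "default_search_interval",
    "analyze_landscape",
    "oracle_grid_search",
    "GRADIENT_TOL",
    "DEGENERACY_TOL",
]

# reduced-unit tolerances (energies in kBT, lengths in r_e)
GRADIENT_TOL = 1e-10
DEGENERACY_TOL = 1e-8
MERGE_TOL = 1e-6  # roots closer than MERGE_TOL * r_e are merged
DEFAULT_GRID_POINTS = 4001

REGIMES = ("double_well", "single_well_dimer", "single_well_dissociated", "barrierless")


@dataclass(frozen=True)
class StationaryPoint:
    """A root of the potential gradient.

    ``kind`` is ``"minimum"`` or ``"maximum"`` by the sign of the curvature;
    roots with |curvature| below the degeneracy tolerance are ``"degenerate"``
    (a well and the barrier coalescing at the bifurcation).
    """

    r: float
    energy: float
    curvature: float
    kind: str


@dataclass(frozen=True)
class PotentialLandscape:
    """Classified stationary-point set for one parameter set.

    ``points`` are ordered by increasing separation.  ``regime`` is one of
    ``double_well``, ``single_well_dimer``, ``single_well_dissociated`` or
    ``barrierless``; the named separations ``r_dim``/``r_ts``/``r_diss`` are
    populated where the regime defines them.
    """

    parameters: ModelParameters
    points: tuple[StationaryPoint, ...]
    regime: str
    r_dim: Optional[float] = None
    r_ts: Optional[float] = None
    r_diss: Optional[float] = None
    search_interval: tuple[float, float] = field(default=(0.0, 0.0))

    @property
    def dimer_well(self) -> Optional[StationaryPoint]:
        return self._point_at(self.r_dim)

    @property
    def transition_state(self) -> Optional[StationaryPoint]:
        return self._point_at(self.r_ts)

    @property
    def dissociated_well(self) -> Optional[StationaryPoint]:
        return self._point_at(self.r_diss)

    def _point_at(self, r: Optional[float]) -> Optional[StationaryPoint]:
        if r is None:
            return None
        return min(self.points, key=lambda pt: abs(pt.r - r))


def default_search_interval(p: ModelParameters) -> tuple[float, float]:
    """Interval bracketing both candidate wells with Morse-decay margin.

    ``[max(eps, r_e - 5/beta), r_e + max(d - l0, 0) + 5/beta + 0.5*r_e]``:
    five Morse decay lengths either side of the dimer well plus the shift of
    the mismatch-relieved separation, with extra slack on the open side.
    """
    lo = max(1e-9 * p.r_e, p.r_e - 5.0 / p.beta)
    shift = max(p.mismatch / p.coupling_slope, 0.0)
    hi = p.r_e + shift + 5.0 / p.beta + 0.5 * p.r_e
    return (lo, hi)


def _refine_root(p: ModelParameters, a: float, b: float) -> float:
    ga = potential_gradient(a, p)
    gb = potential_gradient(b, p)
    if ga == 0.0:
        return a
    if gb == 0.0:
        return b
    if np.sign(ga) == np.sign(gb):
        raise NumericalError(
            f"gradient sign change lost during refinement on [{a!r}, {b!r}]"
        )
    return brentq(lambda r: potential_gradient(r, p), a, b, xtol=1e-15, rtol=8.9e-16)


def _classify(p: ModelParameters, r: float) -> StationaryPoint:
    curv = potential_curvature(r, p)
    curv_reduced = curv * p.r_e**2 / p.kBT
    if abs(curv_reduced) < DEGENERACY_TOL:
        kind = "degenerate"
    else:
        kind = "minimum" if curv > 0 else "maximum"
    return StationaryPoint(r=r, energy=total_potential(r, p), curvature=curv, kind=kind)


def analyze_landscape(
    p: ModelParameters,
    interval: Optional[tuple[float, float]] = None,
    n_grid: int = DEFAULT_GRID_POINTS,
) -> PotentialLandscape:
    """Locate and classify all stationary points on ``interval``.

    Every sign change of the analytic gradient on the ``n_grid``-point
    bracketing grid is refined to machine precision; roots closer than the
    merge tolerance are merged; points are classified by the analytic
    curvature and the landscape regime is assigned:

    - two minima separated by a maximum -> ``double_well`` (the minimum
      nearest ``r_e`` is the dimer well, the largest-r minimum the
      dissociated well);
    - one minimum -> ``single_well_dimer`` or ``single_well_dissociated`` by
      proximity to ``r_e`` versus the mismatch-relieved separation;
    - any degenerate root (well and barrier coalescing) -> ``barrierless``.

    Raises ``ValueError`` if the interval does not contain ``r_e`` and
    :class:`~memtug.errors.NumericalError` if a bracket cannot be resolved.
    """
    if interval is None:
        interval = default_search_interval(p)
    lo, hi = float(interval[0]), float(interval[1])
    if not (0.0 < lo < hi):
        raise ValueError(f"invalid search interval {interval!r}")
    if not (lo <= p.r_e <= hi):
        raise ValueError(
            f"search interval {interval!r} does not contain the equilibrium separation r_e={p.r_e}"
        )
    if n_grid < 3:
        raise ValueError("n_grid must be at least 3")

    grid = np.linspace(lo, hi, int(n_grid))
    g = potential_gradient(grid, p)

    roots: list[float] = []
    for i in range(len(grid) - 1):
        ga, gb = g[i], g[i + 1]
        if ga == 0.0:
            roots.append(float(grid[i]))
        elif np.sign(ga) != np.sign(gb):
            roots.append(_refine_root(p, float(grid[i]), float(grid[i + 1])))
    if len(g) and g[-1] == 0.0:
        roots.append(float(grid[-1]))

    merged: list[float] = []
    for r in sorted(roots):
        if merged and (r - merged[-1]) < MERGE_TOL * p.r_e:
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)

    points = tuple(_classify(p, r) for r in merged)
    gtol = GRADIENT_TOL * p.kBT / p.r_e
    for pt in points:
        if abs(potential_gradient(pt.r, p)) > max(gtol, 1e-9 * abs(pt.curvature) * p.r_e):
            raise NumericalError(
                f"stationary point at r={pt.r} failed the gradient tolerance"
            )

    return _assign_regime(p, points, (lo, hi))


def _assign_regime(
    p: ModelParameters, points: tuple[StationaryPoint, ...], interval: tuple[float, float]
) -> PotentialLandscape:
    if any(pt.kind == "degenerate" for pt in points):
        minima = [pt for pt in points if pt.kind == "minimum"]
        r_dim = None
        if minima:
            dim = min(minima, key=lambda pt: abs(pt.r - p.r_e))
            r_dim = dim.r
        return PotentialLandscape(
            parameters=p, points=points, regime="barrierless", r_dim=r_dim,
            search_interval=interval,
        )

    minima = [pt for pt in points if pt.kind == "minimum"]
    maxima = [pt for pt in points if pt.kind == "maximum"]

    if len(minima) == 0:
        # pure downhill landscape: the membrane pull exceeds the bond force
        # everywhere in the interval
        return PotentialLandscape(
            parameters=p, points=points, regime="barrierless", search_interval=interval
        )

    if len(minima) == 1:
        m = minima[0]
        relieved = p.r_e + p.mismatch / p.coupling_slope
        regime = (
            "single_well_dimer"
            if abs(m.r - p.r_e) <= abs(m.r - relieved)
            else "single_well_dissociated"
        )
        kwargs = {"r_dim": m.r} if regime == "single_well_dimer" else {"r_diss": m.r}
        return PotentialLandscape(
            parameters=p, points=points, regime=regime, search_interval=interval, **kwargs
        )

    dim = min(minima, key=lambda pt: abs(pt.r - p.r_e))
    diss = max(minima, key=lambda pt: pt.r)
    lo_r, hi_r = min(dim.r, diss.r), max(dim.r, diss.r)
    interior = [pt for pt in maxima if lo_r < pt.r < hi_r]
    if dim.r == diss.r or not interior:
        raise NumericalError(
            "unclassifiable stationary-point pattern: "
            f"{[(pt.kind, pt.r) for pt in points]}"
        )
    ts = max(interior, key=lambda pt: pt.energy)
    return PotentialLandscape(
        parameters=p,
        points=points,
        regime="double_well",
        r_dim=dim.r,
        r_ts=ts.r,
        r_diss=diss.r,
        search_interval=interval,
    )


def oracle_grid_search(
    p: ModelParameters,
    interval: Optional[tuple[float, float]] = None,
    n_points: int = 20001,
) -> list[StationaryPoint]:
    """Derivative-free extremum search: sample the potential and report
    interior local minima/maxima of the sampled values.

    Uses only ``total_potential`` evaluations (curvature is estimated from
    the sampled second difference), so it is independent of the analytic
    derivatives and of the root refinement; accuracy is limited to one grid
    step.  Intended as a verification oracle, not a production path.
    """
    if n_points < 10_000:
        raise ValueError("oracle requires n_points >= 10000 for meaningful resolution")
    if interval is None:
        interval = default_search_interval(p)
    grid = np.linspace(float(interval[0]), float(interval[1]), int(n_points))
    v = total_potential(grid, p)
    h = grid[1] - grid[0]

    out: list[StationaryPoint] = []
    inner = slice(1, -1)
    is_min = (v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:])
    is_max = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    second = (v[2:] - 2.0 * v[1:-1] + v[:-2]) / h**2
    for idx in np.flatnonzero(is_min | is_max):
        kind = "minimum" if is_min[idx] else "maximum"
        out.append(
            StationaryPoint(
                r=float(grid[inner][idx]),
                energy=float(v[inner][idx]),
                curvature=float(second[idx]),
                kind=kind,
            )
        )
    return out


def oracle_regime(p: ModelParameters, n_points: int = 10_001) -> str:
    """Coarse regime label from the derivative-free oracle alone."""
    pts = oracle_grid_search(p, n_points=max(n_points, 10_000))
    minima = [pt for pt in pts if pt.kind == "minimum"]
    maxima = [pt for pt in pts if pt.kind == "maximum"]
    if len(minima) == 2 and len(maxima) == 1:
        return "double_well"
    if len(minima) == 1 and not maxima:
        relieved = p.r_e + p.mismatch / p.coupling_slope
        m = minima[0]
        return (
            "single_well_dimer"
            if abs(m.r - p.r_e) <= abs(m.r - relieved)
            else "single_well_dissociated"
        )
    return "barrierless"
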