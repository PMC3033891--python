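"""Parameter sweeps over bilayer thickness and stiffness.

Each scan re-analyzes the landscape point by point and collects the kinetic
summary into a table; an ordinary-least-squares line through ``ln(tau*A)``
versus the swept variable summarizes the approximately linear lifetime
trends.  Rows whose regime is not double-well (no barrier) are kept in the
table but excluded from fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import summarize
from .model import ModelParameters
from .stationary import analyze_landscape

__all__ = [
    "LinearFit",
    "ScanResult",
    "SCAN_COLUMNS",
    "linear_fit",
    "scan_thickness",
    "scan_stiffness",
    "mismatch_slope",
    "disjoining_force_fit",
]

# fixed, documented column order of every scan table / CSV
SCAN_COLUMNS = [
    "swept_value",
    "r_dim",
    "r_ts",
    "r_diss",
    "barrier",
    "ln_lifetime",
    "distance_to_ts",
    "disjoining_force",
    "regime",
]

# operational thresholds for calling a trend "approximately linear";
# recorded in scan metadata so reports are self-describing
R2_LIFETIME_LINEAR = 0.98
R2_FORCE_LINEAR = 0.99


@dataclass(frozen=True)
class LinearFit:
    """Ordinary-least-squares line ``y = slope*x + intercept``.

    ``degenerate`` marks the zero-total-variance case (constant y), for
    which ``r_squared`` is 1 by convention (zero residual).
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ScanResult:
    """One-parameter sweep: per-point landscape/kinetics rows plus the OLS
    summary of ``ln_lifetime`` over the double-well rows."""

    swept_variable: str  # "thickness" | "stiffness"
    rows: pd.DataFrame
    fit: Optional[LinearFit]
    n_double_well: int
    metadata: dict = field(default_factory=dict)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS fit of y on x with explicit degenerate-case convention.

    Requires at least 3 finite pairs and non-zero variance in x.  When y has
    zero total variance the residual is also zero and ``r_squared`` is 1,
    flagged ``degenerate``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"linear fit needs at least 3 finite pairs, got {len(x)}")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise ValueError("linear fit needs non-zero variance in x")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0.0:
        return LinearFit(slope=slope, intercept=intercept, r_squared=1.0, n=len(x), degenerate=True)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    return LinearFit(
        slope=slope,
        intercept=intercept,
        r_squared=1.0 - ss_res / ss_tot,
        n=len(x),
    )


def _scan(p: ModelParameters, field_name: str, values: Sequence[float], label: str) -> ScanResult:
    values = [float(v) for v in values]
    if not values:
        raise ValueError(f"{label} scan needs at least one value")
    if any(b < a for a, b in zip(values, values[1:])):
        raise ValueError(f"{label} scan values must be sorted in non-decreasing order")

    records = []
    for v in values:
        pv = p.replace(**{field_name: v})
        L = analyze_landscape(pv)
        s = summarize(L)
        records.append(
            {
                "swept_value": v,
                "r_dim": L.r_dim if L.r_dim is not None else np.nan,
                "r_ts": L.r_ts if L.r_ts is not None else np.nan,
                "r_diss": L.r_diss if L.r_diss is not None else np.nan,
                "barrier": s.barrier if s.barrier is not None else np.nan,
                "ln_lifetime": s.ln_lifetime if s.ln_lifetime is not None else np.nan,
                "distance_to_ts": s.distance_to_ts if s.distance_to_ts is not None else np.nan,
                "disjoining_force": s.disjoining_force
                if s.disjoining_force is not None
                else np.nan,
                "regime": L.regime,
            }
        )
    rows = pd.DataFrame.from_records(records, columns=SCAN_COLUMNS)

    dw = rows[rows["regime"] == "double_well"]
    fit = None
    if len(dw) >= 3 and dw["swept_value"].nunique() >= 2:
        fit = linear_fit(dw["swept_value"], dw["ln_lifetime"])
    return ScanResult(
        swept_variable=label,
        rows=rows,
        fit=fit,
        n_double_well=int(len(dw)),
        metadata={
            "swept_field": field_name,
            "n_points": len(values),
            "n_excluded_from_fit": len(values) - int(len(dw)),
            "r2_linear_threshold_lifetime": R2_LIFETIME_LINEAR,
            "r2_linear_threshold_force": R2_FORCE_LINEAR,
        },
    )


def scan_thickness(p: ModelParameters, d_values: Sequence[float]) -> ScanResult:
    """Sweep the bilayer hydrophobic thickness ``d`` [nm].

    For thickness above the dimer hydrophobic length the mismatch grows with
    ``d``: the bilayer pulls harder, the barrier shrinks, and both
    ``ln(tau*A)`` and the distance to the transition state decrease.
    """
    if any(v <= 0 for v in d_values):
        raise ValueError("bilayer thickness values must be positive")
    return _scan(p, "d", d_values, "thickness")


def scan_stiffness(p: ModelParameters, hb_values: Sequence[float]) -> ScanResult:
    """Sweep the membrane Hookean coefficient ``H_B`` [kBT/nm^2] at the
    thickness fixed in ``p``.

    With positive mismatch, a stiffer bilayer exerts a larger disjoining
    force, lowering the barrier and shortening the lifetime.
    """
    if any(v < 0 for v in hb_values):
        raise ValueError("stiffness values must be non-negative")
    return _scan(p, "H_B", hb_values, "stiffness")


def _thickness_dw_rows(scan: ScanResult, min_rows: int) -> pd.DataFrame:
    if scan.swept_variable != "thickness":
        raise ValueError("expected a thickness scan")
    dw = scan.rows[scan.rows["regime"] == "double_well"]
    if len(dw) < min_rows:
        raise ValueError(
            f"need at least {min_rows} double-well rows, scan has {len(dw)}"
        )
    return dw


def mismatch_slope(scan: ScanResult, l0: float) -> float:
    """OLS slope of ``ln(tau*A)`` versus hydrophobic mismatch ``d - l0``
    [1/nm] over the double-well rows of a thickness scan.

    Identical to the scan's thickness slope, since ``d`` and ``d - l0``
    differ by a constant; negative for positive-mismatch sweeps.
    """
    dw = _thickness_dw_rows(scan, 3)
    return linear_fit(dw["swept_value"] - l0, dw["ln_lifetime"]).slope


def disjoining_force_fit(scan: ScanResult, l0: float) -> LinearFit:
    """OLS line of the disjoining force versus mismatch ``d - l0`` over the
    double-well rows of a thickness scan (the near-linear force law)."""
    dw = _thickness_dw_rows(scan, 3)
    return linear_fit(dw["swept_value"] - l0, dw["disjoining_force"])
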