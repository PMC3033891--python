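"""Writers for scan tables (CSV), structured summaries (JSON) and plots.

Outputs are deterministic: floats are written in shortest round-trip
representation, JSON keys are sorted, and no timestamps are embedded, so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .model import total_potential
from .scans import SCAN_COLUMNS, ScanResult
from .stationary import PotentialLandscape

__all__ = ["write_scan_csv", "read_scan_csv", "write_json", "render_plot"]


def write_scan_csv(scan: ScanResult, path) -> None:
    """Write the scan table with the fixed documented header
    (see ``memtug.scans.SCAN_COLUMNS``); numeric columns round-trip exactly."""
    scan.rows.to_csv(path, index=False, columns=SCAN_COLUMNS, lineterminator="\n")


def read_scan_csv(path) -> pd.DataFrame:
    """Read a scan table written by :func:`write_scan_csv`."""
    return pd.read_csv(path)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return [_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_json(obj, path) -> None:
    """Serialize dataclasses / DataFrames / numpy scalars to stable JSON
    (sorted keys, NaN -> null)."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def render_plot(obj, path, n_samples: int = 1000) -> None:
    """Render a landscape (potential curve with stationary points) or a scan
    (ln lifetime / distance versus the swept variable) to an image file."""
    if isinstance(obj, PotentialLandscape):
        _plot_landscape(obj, path, n_samples)
    elif isinstance(obj, ScanResult):
        _plot_scan(obj, path)
    else:
        raise TypeError(f"cannot plot object of type {type(obj).__name__}")


def _plot_landscape(L: PotentialLandscape, path, n_samples: int) -> None:
    lo, hi = L.search_interval
    r = np.linspace(lo, hi, n_samples)
    v = total_potential(r, L.parameters)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(r, v, lw=1.5)
    for pt in L.points:
        marker = "o" if pt.kind == "minimum" else ("x" if pt.kind == "maximum" else "s")
        ax.plot([pt.r], [pt.energy], marker, ms=7, color="crimson")
    ax.set_xlabel("subunit separation r [nm]")
    ax.set_ylabel("V(r) [kBT]")
    ax.set_title(f"regime: {L.regime}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_scan(scan: ScanResult, path) -> None:
    rows = scan.rows
    xlabel = (
        "bilayer thickness d [nm]"
        if scan.swept_variable == "thickness"
        else "membrane stiffness H_B [kBT/nm$^2$]"
    )
    two_panel = scan.swept_variable == "thickness"
    fig, axes = plt.subplots(1, 2 if two_panel else 1, figsize=(9 if two_panel else 5, 4))
    axes = np.atleast_1d(axes)
    axes[0].plot(rows["swept_value"], rows["ln_lifetime"], "o-")
    axes[0].set_xlabel(xlabel)
    axes[0].set_ylabel(r"ln($\tau$ A)")
    if two_panel:
        axes[1].plot(rows["swept_value"], rows["distance_to_ts"], "s-")
        axes[1].set_xlabel(xlabel)
        axes[1].set_ylabel("distance to transition state [nm]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
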