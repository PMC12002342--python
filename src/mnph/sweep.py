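"""Single-parameter sensitivity sweeps over the bioheat scenario.

One full transient solve per parameter value, all else held at the base
scenario; the headline scalar per run is the domain-maximum temperature at
the final time (robust to probe-placement ambiguity).  The monotonicity
report classifies each parameter as "inverse" (peak temperature falls as the
parameter rises), "direct", or "non-monotone".

Default value grids:
omega_b 0.001-0.005 1/s, rho_b 700-1100 kg/m^3, C_b 2800-4400 J/kg/K,
Q_met 1-5 kW/m^3, Q_nano 110-190 kW/m^3, five values each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioheat import SimulationGrid, TissueModel, simulate
from .constants import kelvin_to_celsius
from .scenario import _apply_parameter, default_scenario

__all__ = ["SweepSpec", "DEFAULT_SWEEP_VALUES", "run_sweep", "run_all_sweeps", "monotonicity_report"]

DEFAULT_SWEEP_VALUES = {
    "omega_b": [0.001, 0.002, 0.003, 0.004, 0.005],
    "rho_b": [700.0, 800.0, 900.0, 1000.0, 1100.0],
    "C_b": [2800.0, 3200.0, 3600.0, 4000.0, 4400.0],
    "Q_met": [1e3, 2e3, 3e3, 4e3, 5e3],
    "Q_nano": [110e3, 130e3, 150e3, 170e3, 190e3],
}


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep description."""

    parameter: str
    values: tuple = ()
    base: TissueModel = field(default_factory=default_scenario)

    def __post_init__(self):
        if self.parameter not in DEFAULT_SWEEP_VALUES:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; "
                f"expected one of {sorted(DEFAULT_SWEEP_VALUES)}"
            )
        vals = tuple(self.values) or tuple(DEFAULT_SWEEP_VALUES[self.parameter])
        object.__setattr__(self, "values", vals)
        if len(vals) >= 2:
            diffs = np.diff(vals)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError("sweep values must be strictly ordered")


def run_sweep(spec: SweepSpec, grid: SimulationGrid) -> pd.DataFrame:
    """One simulation per value; returns a tidy table.

    Columns: parameter, value, peak_T_C, then the probe temperatures at the
    final time (P1..P6, Celsius).  A failed run is reported in-row (``error``
    column) and the sweep continues.
    """
    rows = []
    for value in spec.values:
        row = {"parameter": spec.parameter, "value": value}
        try:
            model = _apply_parameter(spec.base, spec.parameter, value)
            hist = simulate(model, grid)
            row["peak_T_C"] = kelvin_to_celsius(hist.peak())
            for name, T in zip(hist.probe_names, hist.probe_values[-1]):
                row[f"{name}_C"] = kelvin_to_celsius(float(T))
            row["error"] = ""
        except Exception as exc:  # keep the sweep alive, report per row
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_all_sweeps(grid: SimulationGrid, base: TissueModel | None = None) -> pd.DataFrame:
    """All five default sweeps concatenated."""
    base = base if base is not None else default_scenario()
    tables = [
        run_sweep(SweepSpec(parameter=p, base=base), grid)
        for p in DEFAULT_SWEEP_VALUES
    ]
    return pd.concat(tables, ignore_index=True)


def monotonicity_report(table: pd.DataFrame) -> dict[str, dict]:
    """Verdict per parameter from the signs of successive peak-T differences.

    "inverse" when every step decreases the peak, "direct" when every step
    increases it, "non-monotone" otherwise (with a zero-difference note when
    applicable).
    """
    out = {}
    for param, sub in table.groupby("parameter", sort=False):
        sub = sub.sort_values("value")
        ok = sub[sub["error"] == ""] if "error" in sub else sub
        diffs = np.diff(ok["peak_T_C"].to_numpy())
        if len(diffs) == 0:
            verdict = "non-monotone"
            note = "fewer than two successful runs"
        elif np.all(diffs < 0):
            verdict, note = "inverse", ""
        elif np.all(diffs > 0):
            verdict, note = "direct", ""
        else:
            verdict = "non-monotone"
            note = "zero difference between consecutive values" if np.any(diffs == 0) else ""
        out[param] = {
            "verdict": verdict,
            "note": note,
            "peak_T_C": [float(x) for x in ok["peak_T_C"]],
            "values": [float(x) for x in ok["value"]],
        }
    return out
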