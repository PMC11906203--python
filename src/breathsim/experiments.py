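"""Replication harness for the three bench test series.

* **Series 1** — airflow resistance alone: the open 300 mm x 5 mm tube,
  then the same tube behind orifices of 4.03, 3.25, 2.64, 1.93 and
  1.07 mm, with no gas storage.  Expected signature: work of breathing
  rises steeply as the orifice narrows while equilibrium lung CO2 stays
  flat (no storage, no rebreathing).
* **Series 2** — gas storage alone: the open tube surrounded by a growing
  polyfill ladder (0, 1, 2, 4, 8 layers).  Expected signature:
  equilibrium CO2 climbs with each layer while work barely moves.
* **Series 3** — the 3x3 combination grid: {open tube, 3.25 mm, 1.93 mm}
  x {2 layers, 4 layers, wrapped (8-layer equivalent)}.  Expected
  signature: the two effects superpose — CO2 follows the storage axis,
  work follows the resistance axis, and their combination is summative.

All three series run through one code path (:func:`run_conditions`);
series 1 and 2 are slices of the series-3 grid logic.  Each ``run_*``
function checks its qualitative trend assertions and raises
:class:`TrendViolation` naming the violated trend if the simulated
physics does not show the expected signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import (
    ORIFICE_DIAMETERS_MM,
    SeriesAirway,
    StorageCompartment,
    polyfill_preset,
)
from .engine import EquilibriumSummary, SimConfig, run_simulation, summarize

__all__ = [
    "SeriesResult",
    "TrendViolation",
    "run_conditions",
    "run_series_1",
    "run_series_2",
    "run_series_3",
    "write_series_report",
    "SERIES2_LAYER_LADDER",
    "SERIES3_RESISTANCES",
    "SERIES3_STORAGES",
]

#: Polyfill ladder for the storage-only series (layer counts).
SERIES2_LAYER_LADDER = (0, 1, 2, 4, 8)
#: Combination-grid axes: resistance conditions x storage conditions.
SERIES3_RESISTANCES = ("open", 3.25, 1.93)
SERIES3_STORAGES = ("2 layers", "4 layers", "wrapped")
_STORAGE_LAYERS = {"2 layers": 2, "4 layers": 4, "wrapped": 8}

REPORT_COLUMNS = (
    "resistance",
    "storage",
    "co2_volpct",
    "o2_volpct",
    "etco2_mmhg",
    "wob_j_per_min",
    "peak_neg_p_mbar",
    "breaths_to_eq",
    "converged",
)


class TrendViolation(AssertionError):
    """A simulated series does not show the expected qualitative trend."""


@dataclass
class SeriesResult:
    """Condition labels plus equilibrium metrics, one row per condition."""

    series: int
    table: pd.DataFrame  # columns REPORT_COLUMNS

    def row(self, resistance: str, storage: str) -> pd.Series:
        t = self.table
        hit = t[(t["resistance"] == resistance) & (t["storage"] == storage)]
        if len(hit) != 1:
            raise KeyError(f"no unique row for ({resistance!r}, {storage!r})")
        return hit.iloc[0]


def _airway_for(resistance: str | float) -> SeriesAirway:
    if resistance == "open":
        return SeriesAirway.open_tube()
    return SeriesAirway.tube_with_orifice(float(resistance))


def _resistance_label(resistance: str | float) -> str:
    return "open tube" if resistance == "open" else f"{float(resistance):.2f} mm orifice"


def run_conditions(
    conditions: list[tuple[str | float, StorageCompartment | None, str]],
    base_config: SimConfig | None = None,
) -> pd.DataFrame:
    """Run the engine for each (resistance, storage, storage-label) condition.

    The single harness behind all three series: a series is just a list
    of grid cells.
    """
    base = base_config or SimConfig()
    rows = []
    for resistance, storage, storage_label in conditions:
        cfg = SimConfig(
            lung=base.lung,
            airway=_airway_for(resistance),
            storage=storage,
            pattern=base.pattern,
            source=base.source,
            ambient=base.ambient,
            steps_per_breath=base.steps_per_breath,
            max_breaths=base.max_breaths,
            equilibrium_tol=base.equilibrium_tol,
            post_equilibrium_breaths=base.post_equilibrium_breaths,
            injection_mode=base.injection_mode,
        )
        summary: EquilibriumSummary = summarize(run_simulation(cfg))
        rows.append(
            {
                "resistance": _resistance_label(resistance),
                "storage": storage_label,
                "co2_volpct": summary.co2_volpct,
                "o2_volpct": summary.o2_volpct,
                "etco2_mmhg": summary.etco2_mmhg,
                "wob_j_per_min": summary.wob_j_per_min,
                "peak_neg_p_mbar": summary.peak_negative_pressure_mbar,
                "breaths_to_eq": summary.breaths_to_equilibrium,
                "converged": summary.converged,
            }
        )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def run_series_1(base_config: SimConfig | None = None, check: bool = True) -> SeriesResult:
    """Resistance ladder, no storage: open tube + the five orifices."""
    conditions = [("open", None, "none")] + [
        (d, None, "none") for d in ORIFICE_DIAMETERS_MM
    ]
    table = run_conditions(conditions, base_config)
    result = SeriesResult(series=1, table=table)
    if check:
        wob = table["wob_j_per_min"].to_numpy()
        if not np.all(np.diff(wob) > 0):
            raise TrendViolation(
                "series 1: work of breathing must increase strictly as the "
                f"orifice narrows; got {wob.tolist()}"
            )
        co2 = table["co2_volpct"].to_numpy()
        if co2.max() - co2.min() > 0.1:
            raise TrendViolation(
                "series 1: equilibrium CO2 must be flat (spread <= 0.1 vol%) "
                f"across resistances; got spread {co2.max() - co2.min():.4f} vol%"
            )
    return result


def run_series_2(base_config: SimConfig | None = None, check: bool = True) -> SeriesResult:
    """Storage ladder over the open tube: 0, 1, 2, 4, 8 polyfill layers."""
    conditions = [
        ("open", polyfill_preset(n), f"{n} layers") for n in SERIES2_LAYER_LADDER
    ]
    table = run_conditions(conditions, base_config)
    result = SeriesResult(series=2, table=table)
    if check:
        co2 = table["co2_volpct"].to_numpy()
        if not np.all(np.diff(co2) > 0):
            raise TrendViolation(
                "series 2: equilibrium CO2 must increase strictly with added "
                f"polyfill layers; got {co2.tolist()}"
            )
        wob = table["wob_j_per_min"].to_numpy()
        s1_range = _series1_wob_range(base_config)
        if wob.max() - wob.min() > 0.2 * s1_range:
            raise TrendViolation(
                "series 2: work must stay nearly flat (<= 20% of the series-1 "
                f"work range {s1_range:.4f} J/min); got span {wob.max() - wob.min():.4f}"
            )
    return result


def _series1_wob_range(base_config: SimConfig | None = None) -> float:
    table = run_series_1(base_config, check=False).table
    w = table["wob_j_per_min"]
    return float(w.max() - w.min())


def run_series_3(base_config: SimConfig | None = None, check: bool = True) -> SeriesResult:
    """The 3x3 combination grid of resistance x storage conditions."""
    conditions = [
        (r, polyfill_preset(_STORAGE_LAYERS[s]), s)
        for r in SERIES3_RESISTANCES
        for s in SERIES3_STORAGES
    ]
    table = run_conditions(conditions, base_config)
    result = SeriesResult(series=3, table=table)
    if check:
        grid_co2 = table["co2_volpct"].to_numpy().reshape(3, 3)
        grid_wob = table["wob_j_per_min"].to_numpy().reshape(3, 3)
        if not np.all(np.diff(grid_co2, axis=1) >= 0):
            raise TrendViolation(
                "series 3: CO2 must be non-decreasing along the storage axis "
                f"at fixed resistance; got grid {grid_co2.tolist()}"
            )
        if not np.all(np.diff(grid_wob, axis=0) >= 0):
            raise TrendViolation(
                "series 3: work must be non-decreasing along the resistance "
                f"axis at fixed storage; got grid {grid_wob.tolist()}"
            )
        # summative behavior: WOB(r, s) ~ WOB(r, s_min) + storage increment
        for i in range(3):
            for j in range(3):
                pred = grid_wob[i, 0] + (grid_wob[0, j] - grid_wob[0, 0])
                if abs(grid_wob[i, j] - pred) > 0.1 * max(abs(pred), 1e-12):
                    raise TrendViolation(
                        "series 3: combined work must be summative within 10%; "
                        f"cell ({i},{j}) has {grid_wob[i, j]:.5f} vs predicted {pred:.5f}"
                    )
    return result


def write_series_report(result: SeriesResult, path: str | Path) -> None:
    """Write the per-condition table as CSV (9 significant digits)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(path, index=False, float_format="%.9g")


def read_series_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in series report")
    return df
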