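"""Configuration parsing and CSV input/output.

The run configuration is a plain-text YAML document with nested sections
``lung``, ``airway``, ``storage``, ``pattern``, ``source`` and
``numerics``.  Every field is optional; omitted fields take the
infant-model defaults (44 breaths/min, 35 mL tidal volume between 30 and
65 mL, 0.7 mL/mbar compliance, open 300 mm x 5 mm tube, no storage,
calibrated CO2 metering).  Unknown keys and out-of-range values raise
:class:`ConfigError` naming the offending field.

Pressure-volume records and simulation traces are exchanged as
comma-separated text with a header row; numeric columns round-trip at 9
significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import (
    CompliantLung,
    OrificeElement,
    SeriesAirway,
    StorageCompartment,
    TubeElement,
    polyfill_preset,
)
from .engine import (
    RESULT_COLUMNS,
    BreathingPattern,
    MetabolicSource,
    SimConfig,
    SimResult,
)
from .wob import PVRecord

__all__ = [
    "ConfigError",
    "load_config",
    "parse_config",
    "read_pv_csv",
    "write_pv_csv",
    "write_result_csv",
    "read_result_csv",
]

#: Accepted header names for each PV channel (case-sensitive).
PV_COLUMN_ALIASES = {
    "t": ("t_s", "t", "time_s"),
    "p": ("p_mbar", "p", "pressure_mbar"),
    "v": ("V_mL", "V", "v_mL", "volume_mL"),
}

_SECTIONS = ("lung", "airway", "storage", "pattern", "source", "numerics")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def _check_keys(section: str, given: dict, allowed: tuple[str, ...]) -> None:
    unknown = sorted(set(given) - set(allowed))
    if unknown:
        raise ConfigError(
            f"unknown key(s) {unknown} in section '{section}'; allowed: {sorted(allowed)}"
        )


def _get(section: dict, key: str, default, caster=float):
    val = section.get(key, default)
    if val is None:
        return default
    try:
        return caster(val)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"field '{key}': cannot interpret {val!r}") from exc


def parse_config(doc: dict | None) -> SimConfig:
    """Build a validated :class:`SimConfig` from a parsed YAML mapping."""
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"top level must be a mapping, got {type(doc).__name__}")
    _check_keys("<top>", doc, _SECTIONS)

    lung_s = doc.get("lung") or {}
    _check_keys("lung", lung_s, ("compliance_ml_per_mbar", "v_min_ml", "v_max_ml"))
    try:
        lung = CompliantLung(
            compliance=_get(lung_s, "compliance_ml_per_mbar", 0.7),
            v_min=_get(lung_s, "v_min_ml", 30.0),
            v_max=_get(lung_s, "v_max_ml", 65.0),
        )
    except ValueError as exc:
        raise ConfigError(f"section 'lung': {exc}") from exc

    airway_s = doc.get("airway") or {}
    _check_keys(
        "airway",
        airway_s,
        ("tube_length_mm", "tube_inner_diameter_mm", "orifice_diameter_mm",
         "discharge_coefficient"),
    )
    try:
        tube = TubeElement(
            length_mm=_get(airway_s, "tube_length_mm", 300.0),
            inner_diameter_mm=_get(airway_s, "tube_inner_diameter_mm", 5.0),
        )
        elements: tuple = (tube,)
        d_orifice = airway_s.get("orifice_diameter_mm")
        if d_orifice is not None:
            elements += (
                OrificeElement(
                    diameter_mm=float(d_orifice),
                    discharge_coefficient=_get(airway_s, "discharge_coefficient", 0.6),
                ),
            )
        airway = SeriesAirway(elements)
    except ValueError as exc:
        raise ConfigError(f"section 'airway': {exc}") from exc

    storage_s = doc.get("storage") or {}
    _check_keys(
        "storage",
        storage_s,
        ("layers", "storage_volume_ml", "entrainment_fraction",
         "washout_retention", "intrinsic_resistance_mbar_s_per_ml"),
    )
    storage: StorageCompartment | None = None
    try:
        if "layers" in storage_s and storage_s["layers"] is not None:
            if any(k in storage_s for k in ("storage_volume_ml", "entrainment_fraction")):
                raise ConfigError(
                    "section 'storage': give either 'layers' (preset) or explicit "
                    "storage parameters, not both"
                )
            storage = polyfill_preset(float(storage_s["layers"]))
        elif storage_s:
            storage = StorageCompartment(
                storage_volume=_get(storage_s, "storage_volume_ml", 0.0),
                entrainment_fraction=_get(storage_s, "entrainment_fraction", 0.0),
                washout_retention=_get(storage_s, "washout_retention", 0.6),
                intrinsic_resistance=_get(
                    storage_s, "intrinsic_resistance_mbar_s_per_ml", 0.0
                ),
            )
            if storage.storage_volume == 0:
                storage = None
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"section 'storage': {exc}") from exc

    pattern_s = doc.get("pattern") or {}
    _check_keys(
        "pattern", pattern_s, ("rate_bpm", "tidal_volume_ml", "waveform", "rise_fraction")
    )
    try:
        pattern = BreathingPattern(
            rate=_get(pattern_s, "rate_bpm", 44.0),
            tidal_volume=_get(pattern_s, "tidal_volume_ml", lung.tidal_volume),
            waveform=_get(pattern_s, "waveform", "sinusoid", str),
            rise_fraction=_get(pattern_s, "rise_fraction", 0.7),
        )
    except ValueError as exc:
        raise ConfigError(f"section 'pattern': {exc}") from exc

    source_s = doc.get("source") or {}
    _check_keys(
        "source", source_s, ("co2_injection_ml_per_min", "o2_uptake_ml_per_min", "rq")
    )
    source: MetabolicSource | None = None
    if source_s:
        try:
            default = MetabolicSource.default_for(pattern, rq=_get(source_s, "rq", 0.8))
            source = MetabolicSource(
                co2_injection=_get(
                    source_s, "co2_injection_ml_per_min", default.co2_injection
                ),
                o2_uptake=_get(source_s, "o2_uptake_ml_per_min", default.o2_uptake),
            )
        except ValueError as exc:
            raise ConfigError(f"section 'source': {exc}") from exc

    numerics_s = doc.get("numerics") or {}
    _check_keys(
        "numerics",
        numerics_s,
        ("steps_per_breath", "max_breaths", "equilibrium_tol",
         "post_equilibrium_breaths", "injection_mode"),
    )
    try:
        return SimConfig(
            lung=lung,
            airway=airway,
            storage=storage,
            pattern=pattern,
            source=source,
            steps_per_breath=_get(numerics_s, "steps_per_breath", 256, int),
            max_breaths=_get(numerics_s, "max_breaths", 1000, int),
            equilibrium_tol=_get(numerics_s, "equilibrium_tol", 1e-4),
            post_equilibrium_breaths=_get(numerics_s, "post_equilibrium_breaths", 10, int),
            injection_mode=_get(numerics_s, "injection_mode", "continuous", str),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML run configuration (empty file -> defaults)."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return parse_config(doc)


def _resolve_pv_columns(columns) -> dict[str, str]:
    resolved = {}
    for channel, aliases in PV_COLUMN_ALIASES.items():
        found = [c for c in columns if c in aliases]
        if not found:
            raise ValueError(
                f"missing column for channel '{channel}'; accepted names: {list(aliases)}"
            )
        resolved[channel] = found[0]
    return resolved


def read_pv_csv(path: str | Path) -> PVRecord:
    """Read a pressure-volume record from CSV (header keyed, any column order)."""
    df = pd.read_csv(path)
    cols = _resolve_pv_columns(df.columns)
    rec = PVRecord(
        t=df[cols["t"]].to_numpy(float),
        p=df[cols["p"]].to_numpy(float),
        v=df[cols["v"]].to_numpy(float),
    )
    return rec


def write_pv_csv(rec: PVRecord, path: str | Path) -> None:
    """Write a record as CSV with columns t_s, p_mbar, V_mL."""
    df = pd.DataFrame({"t_s": rec.t, "p_mbar": rec.p, "V_mL": rec.v})
    df.to_csv(path, index=False, float_format="%.9g")


def write_result_csv(result: SimResult, path: str | Path) -> None:
    """Serialize a simulation trace with the canonical column set."""
    result.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_result_csv(path: str | Path) -> pd.DataFrame:
    """Read a simulation trace, checking the canonical column set."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"missing column(s) {missing}; expected exactly {list(RESULT_COLUMNS)}"
        )
    if not np.all(np.diff(df["t_s"].to_numpy()) > 0):
        raise ValueError("time column t_s must be strictly increasing")
    return df
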