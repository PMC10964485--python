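"""CSV readers/writers, run configuration and the structured run report.

File conventions: CSV (RFC-4180, UTF-8, header row), decimal point only,
column names carrying their unit as a suffix (``time_h``, ``eh_mV``,
``fe2_mg_L``, ``fe_total_mg_L``, ``cells_per_mL``, ``inlet_mg_L`` ...).
Configuration is a single YAML document with a fixed schema; unknown keys
are rejected. Numeric results go to files or standard output, logging to
standard error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .constants import DEFAULT_TEMPERATURE_K, MOLAR_MASS
from .nutrients import NutrientRecord
from .rates import BioreductionSeries, RateLaw, series_from_eh
from .speciation import RedoxCalibration

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_nutrient_table",
    "run_report",
    "load_config",
]

logger = logging.getLogger("ferrokin")

_CONFIG_KEYS = {
    "calibration": {"formal_potential_mV", "temperature_K"},
    "rate_law": {"slope", "intercept", "r2"},
    "reactor": {"volume_L", "hrt_h", "inflow_mL_h"},
    "nutrients": {"co2_uptake_mg_L_h"},
    "output": {"directory", "verbosity"},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated analysis configuration (speciation, reactor, rate law)."""

    calibration: RedoxCalibration = field(default_factory=RedoxCalibration)
    rate_law: RateLaw | None = None
    volume_L: float | None = None
    hrt_h: float | None = None
    inflow_mL_h: float | None = None
    co2_uptake_mg_L_h: float = 40.0
    output_directory: str = "."
    verbosity: int = 0
    seed: int = 0
    source_digest: str = ""


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known_top = set(_CONFIG_KEYS) | {"seed"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, keys in _CONFIG_KEYS.items():
        sub = raw.get(section, {})
        if not isinstance(sub, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(sub) - keys
        if bad:
            raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
    cal = raw.get("calibration", {})
    calibration = RedoxCalibration(
        formal_potential=float(cal.get("formal_potential_mV", 676.6)),
        temperature=float(cal.get("temperature_K", DEFAULT_TEMPERATURE_K)),
    )
    law = None
    if "rate_law" in raw:
        rl = raw["rate_law"]
        law = RateLaw(float(rl["slope"]), float(rl["intercept"]), float(rl.get("r2", 1.0)))
    reactor = raw.get("reactor", {})
    return RunConfig(
        calibration=calibration,
        rate_law=law,
        volume_L=reactor.get("volume_L"),
        hrt_h=reactor.get("hrt_h"),
        inflow_mL_h=reactor.get("inflow_mL_h"),
        co2_uptake_mg_L_h=float(raw.get("nutrients", {}).get("co2_uptake_mg_L_h", 40.0)),
        output_directory=raw.get("output", {}).get("directory", "."),
        verbosity=int(raw.get("output", {}).get("verbosity", 0)),
        seed=int(raw.get("seed", 0)),
        source_digest=hashlib.sha256(text.encode()).hexdigest()[:16],
    )


def _numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for c in cols:
        parsed = pd.to_numeric(df[c], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.index[parsed.isna()][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column {c!r} at line {row}")
        df[c] = parsed
    return df


def read_timeseries(path: str | Path,
                    calibration: RedoxCalibration | None = None) -> BioreductionSeries:
    """Read a monitoring CSV into a BioreductionSeries.

    Requires ``time_h`` plus either ``fe2_mg_L`` directly or the pair
    (``eh_mV``, ``fe_total_mg_L``), in which case Fe(II) is derived
    through the Nernst speciation (default pilot calibration unless one
    is supplied). Optional channel: ``cells_per_mL``.
    """
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_h'")
    has_fe2 = "fe2_mg_L" in df.columns
    has_eh = {"eh_mV", "fe_total_mg_L"}.issubset(df.columns)
    if not (has_fe2 or has_eh):
        raise ValueError(
            f"{path}: need column 'fe2_mg_L' or columns ('eh_mV', 'fe_total_mg_L')"
        )
    cols = [c for c in ("time_h", "fe2_mg_L", "eh_mV", "fe_total_mg_L", "cells_per_mL")
            if c in df.columns]
    df = _numeric(df, cols, path)
    t = df["time_h"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: time_h not strictly increasing at line {int(bad[0]) + 3}"
        )
    cells = df["cells_per_mL"].to_numpy() if "cells_per_mL" in df.columns else None
    if has_fe2:
        return BioreductionSeries(
            times=t,
            fe2=df["fe2_mg_L"].to_numpy(),
            eh=df["eh_mV"].to_numpy() if "eh_mV" in df.columns else None,
            fe_total=df["fe_total_mg_L"].to_numpy() if "fe_total_mg_L" in df.columns else None,
            cells=cells,
        )
    series = series_from_eh(t, df["eh_mV"].to_numpy(), df["fe_total_mg_L"].to_numpy(),
                            calibration or RedoxCalibration())
    if cells is not None:
        series = BioreductionSeries(series.times, series.fe2, series.eh,
                                    series.fe_total, cells)
    return series


def write_timeseries(series: BioreductionSeries, path: str | Path) -> None:
    """Write a series as CSV at 6 significant digits (read/write round-trips)."""
    data = {"time_h": series.times, "fe2_mg_L": series.fe2}
    if series.eh is not None:
        data["eh_mV"] = series.eh
    if series.fe_total is not None:
        data["fe_total_mg_L"] = series.fe_total
    if series.cells is not None:
        data["cells_per_mL"] = series.cells
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


def read_nutrient_table(path: str | Path) -> list[NutrientRecord]:
    """Read a nutrient CSV: species, inlet_mg_L, outlet_mg_L[, molar_mass].

    Molar masses omitted from the file are looked up in the package
    constants table. Negative concentrations are rejected.
    """
    df = pd.read_csv(path)
    required = {"species", "inlet_mg_L", "outlet_mg_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return []
    df = _numeric(df, [c for c in ("inlet_mg_L", "outlet_mg_L", "molar_mass")
                       if c in df.columns], path)
    records = []
    for _, row in df.iterrows():
        mm = row["molar_mass"] if "molar_mass" in df.columns else MOLAR_MASS[row["species"]]
        records.append(
            NutrientRecord(str(row["species"]), float(row["inlet_mg_L"]),
                           float(row["outlet_mg_L"]), float(mm))
        )
    return records


def run_report(results: dict[str, Any], config: RunConfig | None = None,
               path: str | Path | None = None) -> str:
    """Serialise computed quantities plus provenance to a canonical JSON document.

    Deterministic inputs give byte-identical output (sorted keys, fixed
    float formatting via JSON round-tripping of Python floats).
    """
    from . import __version__

    doc = {
        "results": results,
        "provenance": {
            "package": "ferrokin",
            "version": __version__,
            "config_digest": config.source_digest if config else "",
            "seed": config.seed if config else 0,
        },
    }

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    text = json.dumps(doc, indent=2, sort_keys=True, default=default) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
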