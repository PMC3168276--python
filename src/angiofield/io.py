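"""CSV/JSON writers with metadata headers, and their round-trip readers.

Data files are deterministic: identical configurations produce byte-identical
files (no timestamps; floats at 17 significant digits, enough to round-trip
IEEE doubles exactly).  Metadata rides in ``# key = <json>`` header lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .scenarios import RegimeMap, ScenarioResult

__all__ = [
    "write_profiles",
    "read_profiles",
    "profile_table",
    "write_run_record",
    "write_regime_map",
]

def _write_csv(path: Path, df: pd.DataFrame, metadata: Mapping) -> None:
    lines = [f"# {key} = {json.dumps(value)}" for key, value in metadata.items()]
    body = df.to_csv(index=False, float_format="%.17g", lineterminator="\n")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)


def profile_table(result: ScenarioResult) -> tuple[pd.DataFrame, dict]:
    """Radial profiles and metadata of a solved scenario.

    Columns: r_tilde, p_tilde, u_tilde, f_p_tilde, f_a_tilde, activity
    (activity is NaN outside the tumor, where the regime is not defined).
    """
    r = result.factors.r_grid
    pressure = result.pressure.on_grid(result.config.geometry)
    a = np.full_like(r, np.nan)
    a[: len(result.activity.a)] = result.activity.a
    df = pd.DataFrame(
        {
            "r_tilde": r,
            "p_tilde": pressure.p_tilde,
            "u_tilde": pressure.u_tilde,
            "f_p_tilde": result.factors.f_p,
            "f_a_tilde": result.factors.f_a,
            "activity": a,
        }
    )
    geom = result.config.geometry
    metadata = {
        "scenario": result.spec.name,
        "alpha_t": result.pressure.alpha_t,
        "alpha_h": result.pressure.alpha_h,
        "pe": result.config.pe,
        "R": geom.R,
        "r_max": geom.r_max,
        "n_grid": geom.n_grid,
        "regime": result.regime,
    }
    return df, metadata


def write_profiles(result: ScenarioResult, path: str | Path) -> Path:
    """Write the radial profiles of a scenario to one metadata-headed CSV."""
    path = Path(path)
    df, metadata = profile_table(result)
    _write_csv(path, df, metadata)
    return path


def read_profiles(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a profiles CSV back; arrays round-trip bit-exact."""
    path = Path(path)
    metadata = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            metadata[key.strip()] = json.loads(value)
            skip += 1
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    return df, metadata


def write_run_record(result: ScenarioResult, path: str | Path) -> Path:
    """Write the scenario's RunRecord (full parameter set + summary) as JSON."""
    path = Path(path)
    path.write_text(json.dumps(result.record(), indent=2, sort_keys=True) + "\n")
    return path


def write_regime_map(regime_map: RegimeMap, labels_path: str | Path, boundaries_path: str | Path | None = None) -> Path:
    """Write a production-plane regime map: labeled grid CSV (+ boundary CSV).

    The grid CSV has one row per (g̃_p^t, g̃_a^t) cell with its regime label;
    the boundary CSV lists midpoints between differently-labeled neighbors.
    """
    labels_path = Path(labels_path)
    gp, ga = np.meshgrid(regime_map.g_p_axis, regime_map.g_a_axis, indexing="ij")
    df = pd.DataFrame(
        {
            "g_p_tilde": gp.ravel(),
            "g_a_tilde": ga.ravel(),
            "regime": regime_map.labels.ravel(),
        }
    )
    metadata = {"alpha_t": regime_map.alpha_t, "alpha_h": regime_map.alpha_h}
    _write_csv(labels_path, df, metadata)
    if boundaries_path is not None:
        rows = [
            {"between": " | ".join(pair), "g_p_tilde": p, "g_a_tilde": a}
            for pair, pts in sorted(regime_map.boundaries.items())
            for p, a in pts
        ]
        _write_csv(Path(boundaries_path), pd.DataFrame(rows, columns=["between", "g_p_tilde", "g_a_tilde"]), metadata)
    return labels_path
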