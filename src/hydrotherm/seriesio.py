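"""Plain-text I/O: reaction-coordinate series files, result tables, config.

One series file per umbrella window: ``#``-prefixed header lines carrying
window/condition metadata, then two whitespace-delimited columns
``time_ps  distance_A``.  Values are printed with 17 significant digits so a
write/read round trip is exact.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .model import Condition, WindowSpec
from .sampling import ReactionCoordinateSeries
from .wham import PMFProfile

__all__ = [
    "read_series_file",
    "write_series_file",
    "series_filename",
    "write_pmf_table",
    "read_pmf_table",
    "write_features_table",
    "write_thermo_table",
    "load_config",
]

_REQUIRED_KEYS = ("d0_A", "k_kcal_mol_A2", "T_K", "IS_M")


def series_filename(window: WindowSpec, condition: Condition) -> str:
    """Canonical file name for one (window, condition) series."""
    label = window.label or f"d{window.d0:g}"
    return f"series_{label}_T{condition.T:g}_IS{condition.IS:g}.dat"


def write_series_file(series: ReactionCoordinateSeries, path: str) -> None:
    """Write a series to the two-column plain-text format."""
    with open(path, "w") as fh:
        fh.write("# hydrotherm reaction-coordinate series\n")
        fh.write(f"# label: {series.window.label}\n")
        fh.write(f"# d0_A: {series.window.d0:.17g}\n")
        fh.write(f"# k_kcal_mol_A2: {series.window.k:.17g}\n")
        fh.write(f"# T_K: {series.condition.T:.17g}\n")
        fh.write(f"# IS_M: {series.condition.IS:.17g}\n")
        fh.write(f"# seed: {series.seed}\n")
        fh.write("# columns: time_ps distance_A\n")
        for t, x in zip(series.times, series.xi):
            fh.write(f"{t:.17g} {x:.17g}\n")


def read_series_file(path: str) -> ReactionCoordinateSeries:
    """Read a series file, validating header metadata and data rows."""
    meta: Dict[str, str] = {}
    times: List[float] = []
    xi: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                times.append(float(parts[0]))
                xi.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric data row: {line!r}"
                ) from exc
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise ValueError(f"{path}: missing required header key {key!r}")
    window = WindowSpec(
        d0=float(meta["d0_A"]),
        k=float(meta["k_kcal_mol_A2"]),
        label=meta.get("label", ""),
    )
    condition = Condition(T=float(meta["T_K"]), IS=float(meta["IS_M"]))
    return ReactionCoordinateSeries(
        window=window,
        condition=condition,
        times=np.asarray(times),
        xi=np.asarray(xi),
        seed=int(meta.get("seed", 0)),
    )


def write_pmf_table(pmf: PMFProfile, path: str) -> None:
    """PMF profile as TSV: ``xi_A  F_kcal_mol  F_err_kcal_mol  n_counts``."""
    with open(path, "w") as fh:
        fh.write(f"# T_K: {pmf.condition.T:g}\n")
        fh.write(f"# IS_M: {pmf.condition.IS:g}\n")
        if pmf.baseline_range is not None:
            fh.write(
                f"# baseline_A: {pmf.baseline_range[0]:g} {pmf.baseline_range[1]:g}\n"
            )
        fh.write(f"# converged: {pmf.converged} ({pmf.n_iter} iterations)\n")
        fh.write("xi_A\tF_kcal_mol\tF_err_kcal_mol\tn_counts\n")
        err = pmf.F_err if pmf.F_err is not None else np.full_like(pmf.F, np.nan)
        for x, F, e, n in zip(pmf.bin_centers, pmf.F, err, pmf.total_counts):
            fh.write(f"{x:.4f}\t{F:.6f}\t{e:.6f}\t{int(n)}\n")


def read_pmf_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_features_table(rows: Sequence[dict], path: str) -> None:
    """Features TSV: one row per (T, IS), empty fields for absent features."""
    cols = [
        "T_K", "IS_M", "cm_pos", "cm_depth", "cm_depth_err",
        "dm_pos", "dm_height", "ssm_pos", "ssm_depth",
    ]
    df = pd.DataFrame(list(rows))
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="")


def write_thermo_table(rows: Sequence[dict], path: str) -> None:
    df = pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def load_config(path: str) -> dict:
    """Load a study configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
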