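"""Plain-CSV readers and writers for the three input types.

Every file starts with a ``#``-prefixed metadata block of ``key = value``
lines (units, experiment identifiers, seeds), followed by an ordinary CSV
table.  All concentrations are stored in the units named in the column
headers; ligand concentrations are converted to µM on read according to
the declared ``ligand_unit``.  Malformed files raise :class:`SchemaError`
naming the offending column or metadata key.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecaySeries
from .fluorescence import TitrationCurve
from .itc import ItcExperiment

__all__ = [
    "SchemaError",
    "read_metadata",
    "write_titration_csv",
    "read_titration_csv",
    "write_itc_csv",
    "read_itc_csv",
    "write_decay_csv",
    "read_decay_csv",
]

_LIGAND_UNIT_TO_UM = {"uM": 1.0, "µM": 1.0, "mM": 1e3, "M": 1e6}


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def read_metadata(path: str | Path) -> dict[str, str]:
    """Parse the leading ``# key = value`` block of a data file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _write(path: str | Path, meta: dict[str, object], df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False)


# --- titrations -------------------------------------------------------------

_TITRATION_COLS = ("curve_id", "protein_total_uM_trimer", "ligand_total", "signal")


def write_titration_csv(curves: list[TitrationCurve], path: str | Path, **extra_meta) -> None:
    rows = []
    for c in curves:
        for j in range(c.ligand_points.size):
            rows.append(
                {
                    "curve_id": c.curve_id,
                    "protein_total_uM_trimer": c.protein_total,
                    "ligand_total": c.ligand_points[j],
                    "signal": c.signal[j],
                    "signal_sd": c.signal_sd[j] if c.signal_sd is not None else "",
                }
            )
    meta = {"filetype": "titration", "ligand_unit": "uM", **extra_meta}
    _write(path, meta, pd.DataFrame(rows))


def read_titration_csv(path: str | Path) -> list[TitrationCurve]:
    meta = read_metadata(path)
    unit = meta.get("ligand_unit", "uM")
    if unit not in _LIGAND_UNIT_TO_UM:
        raise SchemaError(f"{path}: unknown ligand_unit {unit!r}")
    to_um = _LIGAND_UNIT_TO_UM[unit]
    df = pd.read_csv(path, comment="#")
    _require_columns(df, _TITRATION_COLS, path)
    curves = []
    for cid, grp in df.groupby("curve_id", sort=False):
        grp = grp.sort_values("ligand_total")
        sd = None
        if "signal_sd" in grp.columns and grp["signal_sd"].notna().all():
            sd = grp["signal_sd"].to_numpy(dtype=float)
        curves.append(
            TitrationCurve(
                curve_id=str(cid),
                protein_total=float(grp["protein_total_uM_trimer"].iloc[0]),
                ligand_points=grp["ligand_total"].to_numpy(dtype=float) * to_um,
                signal=grp["signal"].to_numpy(dtype=float),
                signal_sd=sd,
            )
        )
    return curves


# --- ITC --------------------------------------------------------------------

_ITC_COLS = ("injection_index", "volume_uL", "ndh_kcal_per_mol")
_ITC_META = ("experiment_id", "cell_volume_uL", "cell_conc0_uM_trimer", "syringe_conc_uM")


def write_itc_csv(exp: ItcExperiment, path: str | Path, **extra_meta) -> None:
    if exp.ndh is None:
        raise ValueError("cannot write an experiment without NDH values")
    meta = {
        "filetype": "itc",
        "experiment_id": exp.experiment_id,
        "cell_volume_uL": exp.cell_volume,
        "cell_conc0_uM_trimer": exp.cell_conc0,
        "syringe_conc_uM": exp.syringe_conc,
        "temperature_C": exp.temperature,
        **extra_meta,
    }
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, exp.n_injections + 1),
            "volume_uL": exp.injection_volumes,
            "ndh_kcal_per_mol": exp.ndh,
        }
    )
    _write(path, meta, df)


def read_itc_csv(path: str | Path) -> ItcExperiment:
    meta = read_metadata(path)
    missing = [k for k in _ITC_META if k not in meta]
    if missing:
        raise SchemaError(f"{path}: missing metadata key(s) {missing}")
    df = pd.read_csv(path, comment="#")
    _require_columns(df, _ITC_COLS, path)
    df = df.sort_values("injection_index")
    return ItcExperiment(
        experiment_id=meta["experiment_id"],
        cell_volume=float(meta["cell_volume_uL"]),
        cell_conc0=float(meta["cell_conc0_uM_trimer"]),
        syringe_conc=float(meta["syringe_conc_uM"]),
        injection_volumes=df["volume_uL"].to_numpy(dtype=float),
        ndh=df["ndh_kcal_per_mol"].to_numpy(dtype=float),
        temperature=float(meta.get("temperature_C", 25.0)),
    )


# --- decay ------------------------------------------------------------------

_DECAY_COLS = ("time_days", "activity_U_per_mg")


def write_decay_csv(series: DecaySeries, path: str | Path, **extra_meta) -> None:
    meta = {"filetype": "decay", **extra_meta}
    df = pd.DataFrame(
        {
            "time_days": series.t,
            "activity_U_per_mg": series.a,
            "sd_U_per_mg": series.sd if series.sd is not None else np.full(series.t.size, np.nan),
            "buffer": series.buffer,
            "substrate": series.substrate,
        }
    )
    _write(path, meta, df)


def read_decay_csv(path: str | Path) -> DecaySeries:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, _DECAY_COLS, path)
    sd = None
    if "sd_U_per_mg" in df.columns and df["sd_U_per_mg"].notna().all():
        sd = df["sd_U_per_mg"].to_numpy(dtype=float)
    return DecaySeries(
        t=df["time_days"].to_numpy(dtype=float),
        a=df["activity_U_per_mg"].to_numpy(dtype=float),
        sd=sd,
        buffer=str(df["buffer"].iloc[0]) if "buffer" in df.columns else "",
        substrate=str(df["substrate"].iloc[0]) if "substrate" in df.columns else "",
    )
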