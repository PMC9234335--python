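"""Delimited-text readers and writers for every input modality.

All unit conversion happens here, at the boundary: concentrations entered
in µmol/L become mol/L, volumes in µL become L, so the analysis cores work
in consistent SI (+ kJ/mol) units throughout.  Files are plain CSV with an
optional metadata block of ``# key = value`` lines before the header.

Schemas
-------
titration    quencher_conc_M (or quencher_conc_uM), intensity;
             metadata/column: temperature_K
thermogram   time_s, power_ucal_per_s   (+ a schedule CSV: time_s, volume_uL,
             and a JSON/YAML geometry file: cell_volume_uL,
             cell_conc_umol_per_L, syringe_conc_umol_per_L, temperature_K)
spectrum     wavenumber_cm1, absorbance
degradation  time_h, conc_ug_mL; any other column is a condition label and
             must be constant within the file
eem          excitation_nm, emission_nm, intensity (long format)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fluorescence import EEMSurface, TitrationSeries
from .ftir import FTIRSpectrum
from .itc import ITCThermogram
from .stability import DegradationSeries

SCHEMAS = ("titration", "thermogram", "spectrum", "degradation", "eem")


class SchemaError(ValueError):
    """A table does not match its declared schema (missing column,
    non-numeric cell, missing metadata)."""


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, value = line.lstrip("#").partition("=")
                meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return df, meta


def _require(df: pd.DataFrame, path, columns) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _numeric(df: pd.DataFrame, path, columns) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = converted
    return df


def read_table(path, schema: str, **kwargs):
    """Read and validate a delimited table into its domain object.

    ``schema`` selects the reader; see the module docstring for the column
    contracts.  Rows are sorted on read, so file row order never matters.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    return _READERS[schema](path, **kwargs)


def read_titration(path) -> TitrationSeries:
    df, meta = _read_csv(path)
    if "quencher_conc_M" in df.columns:
        conc_col, factor = "quencher_conc_M", 1.0
    elif "quencher_conc_uM" in df.columns:
        conc_col, factor = "quencher_conc_uM", 1e-6
    else:
        raise SchemaError(f"{path}: need a quencher_conc_M or quencher_conc_uM column")
    _require(df, path, [conc_col, "intensity"])
    df = _numeric(df, path, [conc_col, "intensity"])
    df = df.sort_values(conc_col, kind="stable")
    if "temperature_K" in df.columns:
        temperature = float(df["temperature_K"].iloc[0])
    elif "temperature_K" in meta:
        temperature = float(meta["temperature_K"])
    else:
        raise SchemaError(f"{path}: temperature_K missing from columns and metadata")
    return TitrationSeries(
        quencher_conc=df[conc_col].to_numpy() * factor,
        intensity=df["intensity"].to_numpy(),
        temperature=temperature,
    )


def read_thermogram(path, schedule_path, geometry_path) -> ITCThermogram:
    df, _ = _read_csv(path)
    _require(df, path, ["time_s", "power_ucal_per_s"])
    df = _numeric(df, path, ["time_s", "power_ucal_per_s"]).sort_values("time_s", kind="stable")

    sched, _ = _read_csv(schedule_path)
    _require(sched, schedule_path, ["time_s", "volume_uL"])
    sched = _numeric(sched, schedule_path, ["time_s", "volume_uL"]).sort_values(
        "time_s", kind="stable"
    )

    geometry_path = Path(geometry_path)
    with open(geometry_path) as fh:
        geo = json.load(fh) if geometry_path.suffix == ".json" else yaml.safe_load(fh)
    for key in ("cell_volume_uL", "cell_conc_umol_per_L", "syringe_conc_umol_per_L"):
        if key not in geo:
            raise SchemaError(f"{geometry_path}: missing geometry key {key!r}")

    return ITCThermogram(
        time=df["time_s"].to_numpy(),
        power=df["power_ucal_per_s"].to_numpy(),
        injections=tuple(
            (float(t), float(v) * 1e-6)
            for t, v in zip(sched["time_s"], sched["volume_uL"])
        ),
        cell_volume=float(geo["cell_volume_uL"]) * 1e-6,
        cell_conc=float(geo["cell_conc_umol_per_L"]) * 1e-6,
        syringe_conc=float(geo["syringe_conc_umol_per_L"]) * 1e-6,
        temperature=float(geo.get("temperature_K", 298.0)),
    )


def read_spectrum(path) -> FTIRSpectrum:
    df, _ = _read_csv(path)
    _require(df, path, ["wavenumber_cm1", "absorbance"])
    df = _numeric(df, path, ["wavenumber_cm1", "absorbance"]).sort_values(
        "wavenumber_cm1", kind="stable"
    )
    return FTIRSpectrum(
        wavenumber=df["wavenumber_cm1"].to_numpy(), absorbance=df["absorbance"].to_numpy()
    )


def read_degradation(path) -> DegradationSeries:
    df, meta = _read_csv(path)
    _require(df, path, ["time_h", "conc_ug_mL"])
    df = _numeric(df, path, ["time_h", "conc_ug_mL"]).sort_values("time_h", kind="stable")
    condition: dict[str, object] = dict(meta)
    for col in df.columns:
        if col in ("time_h", "conc_ug_mL"):
            continue
        values = df[col].unique()
        if len(values) != 1:
            raise SchemaError(f"{path}: condition column {col!r} is not constant")
        condition[col] = values[0]
    return DegradationSeries(
        time=df["time_h"].to_numpy(),
        concentration=df["conc_ug_mL"].to_numpy(),
        condition=condition,
    )


def read_eem(path) -> EEMSurface:
    df, _ = _read_csv(path)
    _require(df, path, ["excitation_nm", "emission_nm", "intensity"])
    df = _numeric(df, path, ["excitation_nm", "emission_nm", "intensity"])
    pivot = df.pivot_table(
        index="excitation_nm", columns="emission_nm", values="intensity", sort=True
    )
    if pivot.isna().any().any():
        raise SchemaError(f"{path}: EEM grid is incomplete (missing ex/em combinations)")
    return EEMSurface(
        excitation=pivot.index.to_numpy(dtype=float),
        emission=pivot.columns.to_numpy(dtype=float),
        intensity=pivot.to_numpy(dtype=float),
    )


_READERS = {
    "titration": read_titration,
    "thermogram": read_thermogram,
    "spectrum": read_spectrum,
    "degradation": read_degradation,
    "eem": read_eem,
}


# ---------------------------------------------------------------- writers

def write_titration(series: TitrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K = {series.temperature}\n")
        pd.DataFrame(
            {"quencher_conc_M": series.quencher_conc, "intensity": series.intensity}
        ).to_csv(fh, index=False)


def write_thermogram(thermogram: ITCThermogram, path, schedule_path, geometry_path) -> None:
    pd.DataFrame({"time_s": thermogram.time, "power_ucal_per_s": thermogram.power}).to_csv(
        path, index=False
    )
    pd.DataFrame(
        {
            "time_s": [t for t, _ in thermogram.injections],
            "volume_uL": [v * 1e6 for _, v in thermogram.injections],
        }
    ).to_csv(schedule_path, index=False)
    geo = {
        "cell_volume_uL": thermogram.cell_volume * 1e6,
        "cell_conc_umol_per_L": thermogram.cell_conc * 1e6,
        "syringe_conc_umol_per_L": thermogram.syringe_conc * 1e6,
        "temperature_K": thermogram.temperature,
    }
    with open(geometry_path, "w") as fh:
        json.dump(geo, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_spectrum(spectrum: FTIRSpectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumber, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def write_degradation(series: DegradationSeries, path) -> None:
    with open(path, "w") as fh:
        for key, value in series.condition.items():
            fh.write(f"# {key} = {value}\n")
        pd.DataFrame({"time_h": series.time, "conc_ug_mL": series.concentration}).to_csv(
            fh, index=False
        )


def write_eem(surface: EEMSurface, path) -> None:
    ex, em = np.meshgrid(surface.excitation, surface.emission, indexing="ij")
    pd.DataFrame(
        {
            "excitation_nm": ex.ravel(),
            "emission_nm": em.ravel(),
            "intensity": surface.intensity.ravel(),
        }
    ).to_csv(path, index=False)
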