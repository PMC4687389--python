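"""Plain-text I/O: INI-style configs and delimited profile/field tables.

All tabular exchange is comma-separated text with a header row; configs are
flat key/value files with ``[section]`` headers (``[zone.<name>]`` blocks
describe tissue layers, positions in millimetres at the file boundary, SI
metres internally).
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import HUCalibration, ScanCalibration
from .domain import ConcentrationField, SolverConfig, TissueZone, ZonedDomain
from .profiles import LineProfile, effective_day

__all__ = [
    "FormatError",
    "read_domain_config",
    "write_domain_config",
    "read_hu_config",
    "read_scan_calibrations",
    "read_profile_file",
    "write_profiles",
    "read_field",
    "write_field",
    "data_path",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


def data_path(name: str) -> Path:
    """Path of a bundled data file (reference configs and tables)."""
    return Path(__file__).parent / "data" / name


# -- configs ----------------------------------------------------------------


def read_domain_config(path) -> tuple[ZonedDomain, SolverConfig | None]:
    """Domain (and optional solver section) from an INI config.

    Zone blocks are ``[zone.<name>]`` with keys ``start_mm``, ``end_mm``,
    ``porosity``, ``bulk_density_kg_L``, ``partition_coeff_L_kg``; the
    ``[domain]`` section carries ``length_mm``, ``diffusion_coeff_m2_s``,
    ``boundary_flux``, ``initial_concentration_mmol_L`` and optionally
    ``bath_concentration_mmol_L``.
    """
    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read:
        raise FormatError(f"config file not found or unreadable: {path}")
    if "domain" not in cp:
        raise FormatError(f"{path}: missing [domain] section")
    dom = cp["domain"]
    zones = []
    for section in cp.sections():
        if not section.startswith("zone."):
            continue
        z = cp[section]
        try:
            zones.append(
                TissueZone(
                    name=section.split(".", 1)[1],
                    x_start=z.getfloat("start_mm") / 1000.0,
                    x_end=z.getfloat("end_mm") / 1000.0,
                    porosity=z.getfloat("porosity"),
                    bulk_density=z.getfloat("bulk_density_kg_L"),
                    partition_coeff=z.getfloat("partition_coeff_L_kg"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} [{section}]: {exc}") from exc
    zones.sort(key=lambda z: z.x_start)
    try:
        domain = ZonedDomain(
            zones=tuple(zones),
            length=dom.getfloat("length_mm") / 1000.0,
            diffusion_coeff=dom.getfloat("diffusion_coeff_m2_s"),
            boundary_flux=dom.getfloat("boundary_flux"),
            initial_concentration=dom.getfloat("initial_concentration_mmol_L", 0.0),
            bath_concentration=dom.getfloat("bath_concentration_mmol_L", fallback=None),
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path} [domain]: {exc}") from exc
    solver = None
    if "solver" in cp:
        s = cp["solver"]
        solver = SolverConfig(
            n_cells=s.getint("n_cells", 600),
            time_step=s.getfloat("time_step_s", 60.0),
            tolerance=s.getfloat("tolerance", 1e-8),
            flux_convention=s.get("flux_convention", "total"),
        )
    return domain, solver


def write_domain_config(domain: ZonedDomain, path, solver: SolverConfig | None = None) -> None:
    cp = configparser.ConfigParser()
    cp["domain"] = {
        "length_mm": repr(domain.length * 1000.0),
        "diffusion_coeff_m2_s": repr(domain.diffusion_coeff),
        "boundary_flux": repr(domain.boundary_flux),
        "initial_concentration_mmol_L": repr(domain.initial_concentration),
    }
    if domain.bath_concentration is not None:
        cp["domain"]["bath_concentration_mmol_L"] = repr(domain.bath_concentration)
    for z in domain.zones:
        cp[f"zone.{z.name}"] = {
            "start_mm": repr(z.x_start * 1000.0),
            "end_mm": repr(z.x_end * 1000.0),
            "porosity": repr(z.porosity),
            "bulk_density_kg_L": repr(z.bulk_density),
            "partition_coeff_L_kg": repr(z.partition_coeff),
        }
    if solver is not None:
        cp["solver"] = {
            "n_cells": str(solver.n_cells),
            "time_step_s": repr(solver.time_step),
            "tolerance": repr(solver.tolerance),
            "flux_convention": solver.flux_convention,
        }
    with open(path, "w") as fh:
        cp.write(fh)


def read_hu_config(path) -> HUCalibration:
    """HU calibration from an INI file with a single ``[hu]`` section."""
    cp = configparser.ConfigParser()
    if not cp.read(str(path)):
        raise FormatError(f"config file not found or unreadable: {path}")
    if "hu" not in cp:
        raise FormatError(f"{path}: missing [hu] section")
    h = cp["hu"]
    return HUCalibration(
        gs_air=h.getfloat("gs_air"),
        gs_water=h.getfloat("gs_water"),
        k_factor=h.getfloat("k_factor", 4.6),
        baseline_offset=h.getfloat("baseline_offset_mmol_L", 150.0),
        infiltration_offset=h.getfloat("infiltration_offset_mmol_L", 50.0),
    )


def read_scan_calibrations(path) -> dict[str, ScanCalibration]:
    """Per-scan reference statistics from a CSV with columns scan_id,
    raw_air, raw_reference, raw_range, target_air, target_range."""
    df = pd.read_csv(path)
    required = {"scan_id", "raw_air", "raw_reference", "raw_range", "target_air", "target_range"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return {
        str(r.scan_id): ScanCalibration(
            str(r.scan_id),
            float(r.raw_air),
            float(r.raw_reference),
            float(r.raw_range),
            float(r.target_air),
            float(r.target_range),
        )
        for r in df.itertuples()
    }


# -- profiles ----------------------------------------------------------------


def read_profile_file(path) -> list[LineProfile]:
    """Parse line profiles from delimited text, grouped by scan_id.

    Required columns: ``scan_id``, ``actual_day``, ``grayscale`` and a
    position column named ``position_m`` (metres) or ``position_mm``
    (millimetres, converted on read).  An ``effective_day`` column is
    honoured if present, otherwise computed from the default replacement
    schedule.  Optional ``hu``/``conc_mmol_per_L`` columns are carried along.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    if "position_m" in df.columns:
        pos = df["position_m"].to_numpy(dtype=float)
    elif "position_mm" in df.columns:
        pos = df["position_mm"].to_numpy(dtype=float) / 1000.0
    else:
        raise FormatError(f"{path}: need a position_m or position_mm column")
    for col in ("scan_id", "actual_day", "grayscale"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df[["actual_day", "grayscale"]].isna().any().any() or np.isnan(pos).any():
        bad = int(df.index[df[["actual_day", "grayscale"]].isna().any(axis=1)].min())
        raise FormatError(f"{path}: malformed number near data row {bad + 1}")
    df = df.assign(_pos=pos)
    profiles = []
    for sid, grp in df.groupby("scan_id", sort=False):
        p = grp["_pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            row = int(grp.index[1:][np.diff(p) <= 0][0])
            raise FormatError(
                f"{path}: positions for scan {sid!r} not strictly increasing at data row {row + 1}"
            )
        actual = float(grp["actual_day"].iloc[0])
        eff = (
            float(grp["effective_day"].iloc[0])
            if "effective_day" in grp.columns
            else effective_day(actual)
        )
        profiles.append(
            LineProfile(
                scan_id=str(sid),
                actual_day=actual,
                effective_day=eff,
                positions=p,
                grayscale=grp["grayscale"].to_numpy(dtype=float),
                hu=grp["hu"].to_numpy(dtype=float) if "hu" in grp.columns else None,
                conc=(
                    grp["conc_mmol_per_L"].to_numpy(dtype=float)
                    if "conc_mmol_per_L" in grp.columns
                    else None
                ),
            )
        )
    return profiles


def write_profiles(profiles, path) -> None:
    """Write profiles in the long CSV format read by :func:`read_profile_file`."""
    frames = []
    for p in profiles:
        df = p.to_frame()
        df.insert(2, "effective_day", p.effective_day)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# -- concentration fields -----------------------------------------------------


def write_field(field: ConcentrationField, path) -> None:
    field.to_frame().to_csv(path, index=False)


def read_field(path) -> ConcentrationField:
    df = pd.read_csv(path)
    required = {"time_s", "position_m", "pore_mmol_per_L", "total_mmol_per_L"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    times = np.unique(df["time_s"].to_numpy())
    positions = np.unique(df["position_m"].to_numpy())
    pore = np.full((len(times), len(positions)), np.nan)
    total = np.full_like(pore, np.nan)
    ti = np.searchsorted(times, df["time_s"].to_numpy())
    xi = np.searchsorted(positions, df["position_m"].to_numpy())
    pore[ti, xi] = df["pore_mmol_per_L"].to_numpy()
    total[ti, xi] = df["total_mmol_per_L"].to_numpy()
    if np.isnan(pore).any():
        raise FormatError(f"{path}: field grid is not complete (missing time/position pairs)")
    return ConcentrationField(positions=positions, times=times, pore_conc=pore, total_conc=total)
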