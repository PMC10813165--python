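"""Readers and writers: waveform container, manifest, measure tables, config.

The waveform container is a directory of delimited-text files (two
columns: time_s, voltage_uV — one file per record) plus a
``manifest.csv`` naming each file's subject, genotype, treatment,
timepoint, eye, flash energy and sampling rate.  All writers order rows
deterministically and format floats with 6 significant digits so that
repeated runs are diffable.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ERGWaveform, GENOTYPES, TREATMENTS
from .stats import MEASURE_COLUMNS
from .synthetic import CohortDesign, OCTCohortDesign, OCTLayerSpec, WaveformModelParams
from .decompose import P3Params

__all__ = [
    "MANIFEST_COLUMNS",
    "write_waveforms",
    "read_waveforms",
    "write_measure_table",
    "read_measure_table",
    "write_decomposition_table",
    "load_config",
    "designs_from_config",
    "write_run_log",
]

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("file", "subject", "genotype", "treatment", "time_min", "eye", "flash_log", "fs_hz")
_FLOAT_FMT = "%.6g"


def write_waveforms(directory, waveforms: Iterable[ERGWaveform]) -> Path:
    """Write records and manifest into ``directory``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(
        sorted(waveforms, key=lambda w: (str(w.meta.get("subject", "")), float(w.meta.get("time_min", 0))))
    ):
        name = f"rec_{i:04d}.csv"
        arr = np.column_stack([w.time_s, w.samples_uV])
        np.savetxt(
            directory / name,
            arr,
            delimiter=",",
            header="time_s,voltage_uV",
            comments="",
            fmt=_FLOAT_FMT,
        )
        rows.append(
            {
                "file": name,
                "subject": w.meta.get("subject", f"S{i:04d}"),
                "genotype": w.meta.get("genotype", "WT"),
                "treatment": w.meta.get("treatment", "VEH"),
                "time_min": w.meta.get("time_min", 0),
                "eye": w.meta.get("eye", "OD"),
                "flash_log": w.flash_energy_log,
                "fs_hz": w.fs_hz,
            }
        )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    path = directory / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def _validate_manifest_row(row, line_no: int, directory: Path) -> None:
    if row["genotype"] not in GENOTYPES:
        raise ValueError(f"manifest line {line_no}: unknown genotype {row['genotype']!r}")
    if row["treatment"] not in TREATMENTS:
        raise ValueError(f"manifest line {line_no}: unknown treatment {row['treatment']!r}")
    if not (directory / str(row["file"])).exists():
        raise FileNotFoundError(f"manifest line {line_no}: missing file {row['file']!r}")
    if not np.isfinite(row["fs_hz"]) or row["fs_hz"] <= 0:
        raise ValueError(f"manifest line {line_no}: invalid fs_hz {row['fs_hz']!r}")


def read_waveforms(manifest_path) -> list[ERGWaveform]:
    """Load every record listed in a manifest; validates vocabulary and grids."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    key = manifest[["subject", "time_min", "eye"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError(f"duplicate (subject, time_min, eye) rows: {key[key.duplicated()].tolist()}")
    out = []
    for i, row in manifest.iterrows():
        line_no = i + 2  # header is line 1
        _validate_manifest_row(row, line_no, directory)
        data = pd.read_csv(directory / row["file"])
        if list(data.columns) != ["time_s", "voltage_uV"]:
            raise ValueError(f"manifest line {line_no}: {row['file']} has unexpected columns")
        t = data["time_s"].to_numpy(float)
        v = data["voltage_uV"].to_numpy(float)
        dt = np.diff(t)
        if not np.allclose(dt, 1.0 / row["fs_hz"], rtol=1e-3):
            raise ValueError(
                f"manifest line {line_no}: sample spacing of {row['file']} does not match fs_hz"
            )
        out.append(
            ERGWaveform(
                samples_uV=v,
                fs_hz=float(row["fs_hz"]),
                t0_s=float(t[0]),
                flash_energy_log=float(row["flash_log"]),
                meta={
                    "subject": row["subject"],
                    "genotype": row["genotype"],
                    "treatment": row["treatment"],
                    "time_min": float(row["time_min"]),
                    "eye": row["eye"],
                },
            )
        )
    return out


def write_measure_table(path, table: pd.DataFrame) -> Path:
    """Schema-validated, deterministically ordered CSV of a measure table."""
    missing = set(MEASURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measure table missing columns {sorted(missing)}")
    bad_g = set(table["genotype"]) - set(GENOTYPES)
    bad_t = set(table["treatment"]) - set(TREATMENTS)
    if bad_g or bad_t:
        raise ValueError(f"unknown genotype/treatment tokens: {sorted(bad_g | bad_t)}")
    out = table[list(MEASURE_COLUMNS)].sort_values(
        ["measure", "genotype", "treatment", "subject_id", "time_min"], kind="mergesort"
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_measure_table(path) -> pd.DataFrame:
    """Read and validate a measure-table CSV ('.'-decimal, exponent notation ok)."""
    t = pd.read_csv(path)
    missing = set(MEASURE_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"measure table missing columns {sorted(missing)}")
    bad = set(t["genotype"]) - set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotype tokens {sorted(bad)}")
    bad = set(t["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment tokens {sorted(bad)}")
    t["time_min"] = t["time_min"].astype(float)
    t["value"] = t["value"].astype(float)
    return t


def write_decomposition_table(path, table: pd.DataFrame) -> Path:
    """Per-record decomposition results as deterministic CSV."""
    out = table.sort_values(["subject_id", "time_min"], kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# Config


def load_config(path) -> dict:
    """Load a YAML run configuration; the seed key is mandatory."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise KeyError("config is missing required key 'seed'")
    return cfg


def designs_from_config(cfg: dict):
    """Build (CohortDesign, WaveformModelParams, OCTCohortDesign) from a config dict."""
    seed = int(cfg["seed"])
    ckw = dict(cfg.get("cohort", {}))
    ckw.setdefault("seed", seed)
    design = CohortDesign(**ckw)
    wkw = dict(cfg.get("waveform", {}))
    if "p3" in wkw:
        wkw["p3"] = P3Params(**wkw["p3"])
    if "op_atoms" in wkw:
        wkw["op_atoms"] = tuple(tuple(a) for a in wkw["op_atoms"])
    params = WaveformModelParams(**wkw)
    okw = dict(cfg.get("oct", {}))
    if "layers" in okw:
        okw["layers"] = {k: OCTLayerSpec(**v) for k, v in okw["layers"].items()}
    okw.setdefault("seed", seed)
    okw.setdefault("n_per_group", dict(design.n_per_group))
    oct_design = OCTCohortDesign(**okw)
    return design, params, oct_design


def write_run_log(path, seed: int, config: dict | None = None, extra: dict | None = None) -> Path:
    """JSON run log with seed, package/runtime versions and parameters."""
    from . import __version__

    payload = {
        "seed": seed,
        "retscreen_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config or {},
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    log.info("run log written to %s", path)
    return path
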