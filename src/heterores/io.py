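"""CSV schemas and readers/writers.

All tabular I/O is plain, UTF-8, decimal-point CSV.  Lines starting with
``#`` are metadata comments; writers prepend the package version and the
resolved run configuration as such comments so every output records how it
was produced (no timestamps — outputs are byte-reproducible for a fixed
seed).  Unknown columns are preserved on read but ignored.

Schemas
-------
inoculum observations : strain_id, replicate_id, inoculum_cells, mic_exp_mM
dose-response         : strain_id, replicate_id, concentration_mM,
                        percent_survival  (or cfu + cfu_control)
panel                 : strain_id, species, heteroresistance, ic50_mM,
                        mic_model_mM
fit results           : flat rows from ResistanceFitResults.to_row()
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import CsvParseError, SchemaError
from .models import DoseResponseObservation, InoculumMicObservation
from .panel import StrainRecord, records_to_frame

__all__ = [
    "read_inoculum_csv",
    "write_inoculum_csv",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "read_panel_csv",
    "write_panel_csv",
    "write_fit_results_csv",
    "write_report_csv",
]


def _read(path, required, numeric):
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except FileNotFoundError:
        raise
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CsvParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise CsvParseError(
                f"{path}: empty value in column {col!r}, data row {row + 1}"
            )
        df[col] = vals
    return df


def _write(df, path, metadata=None):
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# heterores {__version__}\n")
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_inoculum_csv(path):
    """Read inoculum-effect MIC observations."""
    df = _read(
        path,
        required=["strain_id", "replicate_id", "inoculum_cells", "mic_exp_mM"],
        numeric=["inoculum_cells", "mic_exp_mM"],
    )
    return [
        InoculumMicObservation(
            strain_id=str(r.strain_id),
            replicate_id=str(r.replicate_id),
            inoculum_cells=float(r.inoculum_cells),
            mic_exp_mM=float(r.mic_exp_mM),
        )
        for r in df.itertuples()
    ]


def write_inoculum_csv(observations, path, metadata=None):
    df = pd.DataFrame(
        [
            {
                "strain_id": o.strain_id,
                "replicate_id": o.replicate_id,
                "inoculum_cells": o.inoculum_cells,
                "mic_exp_mM": o.mic_exp_mM,
                "censored": o.censored,
            }
            for o in observations
        ]
    )
    _write(df, path, metadata)


def read_dose_response_csv(path):
    """Read dose-response observations.

    Accepts either a ``percent_survival`` column, or raw ``cfu`` and
    ``cfu_control`` counts from which percent survival is computed.
    """
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#") and line.strip():
                header = [c.strip() for c in line.split(",")]
                break
    if header is not None and "percent_survival" not in header and "cfu" in header:
        df = _read(
            path,
            required=["strain_id", "replicate_id", "concentration_mM", "cfu", "cfu_control"],
            numeric=["concentration_mM", "cfu", "cfu_control"],
        )
        df["percent_survival"] = 100.0 * df["cfu"] / df["cfu_control"]
    else:
        df = _read(
            path,
            required=["strain_id", "replicate_id", "concentration_mM", "percent_survival"],
            numeric=["concentration_mM", "percent_survival"],
        )
    return [
        DoseResponseObservation(
            strain_id=str(r.strain_id),
            replicate_id=str(r.replicate_id),
            concentration_mM=float(r.concentration_mM),
            percent_survival=float(r.percent_survival),
        )
        for r in df.itertuples()
    ]


def write_dose_response_csv(observations, path, metadata=None):
    df = pd.DataFrame(
        [
            {
                "strain_id": o.strain_id,
                "replicate_id": o.replicate_id,
                "concentration_mM": o.concentration_mM,
                "percent_survival": o.percent_survival,
            }
            for o in observations
        ]
    )
    _write(df, path, metadata)


def read_panel_csv(path):
    """Read a per-strain panel table into StrainRecord objects."""
    df = _read(
        path,
        required=["strain_id", "species", "heteroresistance", "ic50_mM", "mic_model_mM"],
        numeric=["heteroresistance", "ic50_mM", "mic_model_mM"],
    )
    return [
        StrainRecord(
            strain_id=str(r.strain_id),
            species=str(r.species),
            heteroresistance=float(r.heteroresistance),
            ic50_mM=float(r.ic50_mM),
            mic_model_mM=float(r.mic_model_mM),
        )
        for r in df.itertuples()
    ]


def write_panel_csv(records, path, metadata=None):
    _write(records_to_frame(records), path, metadata)


def write_fit_results_csv(rows, path, metadata=None):
    """Write fit-result rows (dicts from ``to_row()``) as a flat CSV."""
    _write(pd.DataFrame(list(rows)), path, metadata)


def write_report_csv(report, path_prefix, metadata=None):
    """Write the four PanelReport tables as ``<prefix>_<table>.csv``."""
    prefix = Path(path_prefix)
    for name in ("correlations", "group_summary", "welch_tests", "ranges"):
        _write(getattr(report, name), f"{prefix}_{name}.csv", metadata)
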