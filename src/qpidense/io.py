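"""File formats: float OPD TIFFs, CSV observation tables, and the deposited
multi-tab Excel workbooks (one tab per published sub-figure).

OPD images travel as 32-bit-float TIFF in nm; tables as CSV with fixed column
names. Chamber OPD is signed: negative while the interior is optically rarer
than PDMS.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_opd_tiff",
    "write_opd_tiff",
    "read_table",
    "write_table",
    "read_zenodo_tabs",
    "OBSERVATION_COLUMNS",
]

OBSERVATION_COLUMNS = ["gip_mpa", "mean_opd_vs_pdms_nm", "ri", "density_mg_ml", "underestimated"]


def write_opd_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write an OPD image (nm) as single- or multi-page 32-bit-float TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_opd_tiff(path: str | Path) -> np.ndarray:
    """Read an OPD image (nm) written by :func:`write_opd_tiff`, bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such OPD image: {path}")
    data = tifffile.imread(str(path))
    return np.asarray(data)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_table(path: str | Path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking for required columns by name."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough with context
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in table.columns]
        if missing:
            raise ValueError(f"table {path} is missing required columns: {missing}")
    return table


def read_zenodo_tabs(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a deposited multi-tab Excel workbook into {tab name: DataFrame}.

    Each tab corresponds to one published sub-figure; the caller selects tabs
    by name. The function accepts a local path only — no DOI resolution.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such workbook: {path}")
    try:
        tabs = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    except Exception as exc:
        raise ValueError(f"could not parse workbook {path}: {exc}") from exc
    if not tabs:
        raise ValueError(f"workbook {path} has no sheets")
    return tabs
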