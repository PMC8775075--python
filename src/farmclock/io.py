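"""Delimited-text readers/writers for beta matrices, sample sheets and QC output.

All on-disk formats are plain CSV: a beta matrix has probe ids as the
header row and sample_id as the first column, with masked entries written
as empty fields; a sample sheet has the required columns sample_id,
species, sex, age_days, batch.  Intensity input is a pair of parallel
matrices (methylated / unmethylated) with identical shape and headers,
from which beta values are computed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .preprocess import SAMPLE_SHEET_COLUMNS, MethylationDataset, QCReport, compute_beta

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_dataset",
    "write_dataset",
    "read_intensity_pair",
    "read_detection_p",
    "write_qc_report",
]

PathLike = Union[str, Path]


def read_beta_matrix(path: PathLike) -> pd.DataFrame:
    """Read a samples x probes beta matrix; empty/NA fields become NaN."""
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = "sample_id"
    return frame.astype(float)

def write_beta_matrix(beta: pd.DataFrame, path: PathLike) -> None:
    beta.to_csv(path, index_label="sample_id")


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """Read a sample sheet CSV, indexed by sample_id."""
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing required columns: {missing}")
    sheet = sheet.set_index("sample_id")
    sheet["age_days"] = sheet["age_days"].astype(float)
    return sheet

def write_sample_sheet(samples: pd.DataFrame, path: PathLike) -> None:
    samples.to_csv(path, index_label="sample_id")


def read_dataset(beta_path: PathLike, sheet_path: PathLike) -> MethylationDataset:
    """Assemble a dataset from a beta matrix and sample sheet on disk.

    The sheet is reordered to the matrix's sample order; samples present in
    only one of the two files raise.
    """
    beta = read_beta_matrix(beta_path)
    sheet = read_sample_sheet(sheet_path)
    if set(beta.index) != set(sheet.index):
        raise ValueError("beta matrix and sample sheet list different sample ids")
    return MethylationDataset(beta, sheet.loc[beta.index])

def write_dataset(dataset: MethylationDataset, beta_path: PathLike, sheet_path: PathLike) -> None:
    write_beta_matrix(dataset.beta, beta_path)
    write_sample_sheet(dataset.samples, sheet_path)


def read_intensity_pair(
    methylated_path: PathLike,
    unmethylated_path: PathLike,
    offset: float = 100.0,
) -> pd.DataFrame:
    """Compute a beta matrix from parallel M / U intensity matrices."""
    m = pd.read_csv(methylated_path, index_col=0)
    u = pd.read_csv(unmethylated_path, index_col=0)
    if m.shape != u.shape or not m.columns.equals(u.columns) or not m.index.equals(u.index):
        raise ValueError("methylated and unmethylated matrices must have identical layout")
    beta = pd.DataFrame(
        compute_beta(m.to_numpy(dtype=float), u.to_numpy(dtype=float), offset=offset),
        index=m.index.astype(str),
        columns=m.columns,
    )
    beta.index.name = "sample_id"
    return beta


def read_detection_p(path: PathLike) -> pd.DataFrame:
    """Read a detection p-value matrix laid out like a beta matrix."""
    frame = pd.read_csv(path, index_col=0).astype(float)
    frame.index = frame.index.astype(str)
    return frame


def write_qc_report(report: QCReport, path: PathLike) -> None:
    report.to_frame().to_csv(path)
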