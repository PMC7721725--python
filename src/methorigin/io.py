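"""Delimited-text, Newick and BED input/output with validation.

Matrices and sheets travel as TSV/CSV (delimiter auto-detected from the
header line, overridable); trees as Newick via scikit-bio; copy-number
bins/segments as BED. Internal coordinates are 1-based inclusive; only
BED export converts to 0-based half-open intervals.
"""

from __future__ import annotations

import configparser
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (
    BetaMatrix,
    IntensityMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _sniff_delimiter(path: PathLike, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_beta_matrix(
    path: PathLike, strict: bool = False, delimiter: Optional[str] = None
) -> BetaMatrix:
    """Read a probes x samples beta matrix from delimited text.

    First column holds probe ids, header row sample ids. Out-of-range
    values raise in ``strict`` mode and are set missing (with a logged
    warning) otherwise. Duplicate ids are always a hard error.
    """
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not strict:
        df = df.apply(pd.to_numeric, errors="coerce")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric beta value in {path}: {exc}") from exc
    arr = df.to_numpy()
    with np.errstate(invalid="ignore"):
        out_of_range = (arr < 0) | (arr > 1)
    n_bad = int(np.nansum(out_of_range))
    if n_bad:
        if strict:
            raise ValidationError(f"{n_bad} beta value(s) outside [0, 1] in {path}")
        logger.warning("%d beta value(s) outside [0, 1] set to missing", n_bad)
        arr = arr.copy()
        arr[np.asarray(out_of_range, dtype=bool)] = np.nan
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: PathLike, delimiter: str = "\t") -> Path:
    path = Path(path)
    beta.values.to_csv(path, sep=delimiter, index_label="probe_id", float_format="%.6g")
    return path


def read_annotation(path: PathLike, delimiter: Optional[str] = None) -> ProbeAnnotation:
    """Read a probe annotation table; "chr" prefixes are normalized away."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    missing = [c for c in ProbeAnnotation.REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation misses mandatory column(s): {missing}")
    return ProbeAnnotation(df)


def write_annotation(ann: ProbeAnnotation, path: PathLike, delimiter: str = "\t") -> Path:
    path = Path(path)
    ann.table.to_csv(path, sep=delimiter, index_label="probe_id")
    return path


def read_sample_sheet(path: PathLike, delimiter: Optional[str] = None) -> SampleSheet:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, keep_default_na=False, na_values=[""])
    df.index = df.index.astype(str)
    if "role" not in df.columns:
        raise ValidationError("sample sheet misses mandatory column(s): ['role']")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: PathLike, delimiter: str = ",") -> Path:
    path = Path(path)
    sheet.table.to_csv(path, sep=delimiter, index_label="sample_id")
    return path


def read_intensity_matrix(path: PathLike, delimiter: Optional[str] = None) -> IntensityMatrix:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return IntensityMatrix(df.astype(float))


def write_intensity_matrix(
    intens: IntensityMatrix, path: PathLike, delimiter: str = "\t"
) -> Path:
    path = Path(path)
    intens.totals.to_csv(path, sep=delimiter, index_label="probe_id", float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: PathLike) -> Path:
    """Serialize a tree to Newick with branch lengths.

    Every tip must carry a non-empty label; re-reading the file
    reproduces the topology and the branch lengths to 6 decimals.
    """
    for tip in tree.tips():
        if not tip.name:
            raise ValidationError("tree has an unlabelled tip")
    path = Path(path)
    tree.write(str(path))
    return path


def read_newick(path: PathLike) -> TreeNode:
    return TreeNode.read(str(path))


# ---------------------------------------------------------------------------
# BED export of copy-number bins / segments
# ---------------------------------------------------------------------------

def write_segments_bed(cna, path: PathLike) -> Path:
    """Write per-bin copy-number values of one sample as BED.

    Internal bins are 1-based inclusive; BED lines are 0-based
    half-open, sorted by (chromosome, start), non-overlapping within
    a chromosome arm.
    """
    path = Path(path)
    bins = cna.bins if hasattr(cna, "bins") else cna
    rows = []
    for b in bins:
        rows.append((b.chromosome, b.start - 1, b.end, f"{b.chromosome}{b.arm}", b.median))

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    rows.sort(key=lambda r: (chrom_key(r[0]), r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, name, value in rows:
            fh.write(f"chr{chrom}\t{start}\t{end}\t{name}\t{value:.4f}\n")
    return path


# ---------------------------------------------------------------------------
# Config files (key-value with sections, mirroring CLI flags)
# ---------------------------------------------------------------------------

def read_config(path: PathLike) -> dict:
    """Read an INI-style config into a dict of section -> {key: value}."""
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise FileNotFoundError(path)
    return {section: dict(parser.items(section)) for section in parser.sections()}


def write_config(config: dict, path: PathLike) -> Path:
    parser = configparser.ConfigParser()
    for section, values in config.items():
        parser[section] = {k: str(v) for k, v in values.items()}
    path = Path(path)
    with open(path, "w") as fh:
        parser.write(fh)
    return path
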