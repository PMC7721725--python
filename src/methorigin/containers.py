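"""Core in-memory containers for 450K-style methylation data.

The pipeline's central object is a beta-value matrix (probes x samples,
values in [0, 1]); probe metadata, sample metadata and raw total signal
intensities are carried in companion tables. All containers are thin,
validated wrappers around :class:`pandas.DataFrame`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))
VALID_CHROMOSOMES = AUTOSOMES + ("X", "Y")
DESIGN_TYPES = ("I", "II")
MUTATION_GENES = ("MEN1", "DAXX", "ATRX")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


def _check_unique(ids: Iterable[str], kind: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} id(s): {dup[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame with probe ids as index and sample ids as columns.
        Every non-missing entry must lie in [0, 1]; missing values are
        NaN (never sentinel numbers).
    mask
        Optional boolean DataFrame of detection-pass flags, same shape.
    """

    values: pd.DataFrame
    mask: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = np.nansum((arr < 0) | (arr > 1))
        if bad:
            raise ValidationError(
                f"{int(bad)} beta value(s) outside [0, 1]"
            )
        if self.mask is not None:
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape differs from values shape")
            self.mask = self.mask.astype(bool)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        """Row-subset preserving the given probe order."""
        missing = pd.Index(probes).difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown probe id(s): {list(missing[:5])}")
        mask = self.mask.loc[probes] if self.mask is not None else None
        return BetaMatrix(self.values.loc[probes], mask)

    def select_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        missing = pd.Index(samples).difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown sample id(s): {list(missing[:5])}")
        mask = self.mask[samples] if self.mask is not None else None
        return BetaMatrix(self.values[samples], mask)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic and regulatory metadata.

    Coordinates are 1-based inclusive throughout the package; only BED
    export converts to 0-based half-open. Chromosome labels are stored
    without any "chr" prefix.
    """

    table: pd.DataFrame

    REQUIRED = ("chromosome", "position", "design_type")
    OPTIONAL = ("chromatin_state", "nearest_gene", "arm")

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "probe")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"annotation misses mandatory column '{col}'")
        t = t.copy()
        t["chromosome"] = (
            t["chromosome"].astype(str).str.replace(r"^chr", "", regex=True)
        )
        bad_chr = set(t["chromosome"]) - set(VALID_CHROMOSOMES)
        if bad_chr:
            raise ValidationError(f"unknown chromosome label(s): {sorted(bad_chr)[:5]}")
        t["position"] = t["position"].astype(int)
        if (t["position"] < 1).any():
            raise ValidationError("positions must be >= 1 (1-based coordinates)")
        bad_dt = set(t["design_type"]) - set(DESIGN_TYPES)
        if bad_dt:
            raise ValidationError(f"design_type must be I or II, got {sorted(bad_dt)}")
        for col in self.OPTIONAL:
            if col not in t.columns:
                t[col] = ""
        t["arm"] = t["arm"].replace("", "q")
        bad_arm = set(t["arm"]) - {"p", "q"}
        if bad_arm:
            raise ValidationError(f"arm must be p or q, got {sorted(bad_arm)}")
        self.table = t

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def autosomal_probes(self) -> pd.Index:
        return self.table.index[self.table["chromosome"].isin(AUTOSOMES)]

    def subset(self, probes: Sequence[str]) -> "ProbeAnnotation":
        missing = pd.Index(probes).difference(self.table.index)
        if len(missing):
            raise KeyError(f"probe(s) without annotation: {list(missing[:5])}")
        return ProbeAnnotation(self.table.loc[probes])


@dataclass
class SampleSheet:
    """Per-sample metadata: batch, role, cell type, mutations, outcome."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample")
        if "role" not in t.columns:
            raise ValidationError("sample sheet misses mandatory column 'role'")
        bad_role = set(t["role"]) - {"reference", "tumour"}
        if bad_role:
            raise ValidationError(f"role must be reference/tumour, got {sorted(bad_role)}")
        t = t.copy()
        for col in ("batch", "cell_type", "group", "mutation_status", "grade", "stage"):
            if col not in t.columns:
                t[col] = ""
            t[col] = t[col].fillna("").astype(str)
        ref = t["role"] == "reference"
        if (t.loc[ref, "cell_type"] == "").any():
            bad = t.index[ref & (t["cell_type"] == "")].tolist()
            raise ValidationError(f"reference sample(s) without cell_type: {bad[:5]}")
        for col in ("relapse_time", "relapse_event"):
            if col not in t.columns:
                t[col] = np.nan
            t[col] = pd.to_numeric(t[col], errors="coerce")
        if (t["relapse_time"].dropna() < 0).any():
            raise ValidationError("relapse_time must be >= 0")
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def reference_samples(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "reference"]

    def tumour_samples(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "tumour"]


@dataclass
class IntensityMatrix:
    """Probes x samples matrix of total (methylated + unmethylated) signal."""

    totals: pd.DataFrame

    def __post_init__(self) -> None:
        self.totals = self.totals.astype(float)
        _check_unique(self.totals.index, "probe")
        _check_unique(self.totals.columns, "sample")
        if (self.totals.to_numpy() <= 0).any():
            raise ValidationError("intensities must be strictly positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.totals.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.totals.columns
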