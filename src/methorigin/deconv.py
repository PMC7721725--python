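"""Reference-based cell-type deconvolution by constrained projection.

Marker CpGs are screened by between-cell-type variance and ranked by a
one-way ANOVA F statistic; each bulk profile is then projected onto the
reference mean profiles under non-negativity and a sum-to-at-most-one
constraint (a quadratic program). The projection coefficients, times
100, are reported as percent similarity to each cell type; a sample is
called alpha-like or beta-like when the corresponding similarity
exceeds a threshold (65% by default), and intermediate otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import f_oneway

from .containers import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSet:
    """Marker probes x cell types matrix of reference mean betas."""

    cell_types: List[str]
    marker_probes: List[str]
    M: pd.DataFrame  # markers x cell types
    screening_stat: str = "between_type_variance"
    ranking_stat: str = "anova_F"

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ValidationError("need at least 2 reference cell types")
        if pd.Index(self.marker_probes).has_duplicates:
            raise ValidationError("marker probes must be unique")
        vals = self.M.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValidationError("reference means must lie in [0, 1]")


def select_markers(
    reference_beta: BetaMatrix,
    sheet: SampleSheet,
    n_screen: int = 10_000,
    n_markers: int = 500,
) -> ReferenceSet:
    """Screen and rank cell-type marker CpGs from sorted reference data.

    The ``n_screen`` probes with the largest between-cell-type variance
    of type means are ranked by one-way ANOVA F across cell types; the
    top ``n_markers`` are returned with per-type mean betas. F ties are
    broken by probe id for determinism.
    """
    if n_markers > n_screen:
        raise ValidationError("n_markers must not exceed n_screen")
    refs = sheet.reference_samples()
    cell_types = sorted(refs["cell_type"].unique())
    if len(cell_types) < 2:
        raise ValidationError("need at least 2 reference cell types")
    beta = reference_beta.select_samples(refs.index.tolist())
    n_screen = min(n_screen, beta.shape[0])

    by_type = {
        ct: beta.values[refs.index[refs["cell_type"] == ct]].to_numpy()
        for ct in cell_types
    }
    type_means = np.column_stack([v.mean(axis=1) for v in by_type.values()])
    between_var = type_means.var(axis=1)
    order = np.lexsort((beta.probe_ids.to_numpy(), -between_var))
    screened = order[:n_screen]

    groups = [by_type[ct][screened].T for ct in cell_types]  # samples x probes
    if min(g.shape[0] for g in groups) > 1:
        f_stat = f_oneway(*groups, axis=0).statistic
        f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    else:
        # single replicate per type: fall back to between-type variance
        f_stat = between_var[screened]
    probe_names = beta.probe_ids.to_numpy()[screened]
    rank = np.lexsort((probe_names, -f_stat))
    top = rank[:n_markers]
    marker_probes = probe_names[top].tolist()

    M = pd.DataFrame(
        {ct: by_type[ct][screened][top].mean(axis=1) for ct in cell_types},
        index=pd.Index(marker_probes, name="probe_id"),
    )
    return ReferenceSet(cell_types=cell_types, marker_probes=marker_probes, M=M)


def _solve_qp(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """minimize ||y - M w||^2  s.t.  w >= 0, sum(w) <= 1."""
    k = M.shape[1]
    MtM = M.T @ M
    Mty = M.T @ y

    def objective(w):
        r = M @ w - y
        return float(r @ r)

    def gradient(w):
        return 2.0 * (MtM @ w - Mty)

    w0 = np.full(k, 1.0 / (k + 1))
    res = optimize.minimize(
        objective,
        w0,
        jac=gradient,
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones(k)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    if w.sum() > 1.0:
        w = w / w.sum()
    return w


def estimate_fractions(
    sample_beta: pd.Series,
    ref: ReferenceSet,
    min_coverage: float = 0.9,
) -> pd.DataFrame:
    """Constrained projection of one or more samples onto the reference.

    ``sample_beta`` may be a Series (one sample) or DataFrame (probes x
    samples). Markers missing in a sample are dropped pairwise, but at
    least ``min_coverage`` of the marker probes must be available.
    Returns a DataFrame indexed by sample with one fraction column per
    cell type plus an RMS ``residual`` column.
    """
    if isinstance(sample_beta, pd.Series):
        sample_beta = sample_beta.to_frame()
    present = pd.Index(ref.marker_probes).intersection(sample_beta.index)
    if len(present) < min_coverage * len(ref.marker_probes):
        raise ValidationError(
            f"only {len(present)}/{len(ref.marker_probes)} marker probes available "
            f"(need >= {min_coverage:.0%})"
        )
    M_full = ref.M.loc[present].to_numpy()
    if np.linalg.matrix_rank(M_full) < M_full.shape[1]:
        logger.warning("reference matrix is rank-deficient; solution may be non-unique")

    rows = {}
    for sid in sample_beta.columns:
        y = sample_beta.loc[present, sid].to_numpy()
        ok = ~np.isnan(y)
        if ok.sum() < min_coverage * len(ref.marker_probes):
            raise ValidationError(
                f"sample {sid!r}: insufficient non-missing marker coverage"
            )
        w = _solve_qp(M_full[ok], y[ok])
        resid = float(np.sqrt(np.mean((y[ok] - M_full[ok] @ w) ** 2)))
        rows[sid] = list(w) + [resid]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(ref.cell_types) + ["residual"]
    )


def classify_origin(
    fractions: pd.DataFrame,
    threshold: float = 65.0,
    alpha_col: str = "alpha",
    beta_col: str = "beta",
) -> pd.DataFrame:
    """Similarity-threshold cell-of-origin call per sample.

    alpha-like iff 100*w_alpha > threshold (strictly), beta-like
    analogously, otherwise intermediate; both cannot exceed the
    threshold at 65 since the fractions sum to at most 1.
    """
    for col in (alpha_col, beta_col):
        if col not in fractions.columns:
            raise ValidationError(f"fractions table misses column {col!r}")
    alpha_sim = 100.0 * fractions[alpha_col]
    beta_sim = 100.0 * fractions[beta_col]
    label = np.where(
        alpha_sim > threshold, "alpha_like",
        np.where(beta_sim > threshold, "beta_like", "intermediate"),
    )
    return pd.DataFrame(
        {
            "label": label,
            "alpha_similarity": alpha_sim,
            "beta_similarity": beta_sim,
        },
        index=fractions.index,
    )
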