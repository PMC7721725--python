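"""Resampling consensus clustering, stability-based k selection, and
TF-checkpoint probe selection by chromatin state.

Consensus clustering follows the Monti resampling scheme: for each k,
repeated subsamples of the cohort are clustered hierarchically (Ward
minimum-variance on squared dissimilarities of 1 - Pearson correlation,
the "ward.D2" flavour) and the co-clustering frequency of every sample
pair, conditional on co-sampling, forms the consensus matrix. Final
assignments come from average-linkage clustering of 1 - consensus. The
number of clusters is chosen where the area under the consensus CDF
stops increasing appreciably (delta-area elbow).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, ward
from scipy.spatial.distance import squareform

from .containers import AUTOSOMES, BetaMatrix, ProbeAnnotation, ValidationError
from .diffmeth import DMParams, differential_methylation
from .simulate import ALPHA_TF_GENES, BETA_TF_GENES, ENHANCER_STATES

logger = logging.getLogger(__name__)


@dataclass
class ConsensusParams:
    """Resampling-clustering settings (ConsensusClusterPlus-style defaults)."""

    k_max: int = 20
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    distance: str = "pearson"
    inner_linkage: str = "ward"
    final_linkage: str = "average"
    elbow_threshold: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_item <= 1 or not 0 < self.p_feature <= 1:
            raise ValidationError("p_item and p_feature must lie in (0, 1]")
        if self.k_max < 2:
            raise ValidationError("k_max must be >= 2")
        if self.distance != "pearson":
            raise ValidationError("only pearson distance is supported")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and stability statistics."""

    sample_ids: List[str]
    consensus: Dict[int, np.ndarray]
    assignments: Dict[int, np.ndarray]
    area: Dict[int, float]
    delta_area: Dict[int, float]
    params: ConsensusParams

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.assignments, index=self.sample_ids)


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of X."""
    R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, None)


def _cut(D: np.ndarray, k: int, linkage: str) -> np.ndarray:
    condensed = squareform(D, checks=False)
    Z = ward(condensed) if linkage == "ward" else average(condensed)
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    beta: BetaMatrix,
    probes: Optional[Sequence[str]] = None,
    params: ConsensusParams = None,
) -> ConsensusResult:
    """Monti consensus clustering over k = 2..k_max.

    For each k and each of ``reps`` iterations, floor(p_item * n)
    samples are drawn without replacement (and floor(p_feature * p)
    features if p_feature < 1), the 1 - Pearson distance is clustered by
    Ward linkage and cut at k, and co-cluster / co-sample counts are
    accumulated; the consensus matrix is their ratio. One seeded
    generator stream per k keeps runs reproducible under parallelism.
    """
    params = params or ConsensusParams()
    values = beta.values if probes is None else beta.select_probes(list(probes)).values
    X = values.to_numpy().T  # samples x features
    n, p = X.shape
    if n < 5:
        raise ValidationError("need at least 5 samples for consensus clustering")
    if params.k_max >= n:
        raise ValidationError("k_max must be smaller than the number of samples")
    var = X.var(axis=0)
    if (var == 0).all():
        raise ValidationError("all features have zero variance")
    sample_ids = list(values.columns)

    m_item = int(np.floor(params.p_item * n))
    m_feat = int(np.floor(params.p_feature * p))
    full_D = _pearson_distance(X) if params.p_feature >= 1.0 else None

    consensus: Dict[int, np.ndarray] = {}
    assignments: Dict[int, np.ndarray] = {}
    for k in range(2, params.k_max + 1):
        rng = np.random.default_rng([params.seed % (2**31), k])
        I = np.zeros((n, n))
        N = np.zeros((n, n))
        for _ in range(params.reps):
            idx = np.sort(rng.choice(n, size=m_item, replace=False))
            if full_D is not None:
                D = full_D[np.ix_(idx, idx)]
            else:
                feats = rng.choice(p, size=m_feat, replace=False)
                D = _pearson_distance(X[np.ix_(idx, feats)])
            labels = _cut(D, k, params.inner_linkage)
            co = (labels[:, None] == labels[None, :]).astype(float)
            I[np.ix_(idx, idx)] += co
            N[np.ix_(idx, idx)] += 1.0
        off_diag = ~np.eye(n, dtype=bool)
        if (N[off_diag] == 0).any():
            raise ValidationError(
                "some sample pairs were never co-sampled; increase reps"
            )
        C = I / np.maximum(N, 1.0)
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2.0
        consensus[k] = C
        assignments[k] = _cut(1.0 - C, k, params.final_linkage)

    area, delta_area = _stability_profile(consensus)
    return ConsensusResult(
        sample_ids=sample_ids,
        consensus=consensus,
        assignments=assignments,
        area=area,
        delta_area=delta_area,
        params=params,
    )


def _cdf_area(C: np.ndarray) -> float:
    """Area under the empirical CDF of off-diagonal consensus values."""
    n = C.shape[0]
    vals = np.sort(C[np.triu_indices(n, k=1)])
    xs = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.searchsorted(vals, xs, side="right") / len(vals)
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def _stability_profile(consensus: Dict[int, np.ndarray]) -> Tuple[Dict[int, float], Dict[int, float]]:
    ks = sorted(consensus)
    area = {k: _cdf_area(consensus[k]) for k in ks}
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    return area, delta


def pac_score(C: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus mass
    falling strictly between ``lower`` and ``upper``."""
    n = C.shape[0]
    v = C[np.triu_indices(n, k=1)]
    return float(((v > lower) & (v < upper)).mean())


def select_k(
    result: ConsensusResult,
    elbow_threshold: Optional[float] = None,
    max_ambiguity: float = 0.03,
) -> int:
    """Stability-based choice of the number of clusters.

    Candidate k values are those whose relative delta-area gain exceeds
    the elbow threshold; among them the largest k whose consensus matrix
    is still crisp (proportion of ambiguous entries at most
    ``max_ambiguity``) is chosen. Splitting past the true structure
    inflates the CDF area while filling the consensus matrix with
    intermediate values, so requiring crispness prevents the delta-area
    gain of an over-split from being mistaken for new structure. If no
    candidate is crisp the least ambiguous candidate wins.
    """
    thr = elbow_threshold if elbow_threshold is not None else result.params.elbow_threshold
    candidates = [k for k in sorted(result.delta_area) if result.delta_area[k] > thr]
    if not candidates:
        candidates = [min(result.delta_area)]
    pac = {k: pac_score(result.consensus[k]) for k in candidates}
    crisp = [k for k in candidates if pac[k] <= max_ambiguity]
    if crisp:
        return max(crisp)
    return min(candidates, key=lambda k: (pac[k], k))


# ---------------------------------------------------------------------------
# TF-checkpoint probe selection
# ---------------------------------------------------------------------------

@dataclass
class TFCheckpointSpec:
    """Gene lists and regulatory-state gate for TF-checkpoint CpGs.

    Defaults carry the 7 alpha-cell and 9 beta-cell lineage TF
    checkpoints and the eight enhancer/insulator/polycomb chromatin
    states; both are pure configuration and overridable.
    """

    alpha_genes: Tuple[str, ...] = ALPHA_TF_GENES
    beta_genes: Tuple[str, ...] = BETA_TF_GENES
    allowed_states: Tuple[str, ...] = ENHANCER_STATES
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if set(self.alpha_genes) & set(self.beta_genes):
            raise ValidationError("alpha and beta gene lists must be disjoint")
        if not self.allowed_states:
            raise ValidationError("allowed_states must be non-empty")


def select_tf_probes(
    ann: ProbeAnnotation,
    spec: TFCheckpointSpec,
    cell: str,
) -> List[str]:
    """Probes in allowed chromatin states whose nearest gene is a
    checkpoint of the requested cell type ("alpha" or "beta")."""
    if cell == "alpha":
        genes = set(spec.alpha_genes)
    elif cell == "beta":
        genes = set(spec.beta_genes)
    else:
        raise ValidationError("cell must be 'alpha' or 'beta'")
    t = ann.table
    keep = t["chromatin_state"].isin(spec.allowed_states) & t["nearest_gene"].isin(genes)
    if spec.autosomes_only:
        keep &= t["chromosome"].isin(AUTOSOMES)
    found_genes = set(t.loc[keep, "nearest_gene"])
    absent = genes - set(t["nearest_gene"])
    if absent:
        logger.warning("gene(s) absent from annotation: %s", sorted(absent))
    return t.index[keep].tolist()


# ---------------------------------------------------------------------------
# Multi-group signature
# ---------------------------------------------------------------------------

def build_signature(
    beta: BetaMatrix,
    groups: Sequence[str],
    params: DMParams = None,
) -> List[str]:
    """Union of pairwise differentially methylated sites across groups.

    With the three origin classes this reproduces the union-of-contrasts
    construction of the tumour subtype signature: each pair of groups is
    compared separately and the selected sets are united, deduplicated
    and sorted.
    """
    params = params or DMParams()
    groups = pd.Series(list(groups), index=beta.sample_ids, dtype=str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need at least two groups to build a signature")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValidationError(f"group {lv!r} has fewer than 2 samples")
    sig: Set[str] = set()
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            pair = groups.isin([levels[i], levels[j]])
            sub = beta.select_samples(groups.index[pair].tolist())
            _, selected = differential_methylation(sub, groups[pair], params)
            sig.update(selected)
    return sorted(sig)
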