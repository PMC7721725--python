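"""Phyloepigenetic trees: correlation distances, neighbor joining, rooting.

Samples are compared by 1 - Pearson correlation over a selected CpG
subset; trees are built by the Saitou-Nei neighbor-joining
agglomeration (tie-broken deterministically), rooted on the pendant
edge of a chosen reference sample, and read back group-wise by nearest
reference tip in patristic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

MIN_SHARED_PROBES = 30


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with ordered labels."""

    labels: List[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if (np.diag(self.D) != 0).any():
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.D < -1e-12).any():
            raise ValidationError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


def correlation_distance(
    beta: BetaMatrix, probes: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    """Pairwise 1 - Pearson correlation over a probe subset.

    Uses pairwise-complete observations when values are missing; sample
    pairs sharing fewer than 30 probes raise an error, as does a sample
    with zero variance over the subset.
    """
    values = beta.values if probes is None else beta.select_probes(list(probes)).values
    if values.shape[1] < 3:
        raise ValidationError("need at least 3 samples for a distance matrix")
    arr = values.to_numpy()
    labels = list(values.columns)

    sds = np.nanstd(arr, axis=0)
    zero_var = [labels[j] for j in range(len(labels)) if sds[j] == 0]
    if zero_var:
        raise ValidationError(f"sample(s) with zero variance over subset: {zero_var[:5]}")

    if np.isnan(arr).any():
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(arr[:, i]) & ~np.isnan(arr[:, j])
                if ok.sum() < MIN_SHARED_PROBES:
                    raise ValidationError(
                        f"samples {labels[i]!r}/{labels[j]!r} share only {int(ok.sum())} probes"
                    )
                r = np.corrcoef(arr[ok, i], arr[ok, j])[0, 1]
                D[i, j] = D[j, i] = 1.0 - r
    else:
        if arr.shape[0] < MIN_SHARED_PROBES:
            raise ValidationError(f"need at least {MIN_SHARED_PROBES} shared probes")
        R = np.corrcoef(arr.T)
        D = 1.0 - R
        np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    D = (D + D.T) / 2.0
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q_ij = (n-2) D_ij - r_i - r_j is
    joined (ties broken by the lexicographically smallest pair of
    subtree labels); branch lengths follow the canonical formulas and
    negative lengths are retained but flagged in the log. The result is
    an unrooted tree whose root node has three children.
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    D = dist.D.copy()
    # canonical label of each active node = smallest tip name in its subtree
    nodes: List[TreeNode] = [TreeNode(name=l) for l in labels]
    canon: List[str] = list(labels)
    n_negative = 0

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(cand, key=lambda ij: tuple(sorted((canon[ij[0]], canon[ij[1]]))))

        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            n_negative += 1
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)

        d_new = (D[i] + D[j] - D[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        D_next = np.zeros((len(keep) + 1, len(keep) + 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D = D_next
        nodes = [nodes[k] for k in keep] + [parent]
        canon = [canon[k] for k in keep] + [min(canon[i], canon[j])]

    # join the final three nodes in a star
    a, b, c = range(3)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = float(length)
        if length < 0:
            n_negative += 1
    if n_negative:
        logger.warning("neighbor joining produced %d negative branch length(s)", n_negative)
    root = TreeNode(children=list(nodes))
    return root


def root_tree(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the edge subtending the outgroup tip, at its midpoint."""
    try:
        tip = tree.find(outgroup)
    except Exception as exc:
        raise ValidationError(f"unknown tip {outgroup!r}") from exc
    if not tip.is_tip():
        raise ValidationError(f"{outgroup!r} is not a tip")
    if tip.length is None or tip.length <= 0:
        # degenerate pendant edge (possible after NJ): root directly above
        tip.length = max(tip.length or 0.0, 0.0)
        return tree.root_at(tip.parent, reset=True)
    return tree.root_at(tip, above=True, reset=True)


def clade_membership(
    tree: TreeNode, reference_tips: Dict[str, str]
) -> pd.DataFrame:
    """Label each non-reference tip by its nearest reference cell type.

    ``reference_tips`` maps reference tip name -> cell type. Nearness is
    patristic (path) distance; exact ties yield the label "ambiguous".
    Returns a DataFrame indexed by tumour tip with columns ``label`` and
    ``distance``.
    """
    if not reference_tips:
        raise ValidationError("no reference tips supplied")
    tip_names = {t.name for t in tree.tips()}
    missing = set(reference_tips) - tip_names
    if missing:
        raise ValidationError(f"reference tip(s) not in tree: {sorted(missing)[:5]}")
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    ref_names = list(reference_tips)
    rows = {}
    for name in ids:
        if name in reference_tips:
            continue
        dists = np.array([dm[name, r] for r in ref_names])
        # nearest distance per cell type
        by_type: Dict[str, float] = {}
        for r, d in zip(ref_names, dists):
            ct = reference_tips[r]
            by_type[ct] = min(by_type.get(ct, np.inf), d)
        best = min(by_type.values())
        winners = sorted(ct for ct, d in by_type.items() if np.isclose(d, best, atol=1e-12))
        if len(winners) > 1:
            logger.warning("tip %r equidistant from types %s", name, winners)
            label = "ambiguous"
        else:
            label = winners[0]
        rows[name] = (label, float(best))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["label", "distance"])
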