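"""Copy-number aberration inference from array total intensities.

Per-probe log2 ratios against the median reference profile are tiled
into adaptive genomic bins (50 kb to 5 Mb, at least 15 probes each),
summarized per chromosome arm by the median of bin medians, called
gain/loss against a margin after an adjustable zero-threshold offset,
and profiles are grouped by Ward/Euclidean hierarchical clustering with
groups numbered by ascending aberration burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import IntensityMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CNAParams:
    min_bin_bp: int = 50_000
    max_bin_bp: int = 5_000_000
    min_probes_per_bin: int = 15
    zero_threshold: float = 0.0  # additive recalibration offset
    call_margin: float = 0.15
    n_groups: int = 3

    def __post_init__(self) -> None:
        if self.min_bin_bp >= self.max_bin_bp:
            raise ValidationError("min_bin_bp must be smaller than max_bin_bp")
        if self.min_probes_per_bin < 1:
            raise ValidationError("min_probes_per_bin must be >= 1")


@dataclass
class GenomicBin:
    chromosome: str
    arm: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    probe_ids: List[str]
    median: float

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class CNAResult:
    """Per-sample log ratios, bins, arm values, calls and group labels."""

    log_ratios: pd.DataFrame  # probes x samples
    bins: Dict[str, List[GenomicBin]]  # per sample
    arm_cn: pd.DataFrame  # samples x arms
    calls: pd.DataFrame  # samples x arms, in {loss, neutral, gain}
    groups: Optional[pd.Series] = None  # per-sample {1..n_groups}


def compute_log_ratios(
    intensities: IntensityMatrix,
    reference_samples: Sequence[str],
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """log2(sample / reference median) per probe, median-centred per sample."""
    refs = list(reference_samples)
    if len(refs) < 2:
        raise ValidationError("need at least 2 reference samples")
    missing = set(refs) - set(intensities.sample_ids)
    if missing:
        raise ValidationError(f"unknown reference sample(s): {sorted(missing)[:5]}")
    totals = intensities.totals
    if (totals.to_numpy() <= 0).any():
        bad = totals.index[(totals <= 0).any(axis=1)][:5].tolist()
        raise ValidationError(f"non-positive intensity at probe(s): {bad}")
    ref_median = totals[refs].median(axis=1)
    cols = samples if samples is not None else [s for s in totals.columns if s not in refs]
    ratios = np.log2(totals[list(cols)].div(ref_median, axis=0))
    ratios = ratios - ratios.median(axis=0)
    return ratios


def bin_genome(
    ratios: pd.Series,
    ann: ProbeAnnotation,
    params: CNAParams = CNAParams(),
) -> List[GenomicBin]:
    """Greedy left-to-right adaptive tiling of one sample's ratios.

    Per chromosome arm: a bin opens at the first unassigned probe and
    extends probe-by-probe while it holds fewer than
    ``min_probes_per_bin`` probes and the next probe keeps the span at
    or under ``max_bin_bp``. A closed bin still short of the probe
    minimum (a large gap, or the end of the arm) merges into its left
    neighbour, or is dropped with a warning if the arm has none.
    """
    ann = ann.subset(ratios.index)
    t = ann.table
    bins: List[GenomicBin] = []
    for (chrom, arm), sub in t.groupby(["chromosome", "arm"], sort=False):
        pos = sub["position"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            order = np.argsort(pos, kind="mergesort")
            sub = sub.iloc[order]
            pos = sub["position"].to_numpy()
        ids = sub.index.to_numpy()
        vals = ratios.loc[ids].to_numpy()
        arm_bins: List[GenomicBin] = []
        i = 0
        n = len(pos)
        while i < n:
            start = int(pos[i])
            j = i
            # extend while underfilled and under the span cap
            while (
                j - i + 1 < params.min_probes_per_bin
                and j + 1 < n
                and pos[j + 1] - start + 1 <= params.max_bin_bp
            ):
                j += 1
            count = j - i + 1
            end = int(pos[j])
            if count < params.min_probes_per_bin:
                if arm_bins:
                    prev = arm_bins[-1]
                    members = list(prev.probe_ids) + list(ids[i : j + 1])
                    arm_bins[-1] = GenomicBin(
                        chromosome=chrom,
                        arm=arm,
                        start=prev.start,
                        end=int(pos[j]),
                        probe_ids=members,
                        median=float(np.median(ratios.loc[members].to_numpy())),
                    )
                else:
                    logger.warning(
                        "arm %s%s has only %d probe(s); no bins emitted", chrom, arm, count
                    )
            else:
                arm_bins.append(
                    GenomicBin(
                        chromosome=chrom,
                        arm=arm,
                        start=start,
                        end=end,
                        probe_ids=list(ids[i : j + 1]),
                        median=float(np.median(vals[i : j + 1])),
                    )
                )
            i = j + 1
        bins.extend(arm_bins)
    return bins


def arm_level_cn(
    bins: List[GenomicBin],
    params: CNAParams = CNAParams(),
) -> pd.DataFrame:
    """Median of bin values per arm, offset by the zero-threshold, called
    gain/loss against the margin."""
    rows = []
    by_arm: Dict[Tuple[str, str], List[float]] = {}
    for b in bins:
        by_arm.setdefault((b.chromosome, b.arm), []).append(b.median)
    for (chrom, arm), vals in by_arm.items():
        value = float(np.median(vals)) + params.zero_threshold
        call = (
            "gain" if value > params.call_margin
            else "loss" if value < -params.call_margin
            else "neutral"
        )
        rows.append({"arm": f"{chrom}{arm}", "value": value, "call": call})
    return pd.DataFrame(rows).set_index("arm")


def infer_cna(
    intensities: IntensityMatrix,
    ann: ProbeAnnotation,
    reference_samples: Sequence[str],
    params: CNAParams = CNAParams(),
    samples: Optional[Sequence[str]] = None,
) -> CNAResult:
    """Full per-cohort copy-number inference."""
    ratios = compute_log_ratios(intensities, reference_samples, samples)
    # restrict to autosomal probes with annotation
    ann_sub = ann.subset(ratios.index)
    auto = ann_sub.autosomal_probes()
    ratios = ratios.loc[auto]
    all_bins: Dict[str, List[GenomicBin]] = {}
    arm_rows = {}
    call_rows = {}
    for sid in ratios.columns:
        bins = bin_genome(ratios[sid], ann, params)
        all_bins[sid] = bins
        arms = arm_level_cn(bins, params)
        arm_rows[sid] = arms["value"]
        call_rows[sid] = arms["call"]
    arm_cn = pd.DataFrame(arm_rows).T
    calls = pd.DataFrame(call_rows).T
    groups = cluster_cna_profiles(arm_cn, params) if arm_cn.shape[0] >= params.n_groups else None
    return CNAResult(
        log_ratios=ratios, bins=all_bins, arm_cn=arm_cn, calls=calls, groups=groups
    )


def cluster_cna_profiles(
    arm_cn: pd.DataFrame, params: CNAParams = CNAParams()
) -> pd.Series:
    """Ward/Euclidean clustering of arm-level profiles into burden tiers.

    Groups are renumbered 1..n by ascending mean total |arm value| so
    group 1 has the fewest copy-number events and the last group the
    most.
    """
    if arm_cn.shape[0] < params.n_groups:
        raise ValidationError("fewer samples than requested CNA groups")
    Z = linkage(arm_cn.to_numpy(), method="ward", metric="euclidean")
    raw = fcluster(Z, t=params.n_groups, criterion="maxclust")
    burden = arm_cn.abs().sum(axis=1)
    order = (
        pd.DataFrame({"raw": raw, "burden": burden})
        .groupby("raw")["burden"]
        .mean()
        .sort_values()
        .index.tolist()
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([remap[r] for r in raw], index=arm_cn.index, name="cna_group")
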