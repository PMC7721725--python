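"""Synthetic methylome cohorts with known ground truth.

Emulates the data the analysis assumes: sorted reference cell types with
planted cell-type-specific CpGs, tumours as noisy convex mixtures of the
reference profiles carrying subtype-specific signatures, batch effects,
the compressed dynamic range of type II probes, arm-level intensity
gains/losses and group-dependent relapse hazards. Every probe role and
sample truth is recorded so downstream stages can be scored exactly.

Noise is added on the logit scale and back-transformed, which keeps all
beta values inside [0, 1] without clipping artifacts. Fixing the seed
fixes every emitted byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import (
    AUTOSOMES,
    BetaMatrix,
    IntensityMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)
from . import io as mio

logger = logging.getLogger(__name__)

#: chromatin states accepted by the TF-checkpoint probe filter
ENHANCER_STATES = (
    "closed weak enhancer",
    "lowly-methylated weak enhancer",
    "open weak enhancer",
    "closed strong enhancer",
    "open strong enhancer",
    "genic enhancer",
    "insulator",
    "polycomb repressed",
)
OTHER_STATES = ("active promoter", "transcribed", "quiescent", "heterochromatin")

#: lineage-determining transcription-factor checkpoints (configuration,
#: overridable): 7 alpha-cell and 9 beta-cell genes
ALPHA_TF_GENES = ("FEV", "IRX2", "LDB2", "MAFB", "PGR", "PTGER3", "BMP5")
BETA_TF_GENES = (
    "MAFA", "PDX1", "SMAD9", "CDKN1C", "TFCP2L1", "SIX3", "SIX2", "RFX6", "MNX1",
)


@dataclass(frozen=True)
class TumourGroupSpec:
    """One tumour group: mixture weights, size, signature and outcome."""

    label: str
    weights: Dict[str, float]
    n: int
    signature_size: int = 150
    signature_shift: float = 1.5  # logit units
    mutation_probs: Dict[str, float] = field(default_factory=dict)
    relapse_hazard: float = 0.0  # events per month
    #: per-sample compositional heterogeneity: log-normal sigma applied to
    #: the group weights before renormalization (0 = identical mixtures)
    weight_jitter: float = 0.15


@dataclass(frozen=True)
class CNAEvent:
    group: str
    chromosome: str
    arm: str
    log2_shift: float


def _default_groups() -> Tuple[TumourGroupSpec, ...]:
    # Group sizes and mixture weights mirror a realistic PanNET cohort: 19
    # alpha-like (~72% alpha similarity), 14 beta-like (~73% beta), 76
    # intermediate-ADM (53/12) and 16 intermediate-WT (51/14), with
    # MEN1/DAXX/ATRX enrichment in the ADM group and relapse risk
    # concentrated in the intermediate groups.
    return (
        TumourGroupSpec(
            "alpha_like",
            {"alpha": 0.72, "acinar": 0.10, "duct": 0.08, "fibroblast": 0.06, "immune": 0.04},
            n=19,
            mutation_probs={"MEN1": 0.58, "DAXX": 0.0, "ATRX": 0.0},
            relapse_hazard=0.002,
        ),
        TumourGroupSpec(
            "beta_like",
            {"beta": 0.73, "acinar": 0.10, "duct": 0.08, "fibroblast": 0.05, "immune": 0.04},
            n=14,
            mutation_probs={"MEN1": 0.07, "DAXX": 0.0, "ATRX": 0.0},
            relapse_hazard=0.001,
        ),
        TumourGroupSpec(
            "intermediate_ADM",
            {"alpha": 0.53, "beta": 0.12, "acinar": 0.14, "duct": 0.10,
             "fibroblast": 0.06, "immune": 0.05},
            n=76,
            mutation_probs={"MEN1": 0.55, "DAXX": 0.40, "ATRX": 0.20},
            relapse_hazard=0.015,
        ),
        TumourGroupSpec(
            "intermediate_WT",
            {"alpha": 0.51, "beta": 0.14, "acinar": 0.14, "duct": 0.10,
             "fibroblast": 0.06, "immune": 0.05},
            n=16,
            mutation_probs={"MEN1": 0.05, "DAXX": 0.03, "ATRX": 0.03},
            relapse_hazard=0.012,
        ),
    )


def _default_cna_events() -> Tuple[CNAEvent, ...]:
    return (
        CNAEvent("intermediate_ADM", "11", "p", -0.35),
        CNAEvent("intermediate_ADM", "11", "q", -0.35),
        CNAEvent("intermediate_ADM", "6", "q", -0.3),
        CNAEvent("intermediate_ADM", "16", "p", -0.3),
        CNAEvent("intermediate_ADM", "22", "q", -0.3),
        CNAEvent("intermediate_ADM", "1", "p", -0.3),
        CNAEvent("intermediate_WT", "7", "p", 0.3),
        CNAEvent("intermediate_WT", "17", "q", 0.3),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort. Defaults emulate a realistic
    PanNET methylome cohort with sorted-islet references."""

    n_probes: int = 20000
    cell_types: Tuple[str, ...] = ("alpha", "beta", "acinar", "duct", "fibroblast", "immune")
    n_reference_per_type: int = 2
    frac_celltype_specific: float = 0.05
    delta_beta: float = 0.35
    noise_sd: float = 0.05  # logit scale
    tumour_groups: Tuple[TumourGroupSpec, ...] = field(default_factory=_default_groups)
    batches: Tuple[Tuple[str, float], ...] = (("UB", 0.0), ("UCL", 0.1), ("ICGC", -0.1))
    type2_fraction: float = 0.72
    type2_compression: float = 0.8  # slope toward 0.5 on type II probes
    cna_events: Tuple[CNAEvent, ...] = field(default_factory=_default_cna_events)
    intensity_noise_sd: float = 0.08  # log2 scale
    censor_max_months: float = 120.0
    frac_sex_probes: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.delta_beta < 1:
            raise ValidationError("delta_beta must lie in (0, 1)")
        for g in self.tumour_groups:
            unknown = set(g.weights) - set(self.cell_types)
            if unknown:
                raise ValidationError(
                    f"group {g.label!r} weights reference unknown cell type(s): {sorted(unknown)}"
                )
            w = np.array(list(g.weights.values()), dtype=float)
            if (w < 0).any() or w.sum() > 1 + 1e-9:
                raise ValidationError(
                    f"group {g.label!r}: weights must be non-negative and sum <= 1"
                )
            for p in g.mutation_probs.values():
                if not 0 <= p <= 1:
                    raise ValidationError("mutation probabilities must lie in [0, 1]")
        if int(self.frac_celltype_specific * self.n_probes) < 1:
            raise ValidationError(
                "frac_celltype_specific * n_probes must be at least 1"
            )


@dataclass
class GroundTruth:
    """Record of every planted structure, for exact downstream scoring."""

    probe_roles: pd.Series  # "marker:<cell_type>" | "signature:<group>" | "neutral"
    ref_means: pd.DataFrame  # probes x cell types, true means (pre-noise)
    marker_probes: Dict[str, List[str]]
    signature_probes: Dict[str, List[str]] = field(default_factory=dict)
    sample_truth: Optional[pd.DataFrame] = None  # per-tumour group/batch/weights/...
    annotation: Optional[ProbeAnnotation] = None
    cna_events: Tuple[CNAEvent, ...] = ()


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stream])


def _probe_ids(n: int) -> List[str]:
    return [f"cg{i:07d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> ProbeAnnotation:
    """Genomic/regulatory annotation for the synthetic probe set.

    Probes are spread over all autosomes (plus a small X/Y fraction to
    exercise filtering), split into p/q arms, assigned design types,
    chromatin states and nearest genes; the lineage TF-checkpoint genes
    each receive a handful of enhancer-state probes.
    """
    rng = _rng(config, 1)
    n = config.n_probes
    probes = _probe_ids(n)

    n_sex = int(round(config.frac_sex_probes * n))
    chroms = np.array(list(AUTOSOMES))
    # weight larger chromosomes a little more heavily
    w = np.linspace(2.0, 1.0, len(chroms))
    w /= w.sum()
    chrom_assign = rng.choice(chroms, size=n, p=w)
    if n_sex:
        sex_idx = rng.choice(n, size=n_sex, replace=False)
        chrom_assign[sex_idx] = rng.choice(["X", "Y"], size=n_sex, p=[0.8, 0.2])

    arm = np.where(rng.random(n) < 0.45, "p", "q")
    position = np.empty(n, dtype=int)
    for c in np.unique(chrom_assign):
        for a in ("p", "q"):
            idx = np.where((chrom_assign == c) & (arm == a))[0]
            if len(idx) == 0:
                continue
            # ~1 probe / 3 kb keeps arms long enough for 50 kb-5 Mb bins
            offsets = np.sort(rng.integers(1, 3000, size=len(idx)).cumsum())
            base = 1 if a == "p" else 130_000_000
            position[idx] = base + offsets

    design = np.where(rng.random(n) < config.type2_fraction, "II", "I")
    state_pool = np.array(ENHANCER_STATES + OTHER_STATES)
    states = rng.choice(state_pool, size=n)
    genes = np.array([f"GENE{i % 997:03d}" for i in rng.integers(0, 997, size=n)], dtype=object)

    # plant enhancer-state probes near each TF-checkpoint gene (autosomal)
    tf_genes = list(ALPHA_TF_GENES) + list(BETA_TF_GENES)
    auto_idx = np.where(np.isin(chrom_assign, AUTOSOMES))[0]
    picked = rng.choice(auto_idx, size=6 * len(tf_genes), replace=False)
    for j, g in enumerate(tf_genes):
        block = picked[6 * j : 6 * (j + 1)]
        genes[block] = g
        states[block] = rng.choice(np.array(ENHANCER_STATES), size=len(block))

    table = pd.DataFrame(
        {
            "chromosome": chrom_assign,
            "position": position,
            "design_type": design,
            "chromatin_state": states,
            "nearest_gene": genes,
            "arm": arm,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return ProbeAnnotation(table)


# ---------------------------------------------------------------------------
# Reference profiles
# ---------------------------------------------------------------------------

def _clamped_logit(x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    return logit(np.clip(x, eps, 1 - eps))


def _compress_type2(values: np.ndarray, is_type2: np.ndarray, slope: float) -> np.ndarray:
    out = values.copy()
    out[is_type2] = 0.5 + (out[is_type2] - 0.5) * slope
    return out


def _true_means(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.Series, Dict[str, List[str]]]:
    """Per-cell-type true mean betas with planted markers."""
    rng = _rng(config, 2)
    n = config.n_probes
    probes = _probe_ids(n)
    types = list(config.cell_types)

    # bimodal background shared by all cell types
    comp = rng.choice(3, size=n, p=[0.45, 0.35, 0.20])
    base = np.where(
        comp == 0,
        rng.uniform(0.03, 0.25, size=n),
        np.where(comp == 1, rng.uniform(0.75, 0.97, size=n), rng.uniform(0.25, 0.75, size=n)),
    )

    n_markers = int(config.frac_celltype_specific * n)
    marker_idx = rng.choice(n, size=n_markers, replace=False)
    owner = np.array(types)[np.arange(n_markers) % len(types)]

    means = pd.DataFrame(
        np.tile(base[:, None], (1, len(types))),
        index=pd.Index(probes, name="probe_id"),
        columns=types,
    )
    roles = pd.Series("neutral", index=means.index, name="role")
    marker_probes: Dict[str, List[str]] = {t: [] for t in types}
    d = config.delta_beta
    hyper = rng.random(n_markers) < 0.5
    for k, (i, ct) in enumerate(zip(marker_idx, owner)):
        if hyper[k]:
            b = float(np.clip(base[i], 0.05, 0.95 - d))
            means.iloc[i] = b
            means.iloc[i, types.index(ct)] = b + d
        else:
            b = float(np.clip(base[i], 0.05 + d, 0.95))
            means.iloc[i] = b
            means.iloc[i, types.index(ct)] = b - d
        roles.iloc[i] = f"marker:{ct}"
        marker_probes[ct].append(probes[i])
    return means, roles, marker_probes


def generate_reference_profiles(
    config: SimulationConfig,
) -> Tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Sorted-cell reference profiles with planted cell-type markers.

    Marker probes of each cell type have a true mean separated from all
    other types by exactly ``delta_beta``; non-marker probes share a
    common mean. Per-sample noise is Gaussian on the logit scale.
    """
    ann = generate_annotation(config)
    means, roles, marker_probes = _true_means(config)
    rng = _rng(config, 3)
    types = list(config.cell_types)
    is_type2 = (ann.table["design_type"] == "II").to_numpy()

    cols = {}
    rows_sheet = []
    for ct in types:
        mu = _clamped_logit(means[ct].to_numpy())
        for r in range(config.n_reference_per_type):
            sid = f"ref_{ct}_{r + 1}"
            noise = rng.normal(0.0, config.noise_sd, size=len(mu)) if config.noise_sd > 0 else 0.0
            v = expit(mu + noise)
            v = _compress_type2(v, is_type2, config.type2_compression)
            cols[sid] = v
            rows_sheet.append(
                {"sample_id": sid, "batch": "reference", "role": "reference",
                 "cell_type": ct, "group": "", "mutation_status": ""}
            )

    beta = BetaMatrix(pd.DataFrame(cols, index=means.index))
    sheet = SampleSheet(pd.DataFrame(rows_sheet).set_index("sample_id"))
    gt = GroundTruth(
        probe_roles=roles,
        ref_means=means,
        marker_probes=marker_probes,
        annotation=ann,
        cna_events=config.cna_events,
    )
    return beta, sheet, gt


# ---------------------------------------------------------------------------
# Tumour cohort
# ---------------------------------------------------------------------------

def generate_tumour_cohort(
    config: SimulationConfig,
    references: Tuple[BetaMatrix, SampleSheet, GroundTruth],
) -> Tuple[BetaMatrix, SampleSheet, GroundTruth]:
    """Tumours as noisy convex mixtures of the reference profiles.

    Each tumour's probe mean is the mixture of true reference means per
    its group weights, plus the group's subtype-signature shift on
    signature probes (logit scale), plus its batch shift, plus noise.
    """
    _, _, gt = references
    rng = _rng(config, 4)
    means = gt.ref_means
    types = list(config.cell_types)
    ann = gt.annotation
    is_type2 = (ann.table["design_type"] == "II").to_numpy()

    # disjoint signature probes drawn from neutral probes
    neutral = gt.probe_roles.index[gt.probe_roles == "neutral"].to_numpy()
    rng_sig = _rng(config, 5)
    pool = rng_sig.permutation(neutral)
    offset = 0
    signature: Dict[str, List[str]] = {}
    sig_shift: Dict[str, pd.Series] = {}
    for g in config.tumour_groups:
        chosen = pool[offset : offset + g.signature_size]
        offset += g.signature_size
        signature[g.label] = list(chosen)
        signs = np.where(rng_sig.random(len(chosen)) < 0.5, 1.0, -1.0)
        sig_shift[g.label] = pd.Series(signs * g.signature_shift, index=chosen)
        gt.probe_roles.loc[chosen] = f"signature:{g.label}"
    gt.signature_probes = signature

    batch_labels = [b for b, _ in config.batches]
    batch_shift = dict(config.batches)

    cols = {}
    rows = []
    counter = 0
    M = means[types].to_numpy()
    for g in config.tumour_groups:
        w_group = np.array([g.weights.get(ct, 0.0) for ct in types])
        shift_vec = np.zeros(M.shape[0])
        sel = means.index.get_indexer(sig_shift[g.label].index)
        shift_vec[sel] = sig_shift[g.label].to_numpy()
        for i in range(g.n):
            sid = f"tum_{g.label}_{i + 1:03d}"
            batch = batch_labels[counter % len(batch_labels)]
            counter += 1
            # per-sample compositional heterogeneity around the group weights
            if g.weight_jitter > 0 and w_group.sum() > 0:
                jit = w_group * np.exp(rng.normal(0.0, g.weight_jitter, size=len(types)))
                w = jit * (w_group.sum() / jit.sum())
            else:
                w = w_group
            mix = M @ w + (1.0 - w.sum()) * means[types].mean(axis=1).to_numpy()
            mu = _clamped_logit(mix)
            noise = rng.normal(0.0, config.noise_sd, size=len(mu)) if config.noise_sd > 0 else 0.0
            v = expit(mu + shift_vec + batch_shift[batch] + noise)
            v = _compress_type2(v, is_type2, config.type2_compression)
            cols[sid] = v
            muts = [gene for gene, p in g.mutation_probs.items() if rng.random() < p]
            rows.append(
                {"sample_id": sid, "batch": batch, "role": "tumour", "cell_type": "",
                 "group": g.label, "mutation_status": ";".join(muts),
                 **{f"weight_{ct}": w[k] for k, ct in enumerate(types)}}
            )

    beta = BetaMatrix(pd.DataFrame(cols, index=means.index))
    truth = pd.DataFrame(rows).set_index("sample_id")
    gt.sample_truth = truth
    sheet = SampleSheet(
        truth[["batch", "role", "cell_type", "group", "mutation_status"]].copy()
    )
    return beta, sheet, gt


# ---------------------------------------------------------------------------
# Intensities with copy-number events
# ---------------------------------------------------------------------------

def generate_intensities_with_cna(
    config: SimulationConfig,
    cohort: Tuple[BetaMatrix, SampleSheet, GroundTruth],
) -> IntensityMatrix:
    """Total-signal intensities with planted arm-level gains/losses.

    Baseline intensities are log-normal around a per-probe mean shared
    by all samples; probes on a planted (group, arm) event are scaled by
    2**log2_shift for samples of that group.
    """
    _, sheet, gt = cohort
    rng = _rng(config, 6)
    ann = gt.annotation
    probes = ann.probe_ids
    n = len(probes)
    base = np.exp(rng.normal(np.log(5000.0), 0.5, size=n))

    chrom = ann.table["chromosome"].to_numpy()
    arm = ann.table["arm"].to_numpy()
    event_mask: Dict[str, np.ndarray] = {}
    for ev in config.cna_events:
        m = (chrom == ev.chromosome) & (arm == ev.arm)
        event_mask.setdefault(ev.group, np.zeros(n))
        event_mask[ev.group] = event_mask[ev.group] + ev.log2_shift * m

    cols = {}
    for sid, row in sheet.table.iterrows():
        shift = event_mask.get(row.get("group", ""), np.zeros(n))
        noise = (
            rng.normal(0.0, config.intensity_noise_sd, size=n)
            if config.intensity_noise_sd > 0
            else 0.0
        )
        cols[sid] = base * np.exp2(shift + noise)
    return IntensityMatrix(pd.DataFrame(cols, index=probes))


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def generate_survival(
    config: SimulationConfig,
    cohort: Tuple[BetaMatrix, SampleSheet, GroundTruth],
) -> SampleSheet:
    """Exponential relapse times with group hazards, uniform censoring."""
    _, sheet, gt = cohort
    rng = _rng(config, 7)
    hazards = {g.label: g.relapse_hazard for g in config.tumour_groups}
    t = sheet.table.copy()
    times, events = [], []
    for sid, row in t.iterrows():
        lam = hazards.get(row.get("group", ""), 0.0)
        relapse = rng.exponential(1.0 / lam) if lam > 0 else np.inf
        censor = rng.uniform(0.0, config.censor_max_months)
        times.append(round(min(relapse, censor), 2))
        events.append(int(relapse <= censor))
    t["relapse_time"] = times
    t["relapse_event"] = events
    return SampleSheet(t)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SimulationConfig
    annotation: ProbeAnnotation
    reference_beta: BetaMatrix
    reference_sheet: SampleSheet
    tumour_beta: BetaMatrix
    tumour_sheet: SampleSheet
    intensities: IntensityMatrix
    ground_truth: GroundTruth


def simulate_cohort(config: Optional[SimulationConfig] = None) -> SyntheticCohort:
    """Generate the complete synthetic cohort in one call."""
    config = config or SimulationConfig()
    ref = generate_reference_profiles(config)
    tum_beta, tum_sheet, gt = generate_tumour_cohort(config, ref)
    combined_sheet = SampleSheet(pd.concat([ref[1].table, tum_sheet.table]))
    intens = generate_intensities_with_cna(config, (tum_beta, combined_sheet, gt))
    tum_sheet = generate_survival(config, (tum_beta, tum_sheet, gt))
    return SyntheticCohort(
        config=config,
        annotation=gt.annotation,
        reference_beta=ref[0],
        reference_sheet=ref[1],
        tumour_beta=tum_beta,
        tumour_sheet=tum_sheet,
        intensities=intens,
        ground_truth=gt,
    )


def write_fixture_bundle(config: SimulationConfig, out_dir) -> Dict[str, Path]:
    """Emit the full cohort as delimited-text files plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    paths = {
        "annotation": mio.write_annotation(cohort.annotation, out / "annotation.tsv"),
        "reference_beta": mio.write_beta_matrix(cohort.reference_beta, out / "reference_beta.tsv"),
        "reference_sheet": mio.write_sample_sheet(cohort.reference_sheet, out / "reference_sheet.csv"),
        "tumour_beta": mio.write_beta_matrix(cohort.tumour_beta, out / "tumour_beta.tsv"),
        "tumour_sheet": mio.write_sample_sheet(cohort.tumour_sheet, out / "tumour_sheet.csv"),
        "intensities": mio.write_intensity_matrix(cohort.intensities, out / "intensities.tsv"),
    }
    truth = cohort.ground_truth
    roles_path = out / "ground_truth_probes.tsv"
    truth.probe_roles.to_frame().to_csv(roles_path, sep="\t")
    paths["ground_truth_probes"] = roles_path
    if truth.sample_truth is not None:
        st_path = out / "ground_truth_samples.tsv"
        truth.sample_truth.to_csv(st_path, sep="\t")
        paths["ground_truth_samples"] = st_path
    return paths
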