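"""End-to-end orchestration of the cell-of-origin analysis.

Stages run in a fixed order (simulate -> preprocess -> differential
methylation -> phyloepigenetic tree -> deconvolution/classification ->
subtype consensus -> copy number -> survival), each stage's randomness
drawn from a substream derived by stable hashing of the stage name, so
adding a stage never shifts another's random numbers. All artifacts are
plain text; a machine-readable summary collects the headline numbers.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as mio
from .containers import BetaMatrix, SampleSheet, ValidationError
from .cna import CNAParams, infer_cna
from .deconv import classify_origin, estimate_fractions, select_markers
from .diffmeth import DMParams, differential_methylation
from .phylo import clade_membership, correlation_distance, nj_tree, root_tree
from .preprocess import FilterSpec, bmiq_normalize, combat_adjust, filter_probes
from .simulate import SimulationConfig, simulate_cohort
from .subtype import ConsensusParams, TFCheckpointSpec, build_signature, consensus_cluster, select_k, select_tf_probes
from .survival import logrank_test, survival_table

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed by stable hashing of the stage name."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """One config object driving the full pipeline run."""

    seed: int = 0
    out_dir: Path = Path("methorigin_out")
    simulation: Optional[SimulationConfig] = None  # None -> defaults with derived seed
    filters: FilterSpec = field(default_factory=FilterSpec)
    dm_params: DMParams = field(default_factory=DMParams)
    n_screen: int = 10_000
    n_markers: int = 500
    similarity_threshold: float = 65.0
    consensus: ConsensusParams = field(default_factory=lambda: ConsensusParams(k_max=10, reps=250))
    tf_spec: TFCheckpointSpec = field(default_factory=TFCheckpointSpec)
    cna_params: CNAParams = field(default_factory=CNAParams)
    run_bmiq: bool = True
    run_combat: bool = True


def run_full_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages and write per-stage artifacts plus a summary.

    Returns the summary dict; artifacts land under ``config.out_dir``.
    Any stage error aborts with the stage name; partial outputs are
    retained next to a FAILED marker naming the stage and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict = {"seed": int(config.seed), "stages": []}
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        sim_cfg = config.simulation or SimulationConfig(seed=stage_seed(config.seed, "simulate"))
        cohort = simulate_cohort(sim_cfg)
        ann = cohort.annotation
        summary["stages"].append(stage)
        summary["n_probes"] = int(sim_cfg.n_probes)
        summary["n_tumours"] = int(cohort.tumour_beta.shape[1])

        # ------------------------------------------------------------------
        stage = "preprocess"
        ref_beta = filter_probes(cohort.reference_beta, ann, config.filters)
        tum_beta = filter_probes(cohort.tumour_beta, ann, config.filters)
        if config.run_bmiq:
            ref_beta = bmiq_normalize(ref_beta, ann)
            tum_beta = bmiq_normalize(tum_beta, ann)
        if config.run_combat:
            batches = cohort.tumour_sheet.table["batch"]
            if batches.nunique() > 1:
                tum_beta = combat_adjust(tum_beta, batches.tolist())
        mio.write_beta_matrix(ref_beta, out / "reference_normalized.tsv")
        mio.write_beta_matrix(tum_beta, out / "tumour_normalized.tsv")
        summary["stages"].append(stage)
        summary["n_probes_retained"] = int(tum_beta.shape[0])

        # ------------------------------------------------------------------
        stage = "diff"
        refs = cohort.reference_sheet.table
        ab = refs.index[refs["cell_type"].isin(["alpha", "beta"])].tolist()
        ab_beta = ref_beta.select_samples(ab)
        dm_result, dm_sites = differential_methylation(
            ab_beta, refs.loc[ab, "cell_type"].tolist(), config.dm_params
        )
        dm_result.to_csv(out / "dm_alpha_vs_beta.tsv", sep="\t", float_format="%.6g")
        retained = [p for p in dm_sites if p in tum_beta.probe_ids]
        summary["stages"].append(stage)
        summary["n_dm_alpha_beta"] = len(dm_sites)
        summary["n_dm_retained"] = len(retained)

        # ------------------------------------------------------------------
        stage = "tree"
        combined = BetaMatrix(
            pd.concat([ref_beta.select_samples(ab).values, tum_beta.values], axis=1)
        )
        dist = correlation_distance(combined, retained)
        tree = nj_tree(dist)
        beta_root = refs.index[refs["cell_type"] == "beta"][0]
        rooted = root_tree(tree, beta_root)
        mio.write_newick(rooted, out / "phyloepigenetic_tree.nwk")
        ref_tips = {sid: refs.loc[sid, "cell_type"] for sid in ab}
        clades = clade_membership(tree, ref_tips)
        clades.to_csv(out / "clade_membership.tsv", sep="\t", float_format="%.6g")
        summary["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "deconv"
        ref_set = select_markers(
            ref_beta, cohort.reference_sheet, config.n_screen, config.n_markers
        )
        fractions = estimate_fractions(tum_beta.values, ref_set)
        fractions.to_csv(out / "cell_fractions.tsv", sep="\t", float_format="%.6g")
        calls = classify_origin(fractions, config.similarity_threshold)
        calls.to_csv(out / "origin_calls.tsv", sep="\t", float_format="%.6g")
        origin_counts = calls["label"].value_counts().to_dict()
        summary["stages"].append(stage)
        summary["origin_group_sizes"] = {k: int(v) for k, v in sorted(origin_counts.items())}

        # ------------------------------------------------------------------
        stage = "subtype"
        labels = calls["label"]
        if labels.nunique() == 3 and labels.value_counts().min() >= 2:
            signature = build_signature(tum_beta, labels.tolist(), config.dm_params)
        else:
            signature = retained
        cons_params = replace(config.consensus, seed=stage_seed(config.seed, "consensus"))
        cons = consensus_cluster(tum_beta, signature, cons_params)
        chosen_k = select_k(cons)
        cons.assignments_frame().to_csv(out / "consensus_assignments.tsv", sep="\t")
        tf_alpha = select_tf_probes(ann, config.tf_spec, "alpha")
        tf_beta = select_tf_probes(ann, config.tf_spec, "beta")
        summary["stages"].append(stage)
        summary["signature_size"] = len(signature)
        summary["chosen_k"] = int(chosen_k)
        summary["n_tf_probes_alpha"] = len(tf_alpha)
        summary["n_tf_probes_beta"] = len(tf_beta)

        # ------------------------------------------------------------------
        stage = "cna"
        ref_ids = cohort.reference_sheet.table.index.tolist()
        cna_res = infer_cna(cohort.intensities, ann, ref_ids, config.cna_params)
        cna_res.arm_cn.to_csv(out / "arm_copy_number.tsv", sep="\t", float_format="%.6g")
        first_sample = cna_res.log_ratios.columns[0]
        mio.write_segments_bed(cna_res.bins[first_sample], out / "cna_bins_first_sample.bed")
        if cna_res.groups is not None:
            cna_res.groups.to_csv(out / "cna_groups.tsv", sep="\t")
            summary["cna_group_sizes"] = {
                int(k): int(v) for k, v in cna_res.groups.value_counts().sort_index().items()
            }
        summary["stages"].append(stage)

        # ------------------------------------------------------------------
        stage = "survival"
        sheet = cohort.tumour_sheet.table.copy()
        sheet["origin"] = calls["label"].reindex(sheet.index)
        surv_sheet = SampleSheet(sheet)
        table = survival_table(surv_sheet, group_col="origin")
        if table["group"].nunique() >= 2 and table["event"].sum() >= 1:
            lr = logrank_test(table)
            summary["logrank"] = {k: (float(v) if k != "df" else int(v)) for k, v in lr.items()}
        table.to_csv(out / "survival_table.tsv", sep="\t", float_format="%.6g")
        summary["stages"].append(stage)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
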