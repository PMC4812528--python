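"""End-to-end orchestration: classify -> burden test -> filters -> combine -> candidates.

Stages run in the study's design order: per-pathway classification on the
training cohort, transfer/validation on further cohorts, pathway mutation
association, the treatment-effect filter, the BRCA1/2-vs-BRCAX subgroup
filter, rank-based evidence combination, and the candidate funnel. A
single seed fans out to per-stage child seeds via a counter-based scheme
so any stage can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from pathrisk.classify import ClassifierConfig, classify_pathways, results_to_frame
from pathrisk.gene_sets import GeneSetCollection
from pathrisk.meta import evidence_from_tables, select_candidate_pathways
from pathrisk.simulate import SimulationConfig, simulate_expression_cohort, simulate_variant_table
from pathrisk.variants import (
    MutationMatrix,
    VariantFilterConfig,
    collapse_to_genes,
    collapse_to_pathways,
    exclude_frequent_genes,
    filter_variants,
    pathway_mutation_association,
    select_frequency_threshold,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class _stage:
    """Re-raise any stage failure with the stage name attached."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise StageError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)


@dataclass
class PipelineConfig:
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    variant_filter: VariantFilterConfig = field(default_factory=VariantFilterConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha_rank: float = 0.05
    alpha_filter: float = 0.05
    alpha_ancova: float = 0.01
    fdr_cutoff: float = 0.2
    cohort_labels: tuple[str, ...] = ("utah", "ontario")
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _brca_subgroup_flags(
    pathway_matrix: MutationMatrix,
    annotations,
    alpha: float,
) -> set[str]:
    """Pathways whose mutation rates differ between BRCA1/2 carriers and BRCAX.

    The unconditional exact test is applied once in each direction; a
    pathway is flagged when either one-sided P falls below alpha.
    """
    status = {a.sample_id: a.brca_status for a in annotations}
    ids = pathway_matrix.sample_ids
    keep = [i for i, s in enumerate(ids) if status.get(s) in ("carrier", "BRCAX")]
    if not keep:
        return set()
    sub = MutationMatrix(level="pathway", matrix=pathway_matrix.matrix.iloc[keep])
    y = np.array([1 if status[ids[i]] == "carrier" else 0 for i in keep])
    if y.sum() == 0 or y.sum() == len(y):
        return set()
    res = pathway_mutation_association(sub, y, mode="each-direction")
    flagged = res.loc[(res["p_greater"] < alpha) | (res["p_less"] < alpha), "pathway"]
    return set(flagged)


def run_mutation_stage(
    variant_list,
    background_freqs,
    annotations,
    collection: GeneSetCollection,
    config: PipelineConfig,
):
    """Cascade -> gene matrix -> frequent-gene exclusion -> pathway matrix -> burden P."""
    sample_ids = [a.sample_id for a in annotations]
    retained, rule_counts = filter_variants(variant_list, len(sample_ids), config.variant_filter)
    gene_matrix = collapse_to_genes(retained, sample_ids)
    lo, hi = config.variant_filter.freq_gene_grid
    threshold, curve = select_frequency_threshold(
        background_freqs, (lo, hi), config.variant_filter.freq_gene_grid_points
    )
    gene_matrix = exclude_frequent_genes(
        gene_matrix, background_freqs, threshold, config.variant_filter.always_keep_genes
    )
    pathway_matrix = collapse_to_pathways(gene_matrix, collection)
    y = np.array([int(a.family_history and a.developed_cancer) for a in annotations])
    assoc = pathway_mutation_association(pathway_matrix, y, mode="one-direction")
    brca_flags = _brca_subgroup_flags(pathway_matrix, annotations, config.alpha_filter)
    return {
        "retained": retained,
        "rule_counts": rule_counts,
        "gene_matrix": gene_matrix,
        "pathway_matrix": pathway_matrix,
        "threshold": threshold,
        "threshold_curve": curve,
        "association": assoc,
        "brca_flags": brca_flags,
    }


def run_synthetic_study(config: PipelineConfig) -> dict:
    """Full pipeline on synthetic cohorts; returns the run report.

    Classification is restricted to family-history samples (cases = women
    who developed cancer), the treatment filter uses each full cohort, the
    mutation stage runs on the first cohort's samples, and evidence is
    combined by rank consistency over all expression datasets plus the
    mutation dataset.
    """
    sim = replace(config.simulation, seed=config.stage_seed("simulate"))
    p_tables: dict[str, pd.Series] = {}
    flags: dict[str, set[str]] = {}
    per_cohort_results = {}
    truth = None
    first_annotations = None
    for label in config.cohort_labels:
        with _stage(f"simulate:{label}"):
            cohort, truth = simulate_expression_cohort(sim, label)
        if first_annotations is None:
            first_annotations = cohort.annotations
        clf = replace(config.classifier, seed=config.stage_seed(f"classify:{label}"))
        fh_mask = [a.family_history for a in cohort.annotations]
        fh_cohort = cohort.subset(fh_mask)
        with _stage(f"classify:{label}"):
            results = classify_pathways(fh_cohort, truth["collection"], clf, apply_treatment_filter=False)
        if label == config.cohort_labels[0]:
            # the treatment filter is a single step on the training cohort:
            # rescore each pathway's panel over the full cohort (the
            # non-family-history arm included) and compare the two control
            # groups
            from pathrisk.classify import crossval_scores, treatment_effect_filter

            for r in results:
                Xfull = cohort.matrix[r.ranked_genes[: r.selected_k]].to_numpy()
                yfull = cohort.labels("developed_cancer")
                scores = crossval_scores(Xfull, yfull, config=clf, calibrate=True, seed=clf.seed)
                excl, tp = treatment_effect_filter(scores, cohort.annotations, config.alpha_filter)
                r.excluded_by_treatment_filter, r.treatment_p = excl, tp
                if excl:
                    flags.setdefault(r.pathway, set()).add("treatment_effect")
        frame = results_to_frame(results)
        p_tables[label] = frame.set_index("pathway")["perm_p"]
        per_cohort_results[label] = frame
        logger.info("cohort %s: %d pathways classified", label, len(frame))

    with _stage("mutation"):
        variant_list, background, _vtruth = simulate_variant_table(sim, annotations=first_annotations)
        mut = run_mutation_stage(variant_list, background, first_annotations, truth["collection"], config)
    p_tables["mutation"] = mut["association"].set_index("pathway")["p"]
    for pw in mut["brca_flags"]:
        flags.setdefault(pw, set()).add("brca_subgroup")

    with _stage("combine"):
        p_matrix = pd.DataFrame(p_tables)
        evidence = evidence_from_tables(p_matrix, flags=flags)
        candidates, funnel = select_candidate_pathways(
            evidence, alpha=config.alpha_rank, required_datasets=list(p_tables)
        )
    return {
        "config": config,
        "truth": truth,
        "per_cohort": per_cohort_results,
        "mutation": mut,
        "p_matrix": p_matrix,
        "evidence": evidence,
        "candidates": candidates,
        "funnel": funnel,
    }


def write_report(report: dict, out_dir: str | Path) -> dict:
    """Persist run artifacts (TSV tables + JSON funnel with provenance)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = report["config"]
    for label, frame in report["per_cohort"].items():
        frame.round(6).to_csv(out / f"classification_{label}.tsv", sep="\t", index=False)
    report["p_matrix"].round(6).to_csv(out / "p_matrix.tsv", sep="\t")
    report["mutation"]["association"].round(6).to_csv(out / "mutation_association.tsv", sep="\t", index=False)
    report["mutation"]["threshold_curve"].to_csv(out / "threshold_curve.tsv", sep="\t", index=False)
    provenance = {
        "schema_version": 1,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(str(asdict(config)), sort_keys=True).encode()
        ).hexdigest()[:16],
        "funnel": report["funnel"],
        "candidates": [e.pathway for e in report["candidates"]],
        "frequent_gene_threshold": report["mutation"]["threshold"],
        "cascade_rule_counts": report["mutation"]["rule_counts"],
    }
    (out / "run_report.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return provenance
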