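"""Synthetic cohorts with known ground truth.

Generates every input the pipeline consumes: pathway gene sets, expression
cohorts with signal planted in causal pathways for familial cases only,
clinical covariates tied to a minority of genes, annotated germline
variant tables with case enrichment plus decoys that exercise every
filtering rule, background gene-frequency tables with a high-frequency
block, and three-channel fluorescence fields for two morphological
phenotypes (compact clusters of small cells vs dispersed large cells).

Everything is deterministic given (config, seed); cohort labels derive
child seeds so the same pathway structure underlies all cohorts of a
study. Strata sizes follow deterministic allocation (rounding, not
sampling), mirroring the case/control composition of the source cohorts:
family-history women split between eventual cases and cancer-free
controls, roughly 40% of family-history women carrying a BRCA1/2
mutation, and a no-family-history control arm of whom about half
developed sporadic cancer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pathrisk.cohort import ExpressionCohort, SampleAnnotation
from pathrisk.gene_sets import GeneSet, GeneSetCollection
from pathrisk.morphology import FluorescenceField
from pathrisk.variants import AnnotatedVariant


@dataclass
class SimulationConfig:
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (20, 40)
    n_causal_pathways: int = 5
    causal_gene_fraction: float = 0.30
    effect_size: float = 1.0  # standardized mean shift, SD units
    n_cases: int = 40
    n_controls_fh: int = 40
    n_controls_nofh: int = 20
    carrier_fraction_fh: float = 0.40
    nofh_cancer_fraction: float = 0.55
    noise_correlation: float = 0.2
    mutation_rate_null: float = 0.002  # per-gene carrier probability
    mutation_rate_causal_cases: float = 0.35  # per-pathway carrier probability in cases
    frequent_gene_count: int = 10
    frequent_gene_freq: float = 0.05
    background_base_freq: float = 0.001
    decoys_per_rule: int = 2
    covariate_link_fraction: float = 0.02
    covariate_coverage: float = 0.5
    image_size: int = 256
    nuclei_count_range: tuple[int, int] = (10, 14)
    nucleus_radius: int = 6
    cell_radius_clustered: int = 12
    cell_radius_dispersed: int = 22
    actin_coverage_clustered: float = 0.35
    actin_coverage_dispersed: float = 0.60
    adhesion_coverage: float = 0.25
    image_noise: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_pathways > self.n_pathways:
            raise ValueError("n_causal_pathways must be <= n_pathways")
        for p in (
            self.causal_gene_fraction,
            self.noise_correlation,
            self.mutation_rate_null,
            self.mutation_rate_causal_cases,
            self.covariate_link_fraction,
            self.covariate_coverage,
        ):
            if not 0 <= p <= 1:
                raise ValueError("proportions must be in [0,1]")


def _child_seed(config: SimulationConfig, label: str) -> int:
    return (config.seed * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def pathway_structure(config: SimulationConfig) -> dict:
    """Pathway membership, causal pathways and signal genes (seed-deterministic).

    Pathways are disjoint gene blocks; causal pathways and the
    ``causal_gene_fraction`` of their members carrying signal are chosen
    once per config seed and shared by every cohort of the study.
    """
    rng = np.random.default_rng(_child_seed(config, "structure"))
    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    sets: list[GeneSet] = []
    gene_counter = 0
    for i, size in enumerate(sizes):
        genes = [f"G{gene_counter + j:05d}" for j in range(size)]
        gene_counter += size
        sets.append(GeneSet(name=f"PW{i:03d}", description=f"synthetic pathway {i}", genes=frozenset(genes)))
    collection = GeneSetCollection(sets=sets)
    causal = sorted(rng.choice(collection.names, size=config.n_causal_pathways, replace=False))
    signal_genes: dict[str, list[str]] = {}
    for name in causal:
        members = sorted(collection[name].genes)
        n_sig = max(1, round(config.causal_gene_fraction * len(members)))
        signal_genes[name] = sorted(rng.choice(members, size=n_sig, replace=False))
    return {"collection": collection, "causal_pathways": causal, "signal_genes": signal_genes}


def simulate_annotations(config: SimulationConfig, cohort_label: str) -> list[SampleAnnotation]:
    """Deterministic stratum allocation for one cohort.

    Cases are family-history women who developed cancer; controls are
    family-history women who did not, plus a no-family-history arm of whom
    ``nofh_cancer_fraction`` developed sporadic cancer. Carrier status is
    assigned to the first ``carrier_fraction_fh`` of each family-history
    stratum.
    """
    ann: list[SampleAnnotation] = []
    idx = 0

    def add(n: int, fh: bool, cancer: bool) -> None:
        nonlocal idx
        n_car = round(config.carrier_fraction_fh * n) if fh else 0
        for j in range(n):
            status = "carrier" if fh and j < n_car else ("BRCAX" if fh else "none")
            ann.append(
                SampleAnnotation(
                    sample_id=f"{cohort_label}_S{idx:03d}",
                    cohort=cohort_label,
                    family_history=fh,
                    brca_status=status,
                    developed_cancer=cancer,
                )
            )
            idx += 1

    add(config.n_cases, True, True)
    add(config.n_controls_fh, True, False)
    n_spor = round(config.nofh_cancer_fraction * config.n_controls_nofh)
    add(n_spor, False, True)
    add(config.n_controls_nofh - n_spor, False, False)
    return ann


def simulate_expression_cohort(
    config: SimulationConfig,
    cohort_label: str = "utah",
) -> tuple[ExpressionCohort, dict]:
    """Expression cohort with planted pathway signal; returns (cohort, truth).

    Gene values are correlated Gaussian noise (exchangeable correlation
    ``noise_correlation`` within pathway blocks); ``effect_size`` SD units
    are added to the signal genes of causal pathways for familial cases
    only, so the no-family-history arm stays null for the treatment filter.
    """
    truth = pathway_structure(config)
    collection: GeneSetCollection = truth["collection"]
    ann = simulate_annotations(config, cohort_label)
    rng = np.random.default_rng(_child_seed(config, f"expr:{cohort_label}"))
    n = len(ann)
    rho = config.noise_correlation
    cols: list[str] = []
    blocks: list[np.ndarray] = []
    for gs in collection:
        genes = sorted(gs.genes)
        shared = rng.standard_normal((n, 1))
        indep = rng.standard_normal((n, len(genes)))
        block = np.sqrt(rho) * shared + np.sqrt(1 - rho) * indep
        if gs.name in truth["signal_genes"]:
            case_mask = np.array([a.family_history and a.developed_cancer for a in ann])
            sig_idx = [genes.index(g) for g in truth["signal_genes"][gs.name]]
            block[np.ix_(case_mask, sig_idx)] += config.effect_size
        cols.extend(genes)
        blocks.append(block)
    matrix = pd.DataFrame(np.hstack(blocks), index=[a.sample_id for a in ann], columns=cols)
    cohort = ExpressionCohort(matrix=matrix, annotations=ann)
    truth = dict(truth)
    truth["cohort_label"] = cohort_label
    return cohort, truth


def simulate_covariates(
    config: SimulationConfig,
    cohort: ExpressionCohort,
) -> tuple[pd.DataFrame, list[str], ExpressionCohort]:
    """Clinical covariates on a partial sample subset, linked to a minority of genes.

    Returns (covariate table indexed by sample_id with NaN for uncovered
    samples, linked gene names, modified cohort). Linked genes get a
    0.8-per-SD contribution from one covariate, emulating immune/clinical
    confounding.
    """
    rng = np.random.default_rng(_child_seed(config, "covariates"))
    ids = cohort.sample_ids
    n = len(ids)
    cov = pd.DataFrame(
        {
            "lymphocyte_count": rng.normal(1.8, 0.4, n),
            "age_menarche": rng.normal(13.0, 1.5, n),
            "n_pregnancies": rng.integers(0, 6, n).astype(float),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    n_cover = round(config.covariate_coverage * n)
    uncovered = rng.choice(n, size=n - n_cover, replace=False)
    cov.iloc[uncovered] = np.nan
    n_linked = max(1, round(config.covariate_link_fraction * len(cohort.genes)))
    linked = sorted(rng.choice(cohort.genes, size=n_linked, replace=False))
    matrix = cohort.matrix.copy()
    full = np.random.default_rng(_child_seed(config, "covariates")).normal(1.8, 0.4, n)
    # expression is linked to the underlying covariate for all samples,
    # even where the survey did not cover them
    lym_z = (cov["lymphocyte_count"].fillna(pd.Series(full, index=cov.index)) - 1.8) / 0.4
    for g in linked:
        matrix[g] = matrix[g] + 0.8 * lym_z.to_numpy()
    return cov, linked, ExpressionCohort(matrix=matrix, annotations=cohort.annotations)


def simulate_variant_table(
    config: SimulationConfig,
    annotations: Sequence[SampleAnnotation] | None = None,
) -> tuple[list[AnnotatedVariant], dict[str, float], dict]:
    """Annotated variants with case enrichment; returns (variants, background freqs, truth).

    Per sample and gene, carriage is Bernoulli(``mutation_rate_null``); in
    causal pathways each familial case additionally carries a variant in
    one random member gene with probability ``mutation_rate_causal_cases``
    (a pathway-level rate, matching the gene->pathway OR collapse). Clean
    variants are rare, exonic and HIGH severity so they survive the
    cascade; ``decoys_per_rule`` extra variants are built to fail each
    rule. The background frequency table holds ``frequent_gene_count``
    non-causal genes at ``frequent_gene_freq`` against a base of
    ``background_base_freq``, which makes the threshold-selection
    breakpoint recoverable by construction.
    """
    truth = pathway_structure(config)
    collection: GeneSetCollection = truth["collection"]
    ann = list(annotations) if annotations is not None else simulate_annotations(config, "utah")
    rng = np.random.default_rng(_child_seed(config, "variants"))
    sample_ids = [a.sample_id for a in ann]
    case_ids = [a.sample_id for a in ann if a.family_history and a.developed_cancer]
    genes = sorted(collection.universe())
    carrier: dict[str, set[str]] = {g: set() for g in genes}
    null_draws = rng.random((len(sample_ids), len(genes))) < config.mutation_rate_null
    for i, s in enumerate(sample_ids):
        for j in np.nonzero(null_draws[i])[0]:
            carrier[genes[j]].add(s)
    for pw in truth["causal_pathways"]:
        members = sorted(collection[pw].genes)
        for s in case_ids:
            if rng.random() < config.mutation_rate_causal_cases:
                carrier[rng.choice(members)].add(s)

    variants: list[AnnotatedVariant] = []
    pos = 1000
    for g in genes:
        if not carrier[g]:
            continue
        pos += 10
        variants.append(
            AnnotatedVariant(
                chrom="1", pos=pos, ref="C", alt="T", gene=g, variant_class="SNV",
                severity="HIGH", is_missense=False, pop_af_max=0.001,
                background_af=0.001, deleterious_call="NA", in_exon_pad2=True,
                carriers=frozenset(carrier[g]),
            )
        )
    # decoys: each block fails exactly one cascade rule
    decoy_specs = [
        dict(pop_af_max=0.05),                                   # pop_af
        dict(background_af=0.10),                                # background_af
        dict(carriers=frozenset(sample_ids[: max(2, len(sample_ids) // 4)])),  # internal_freq
        dict(in_exon_pad2=False),                                # non_exonic
        dict(severity="LOW"),                                    # severity_effect
        dict(severity="MODERATE", variant_class="SNV", is_missense=True,
             deleterious_call="NA"),                             # missense_na
    ]
    for spec in decoy_specs:
        for _ in range(config.decoys_per_rule):
            pos += 10
            base = dict(
                chrom="1", pos=pos, ref="G", alt="A", gene=str(rng.choice(genes)),
                variant_class="SNV", severity="HIGH", is_missense=False,
                pop_af_max=0.001, background_af=0.001, deleterious_call="NA",
                in_exon_pad2=True,
                carriers=frozenset(rng.choice(sample_ids, size=2, replace=False)),
            )
            base.update(spec)
            variants.append(AnnotatedVariant(**base))

    non_causal_genes = sorted(
        set(genes) - {g for pw in truth["causal_pathways"] for g in collection[pw].genes}
    )
    frequent = sorted(rng.choice(non_causal_genes, size=config.frequent_gene_count, replace=False))
    background = {g: config.background_base_freq for g in genes}
    for g in frequent:
        background[g] = config.frequent_gene_freq
    truth = dict(truth)
    truth.update(
        {
            "carrier_sets": carrier,
            "frequent_genes": frequent,
            "case_ids": case_ids,
            "sample_ids": sample_ids,
        }
    )
    return variants, background, truth


# ---------------------------------------------------------------------------
# fluorescence fields


def _disk_mask(size: int, centers: np.ndarray, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    for r, c in centers:
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
    return mask


def _place_centers(
    rng: np.random.Generator,
    n: int,
    size: int,
    min_dist: float,
    spread: float | None,
) -> np.ndarray:
    """Sequential rejection placement; ``spread`` None = uniform over the field."""
    centers: list[tuple[float, float]] = []
    mid = size / 2
    attempts = 0
    sd = spread
    margin = 0.12 * size
    while len(centers) < n:
        if sd is None:
            cand = rng.uniform(margin, size - margin, size=2)
        else:
            cand = np.clip(rng.normal(mid, sd, size=2), margin, size - margin)
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_dist**2 for r, c in centers):
            centers.append((cand[0], cand[1]))
        attempts += 1
        if attempts % 200 == 0 and sd is not None:
            sd *= 1.2  # relax the cluster if packing stalls
    return np.asarray(centers)


def simulate_fluorescence_field(
    config: SimulationConfig,
    phenotype: str,
    seed: int | None = None,
) -> tuple[FluorescenceField, dict]:
    """Three-channel field for one phenotype; returns (field, ground truth).

    ``clustered_small``: nuclei tightly bunched, small cell footprints,
    lower actin coverage. ``dispersed_large``: nuclei spread across the
    field, large footprints, higher actin coverage. Ground truth records
    the placed centers and the exact mask-derived area and stain fractions.
    """
    if phenotype not in ("clustered_small", "dispersed_large"):
        raise ValueError(phenotype)
    rng = np.random.default_rng(_child_seed(config, f"image:{phenotype}") if seed is None else seed)
    S = config.image_size
    n = int(rng.integers(config.nuclei_count_range[0], config.nuclei_count_range[1] + 1))
    r_nuc = config.nucleus_radius
    if phenotype == "clustered_small":
        centers = _place_centers(rng, n, S, min_dist=2 * r_nuc + 5, spread=0.10 * S)
        cell_r = config.cell_radius_clustered
        actin_cov = config.actin_coverage_clustered
    else:
        centers = _place_centers(rng, n, S, min_dist=5 * r_nuc, spread=None)
        cell_r = config.cell_radius_dispersed
        actin_cov = config.actin_coverage_dispersed
    nuc_mask = _disk_mask(S, centers, r_nuc)
    cell_mask = _disk_mask(S, centers, cell_r)
    actin_hi = _disk_mask(S, centers, cell_r * np.sqrt(actin_cov)) & cell_mask
    adh_hi = _disk_mask(S, centers, cell_r * np.sqrt(config.adhesion_coverage)) & cell_mask

    def channel(hi_mask: np.ndarray) -> np.ndarray:
        # base cell signal close enough to the stain peak that a global
        # Otsu separates background from cells, not cells from stain
        img = np.full((S, S), 10.0)
        img[cell_mask] = 100.0
        img[hi_mask] = 180.0
        if config.image_noise > 0:
            img = img + rng.normal(0, config.image_noise, (S, S))
        return np.clip(img, 0, None)

    nuclei_img = np.full((S, S), 10.0)
    nuclei_img[nuc_mask] = 200.0
    if config.image_noise > 0:
        nuclei_img = np.clip(nuclei_img + rng.normal(0, config.image_noise, (S, S)), 0, None)

    field = FluorescenceField(
        actin=channel(actin_hi),
        adhesion=channel(adh_hi),
        nuclei=nuclei_img,
        group="high_risk" if phenotype == "clustered_small" else "control",
    )
    truth = {
        "n_nuclei": n,
        "centers": centers,
        "cell_area_fraction": float(cell_mask.mean()),
        "actin_fraction": float((actin_hi & cell_mask).sum() / cell_mask.sum()),
        "adhesion_fraction": float((adh_hi & cell_mask).sum() / cell_mask.sum()),
        "phenotype": phenotype,
    }
    return field, truth
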