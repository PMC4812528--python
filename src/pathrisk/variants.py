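"""Germline variant filtering cascade, gene/pathway collapsing, and exact burden tests.

The cascade keeps rare, exonic, likely-deleterious variants: population
MAF <= 1%, background-cohort MAF <= 3%, carried by <= 15% of study samples,
within primary-transcript exons +/- 2 bp, and passing the severity rules
(HIGH always retained; MODERATE InDels retained; missense SNVs retained
only when called deleterious; MODIFIER/LOW and remaining MODERATE SNVs
dropped). Heterozygous and homozygous carriage are treated identically.
A sample is "mutated" in a gene (or pathway) if it carries any retained
variant in that gene (or any member gene); multiplicity is discarded.

Pathway mutation rates between groups are compared with a one-sided
unconditional (Barnard) exact test: the score statistic is computed for
every achievable 2x2 table and the P-value is the supremum over the
nuisance success probability of the total probability of tables at least
as extreme as the observed one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from pathrisk.gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)

RULE_ORDER = (
    "pop_af",          # reference-population MAF above threshold
    "background_af",   # background germline cohort MAF above threshold
    "internal_freq",   # carried by too many study samples
    "non_exonic",      # outside primary-transcript exons +/- 2 bp
    "severity_effect", # MODIFIER/LOW, neutral missense, or non-missense MODERATE SNV
    "missense_na",     # missense SNV with no deleteriousness call (configurable)
)


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str  # SNV | InDel
    severity: str  # HIGH | MODERATE | LOW | MODIFIER
    is_missense: bool
    pop_af_max: float
    background_af: float
    deleterious_call: str  # deleterious | neutral | NA
    in_exon_pad2: bool
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based and >= 1")
        for f in (self.pop_af_max, self.background_af):
            if not 0 <= f <= 1:
                raise ValueError("frequencies must be in [0,1]")


@dataclass
class VariantFilterConfig:
    maf_pop: float = 0.01
    maf_background: float = 0.03
    internal_freq_max: float = 0.15
    freq_gene_threshold: float = 0.018
    freq_gene_grid: tuple[float, float] = (0.002, 0.10)
    freq_gene_grid_points: int = 50
    always_keep_genes: frozenset[str] = frozenset({"BRCA1", "BRCA2"})
    drop_missense_na: bool = True

    def __post_init__(self) -> None:
        for t in (self.maf_pop, self.maf_background, self.internal_freq_max, self.freq_gene_threshold):
            if not 0 < t < 1:
                raise ValueError("thresholds must be in (0,1)")
        if not self.freq_gene_grid[0] < self.freq_gene_grid[1]:
            raise ValueError("grid min must be < grid max")


@dataclass
class MutationMatrix:
    """Binary samples x units indicator matrix (units = genes or pathways)."""

    level: str  # gene | pathway
    matrix: pd.DataFrame  # index = sample_id, columns = unit ids, values {0,1}

    def __post_init__(self) -> None:
        if self.level not in ("gene", "pathway"):
            raise ValueError("level must be 'gene' or 'pathway'")
        vals = self.matrix.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be binary")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)


# ---------------------------------------------------------------------------
# filtering cascade


def _first_failing_rule(v: AnnotatedVariant, n_samples: int, cfg: VariantFilterConfig) -> str | None:
    if v.pop_af_max > cfg.maf_pop:
        return "pop_af"
    if v.background_af > cfg.maf_background:
        return "background_af"
    if len(v.carriers) / n_samples > cfg.internal_freq_max:
        return "internal_freq"
    if not v.in_exon_pad2:
        return "non_exonic"
    if v.severity in ("MODIFIER", "LOW"):
        return "severity_effect"
    if v.severity == "HIGH":
        return None
    # MODERATE
    if v.variant_class == "InDel":
        return None
    if v.is_missense:
        if v.deleterious_call == "deleterious":
            return None
        if v.deleterious_call == "neutral":
            return "severity_effect"
        # no call available
        return "missense_na" if cfg.drop_missense_na else None
    return "severity_effect"  # non-missense MODERATE SNV


def filter_variants(
    table: Sequence[AnnotatedVariant],
    n_samples: int,
    config: VariantFilterConfig | None = None,
) -> tuple[list[AnnotatedVariant], dict[str, int]]:
    """Apply the cascade; returns retained variants and per-rule exclusion counts.

    Each excluded variant is attributed to the first rule it fails, so
    ``len(table) == len(retained) + sum(counts.values())`` always holds.
    The internal-frequency rule counts carrier fraction (not alleles).
    """
    if not table:
        raise ValueError("variant table is empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = config or VariantFilterConfig()
    counts = {r: 0 for r in RULE_ORDER}
    retained: list[AnnotatedVariant] = []
    n_na = 0
    for v in table:
        rule = _first_failing_rule(v, n_samples, cfg)
        if rule is None:
            retained.append(v)
        else:
            counts[rule] += 1
            if rule == "missense_na":
                n_na += 1
    if n_na:
        logger.info("dropped %d missense SNVs with no deleteriousness call", n_na)
    return retained, counts


def collapse_to_genes(
    variants: Sequence[AnnotatedVariant],
    sample_ids: Sequence[str],
) -> MutationMatrix:
    """Binary samples x genes matrix: 1 iff the sample carries any retained variant."""
    genes = sorted({v.gene for v in variants})
    mat = pd.DataFrame(0, index=list(sample_ids), columns=genes, dtype=np.int8)
    known = set(sample_ids)
    for v in variants:
        for s in v.carriers:
            if s in known:
                mat.loc[s, v.gene] = 1
    return MutationMatrix(level="gene", matrix=mat)


def select_frequency_threshold(
    background_gene_freqs: Mapping[str, float],
    grid: tuple[float, float] = (0.002, 0.10),
    n_points: int = 50,
) -> tuple[float, pd.DataFrame]:
    """Pick the frequent-gene exclusion threshold from the count-vs-threshold curve.

    For each candidate t on an even grid, count genes with background
    frequency strictly above t; return the lower endpoint of the largest
    adjacent drop in that count (ties -> smallest t). The full curve is
    returned for auditing. If every frequency is below the grid minimum the
    grid minimum is returned with a warning.
    """
    if n_points < 2:
        raise ValueError("need >=2 grid points")
    lo, hi = grid
    if not (0 < lo < hi < 1):
        raise ValueError("grid must lie within (0,1)")
    ts = np.linspace(lo, hi, n_points)
    freqs = np.asarray(list(background_gene_freqs.values()), dtype=float)
    excluded = np.array([(freqs > t).sum() for t in ts])
    curve = pd.DataFrame({"threshold": ts, "n_excluded": excluded})
    if excluded[0] == 0:
        warnings.warn("all background frequencies below grid minimum", stacklevel=2)
        return float(ts[0]), curve
    drops = excluded[:-1] - excluded[1:]
    best = int(np.argmax(drops))  # argmax takes the first (smallest t) on ties
    return float(ts[best]), curve


def exclude_frequent_genes(
    gene_matrix: MutationMatrix,
    background_gene_freqs: Mapping[str, float],
    threshold: float = 0.018,
    always_keep: Iterable[str] = ("BRCA1", "BRCA2"),
) -> MutationMatrix:
    """Drop gene columns with background frequency strictly above the threshold.

    Genes absent from the background table count as frequency 0 (retained);
    ``always_keep`` genes are never dropped.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    keep_always = set(always_keep)
    cols = [
        g
        for g in gene_matrix.matrix.columns
        if g in keep_always or background_gene_freqs.get(g, 0.0) <= threshold
    ]
    return MutationMatrix(level="gene", matrix=gene_matrix.matrix[cols])


def collapse_to_pathways(
    gene_matrix: MutationMatrix,
    collection: GeneSetCollection,
) -> MutationMatrix:
    """Pathway entry is the OR over member-gene entries; empty pathways give zeros."""
    if gene_matrix.level != "gene":
        raise ValueError("input must be gene-level")
    gm = gene_matrix.matrix
    data = {}
    for gs in collection:
        members = [g for g in gs.genes if g in gm.columns]
        if members:
            data[gs.name] = (gm[members].to_numpy().max(axis=1)).astype(np.int8)
        else:
            logger.info("pathway %s has no genes in the mutation matrix", gs.name)
            data[gs.name] = np.zeros(len(gm), dtype=np.int8)
    return MutationMatrix(level="pathway", matrix=pd.DataFrame(data, index=gm.index))


# ---------------------------------------------------------------------------
# Barnard's unconditional exact test


def _score_statistics(n1: int, n2: int) -> np.ndarray:
    """Score (pooled-variance Wald) statistic for every (a,b) table, shape (n1+1, n2+1)."""
    a = np.arange(n1 + 1)[:, None]
    b = np.arange(n2 + 1)[None, :]
    p1 = a / n1
    p2 = b / n2
    pooled = (a + b) / (n1 + n2)
    denom = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p1 - p2) / denom
    return np.where(denom == 0, 0.0, t)


def _table_probabilities(n1: int, n2: int, pis: np.ndarray) -> np.ndarray:
    """P(a,b | pi) for all tables and all pi; shape (len(pis), n1+1, n2+1)."""
    a = np.arange(n1 + 1)
    b = np.arange(n2 + 1)
    c1 = special.comb(n1, a)
    c2 = special.comb(n2, b)
    pis = np.asarray(pis, dtype=float)[:, None]
    pmf1 = c1 * pis**a * (1 - pis) ** (n1 - a)  # (G, n1+1)
    pmf2 = c2 * pis**b * (1 - pis) ** (n2 - b)
    return np.einsum("ga,gb->gab", pmf1, pmf2)


def barnard_test(
    a: int,
    n1: int,
    b: int,
    n2: int,
    direction: str = "greater",
) -> float:
    """One-sided unconditional exact P for a 2x2 table of mutated/total counts.

    ``direction='greater'`` tests whether cases (a/n1) are more often
    mutated than controls (b/n2); ``'less'`` tests the opposite. The
    P-value is sup over the common success probability pi of the total
    probability of tables whose score statistic is at least as extreme as
    the observed one. The supremum is located on a grid of pi in
    {0.001, ..., 0.999} and sharpened by bounded local optimization.
    """
    if not (0 <= a <= n1 and 0 <= b <= n2 and n1 >= 1 and n2 >= 1):
        raise ValueError("invalid table counts")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    t = _score_statistics(n1, n2)
    t_obs = t[a, b]
    mask = t >= t_obs if direction == "greater" else t <= t_obs
    if mask.all():
        return 1.0

    grid = np.arange(0.001, 1.0, 0.001)
    probs = _table_probabilities(n1, n2, grid)
    vals = np.einsum("gab,ab->g", probs, mask.astype(float))
    i = int(np.argmax(vals))

    def neg(pi: float) -> float:
        return -float(np.einsum("ab,ab->", _table_probabilities(n1, n2, np.array([pi]))[0], mask))

    lo = grid[i - 1] if i > 0 else 1e-12
    hi = grid[i + 1] if i < len(grid) - 1 else 1 - 1e-12
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    best = max(float(vals[i]), -float(res.fun))
    return min(1.0, best)


def pathway_mutation_association(
    pathway_matrix: MutationMatrix,
    labels: Sequence[int],
    mode: str = "one-direction",
) -> pd.DataFrame:
    """Per-pathway Barnard exact P comparing mutation rates between label groups.

    ``mode='one-direction'`` tests cases-more-mutated only;
    ``'each-direction'`` reports both one-sided P-values (used for the
    BRCA1/2-vs-BRCAX subgroup comparison). All-zero pathways give P = 1.
    """
    if mode not in ("one-direction", "each-direction"):
        raise ValueError(mode)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(pathway_matrix.matrix):
        raise ValueError("labels must align with matrix rows")
    n1 = int(y.sum())
    n2 = len(y) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    M = pathway_matrix.matrix.to_numpy()
    a_counts = M[y == 1].sum(axis=0)
    b_counts = M[y == 0].sum(axis=0)
    cache: dict[tuple[int, int, str], float] = {}

    def cached(a: int, b: int, direction: str) -> float:
        key = (a, b, direction)
        if key not in cache:
            cache[key] = barnard_test(a, n1, b, n2, direction)
        return cache[key]

    rows = []
    for pw, a, b in zip(pathway_matrix.unit_ids, a_counts, b_counts):
        row = {"pathway": pw, "n_mut_cases": int(a), "n_mut_controls": int(b)}
        if a == 0 and b == 0:
            # nothing mutated anywhere: the observed table is the least
            # extreme possible in either direction
            row["p_greater"] = row["p_less"] = 1.0
            rows.append(row)
            continue
        row["p_greater"] = cached(int(a), int(b), "greater")
        if mode == "each-direction":
            row["p_less"] = cached(int(a), int(b), "less")
        rows.append(row)
    df = pd.DataFrame(rows)
    df["p"] = df["p_greater"] if mode == "one-direction" else df[["p_greater", "p_less"]].min(axis=1)
    return df


# ---------------------------------------------------------------------------
# IO

_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "variant_class", "severity",
    "is_missense", "pop_af_max", "background_af", "deleterious_call",
    "in_exon_pad2", "carriers",
]


def write_variants_tsv(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene, "variant_class": v.variant_class,
                "severity": v.severity, "is_missense": int(v.is_missense),
                "pop_af_max": v.pop_af_max, "background_af": v.background_af,
                "deleterious_call": v.deleterious_call,
                "in_exon_pad2": int(v.in_exon_pad2),
                "carriers": ",".join(sorted(v.carriers)),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[AnnotatedVariant]:
    """Flat-TSV carrier of annotated variants (columns as written by write_variants_tsv)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "carriers": str}, keep_default_na=False, na_values=[""])
    out = []
    for r in df.itertuples(index=False):
        carriers = frozenset(str(r.carriers).split(",")) if isinstance(r.carriers, str) and r.carriers else frozenset()
        out.append(
            AnnotatedVariant(
                chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
                gene=str(r.gene), variant_class=str(r.variant_class),
                severity=str(r.severity), is_missense=bool(int(r.is_missense)),
                pop_af_max=float(r.pop_af_max), background_af=float(r.background_af),
                deleterious_call=str(r.deleterious_call),
                in_exon_pad2=bool(int(r.in_exon_pad2)), carriers=carriers,
            )
        )
    return out


def read_exon_bed(path: str | Path, pad: int = 2) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals from BED (0-based half-open) to 1-based inclusive, padded."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start) + 1 - pad, int(end) + pad))
    return intervals


def _in_intervals(chrom: str, pos: int, intervals: Mapping[str, list[tuple[int, int]]]) -> bool:
    return any(lo <= pos <= hi for lo, hi in intervals.get(chrom, ()))


def read_variants_vcf(
    path: str | Path,
    exon_intervals: Mapping[str, list[tuple[int, int]]] | None = None,
) -> list[AnnotatedVariant]:
    """Read annotated variants from VCF.

    Annotations come from INFO fields GENE, SEV, MISSENSE, POPAF, BGAF,
    DELCALL; carriers are samples with any non-reference genotype
    (heterozygous and homozygous carriage are equivalent). ``in_exon_pad2``
    is filled from a supplied exon interval map (see :func:`read_exon_bed`);
    without one, every variant is treated as exonic.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else ""
        vclass = "SNV" if len(rec.REF) == 1 and len(alt) == 1 else "InDel"
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        carriers = frozenset(s for s, g in zip(samples, gts) if g in (1, 3))
        in_exon = True if exon_intervals is None else _in_intervals(rec.CHROM, rec.POS, exon_intervals)
        out.append(
            AnnotatedVariant(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt, gene=str(rec.INFO.get("GENE", "")),
                variant_class=vclass, severity=str(rec.INFO.get("SEV", "MODIFIER")),
                is_missense=bool(int(rec.INFO.get("MISSENSE", 0))),
                pop_af_max=float(rec.INFO.get("POPAF", 0.0)),
                background_af=float(rec.INFO.get("BGAF", 0.0)),
                deleterious_call=str(rec.INFO.get("DELCALL", "NA")),
                in_exon_pad2=in_exon, carriers=carriers,
            )
        )
    return out
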