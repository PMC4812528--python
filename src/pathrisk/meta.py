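"""Cross-dataset evidence combination and mutation-expression concordance.

Pathways are combined across datasets by rank consistency: within each
dataset pathways are ranked by ascending P, ranks are scaled to (0,1), and
a pathway's mean scaled rank over its observed datasets is referred to the
null that scaled ranks are i.i.d. uniform. Alternative combiners (Fisher,
Wilkinson minimum-P, Edgington sum-of-P) and Storey q-values support the
robustness checks. Concordance between germline mutation status and
expression of the same gene is screened by Spearman correlation with a
local-FDR cut.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PathwayEvidence:
    pathway: str
    p_by_dataset: dict[str, float] = field(default_factory=dict)
    rank_p: float = float("nan")
    alt_p: dict[str, float] = field(default_factory=dict)
    q_value: float = float("nan")
    flags: set[str] = field(default_factory=set)


@dataclass
class ConcordanceResult:
    gene: str
    rho: float
    local_fdr: float
    selected: bool


def rank_consistency_p(p_matrix: pd.DataFrame) -> pd.Series:
    """Combined one-sided P for consistently low rank across datasets.

    Within each dataset column, pathways are ranked by ascending P-value
    (average ranks for ties, missing entries ignored) and scaled to (0,1)
    as (rank - 0.5)/N. Under the null the scaled ranks are i.i.d. uniform;
    a pathway's mean scaled rank over its m observed datasets is referred
    to the exact Irwin-Hall distribution of a sum of m uniforms (for m = 1
    this is the scaled rank itself). Beyond m = 20 the alternating-series
    tail is numerically unstable and the Normal(1/2, 1/(12m)) limit is
    used instead; the normal approximation is orders of magnitude too
    large in the deep tail at small m, which matters for top-ranked
    pathways.
    """
    if p_matrix.shape[1] < 1:
        raise ValueError("need at least one dataset column")
    scaled = pd.DataFrame(index=p_matrix.index, columns=p_matrix.columns, dtype=float)
    for col in p_matrix.columns:
        s = p_matrix[col]
        obs = s.dropna()
        if len(obs) == 0:
            continue
        if obs.nunique() == 1:
            warnings.warn(f"dataset {col!r}: all P equal; contributes nothing", stacklevel=2)
        r = obs.rank(method="average")
        scaled.loc[obs.index, col] = (r - 0.5) / len(obs)
    m = scaled.notna().sum(axis=1)
    mean_rank = scaled.mean(axis=1)
    out = pd.Series(np.nan, index=p_matrix.index, dtype=float)
    for idx in p_matrix.index:
        mi = int(m.loc[idx])
        if mi == 0:
            continue
        out.loc[idx] = _irwin_hall_cdf(mi * mean_rank.loc[idx], mi)
    return out


def _irwin_hall_cdf(s: float, m: int) -> float:
    """P(sum of m i.i.d. Uniform(0,1) <= s); normal limit beyond m = 20."""
    if s <= 0:
        return 0.0
    if s >= m:
        return 1.0
    if m > 20:
        return float(stats.norm.cdf((s - m / 2.0) / math.sqrt(m / 12.0)))
    total = 0.0
    for j in range(int(math.floor(s)) + 1):
        total += (-1) ** j * math.comb(m, j) * (s - j) ** m
    return float(min(1.0, max(0.0, total / math.factorial(m))))


def combine_p(ps: Sequence[float], method: str = "fisher") -> float:
    """Combine independent P-values; every method reduces to identity at m = 1.

    fisher: -2 sum(log p) against chi-square with 2m df.
    wilkinson_min: minimum P against its Beta(1, m) null, 1 - (1-pmin)^m.
    sum_p: Edgington's sum of P with the exact piecewise-polynomial
    (Irwin-Hall) tail.
    """
    p = np.asarray(ps, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0,1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    m = p.size
    if method == "fisher":
        stat = -2.0 * np.sum(np.log(p))
        return float(stats.chi2.sf(stat, 2 * m))
    if method == "wilkinson_min":
        return float(1.0 - (1.0 - p.min()) ** m)
    if method == "sum_p":
        s = float(p.sum())
        # Irwin-Hall lower tail: P(sum of m uniforms <= s)
        total = 0.0
        for j in range(int(math.floor(s)) + 1):
            total += (-1) ** j * math.comb(m, j) * (s - j) ** m
        return float(min(1.0, max(0.0, total / math.factorial(m))))
    raise ValueError(f"unknown method {method!r}")


def storey_qvalues(
    ps: Sequence[float],
    lambdas: Sequence[float] | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the lambda grid
    (default 0.05..0.95 step 0.05); a cubic smoother is evaluated at the
    largest lambda and clamped to (0, 1]. q-values are the monotone
    step-down transform q(i) = min_{j>=i} pi0 * m * p(j) / j.
    """
    p = np.asarray(ps, dtype=float)
    m = p.size
    if m < 10:
        warnings.warn("fewer than 10 p-values; pi0 estimate is unstable", stacklevel=2)
    if np.unique(p).size == 1:
        return p.copy(), 1.0
    lam = np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas, dtype=float)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    try:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam.max()))
    except np.linalg.LinAlgError:
        pi0 = float(pi0_lam[-1])
    pi0 = min(1.0, max(pi0, 1.0 / m))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def select_candidate_pathways(
    evidence: Sequence[PathwayEvidence],
    alpha: float = 0.05,
    required_datasets: Iterable[str] = (),
) -> tuple[list[PathwayEvidence], dict[str, int]]:
    """Apply the candidate funnel; returns (ordered candidates, step counts).

    Steps: all pathways -> observed in every required dataset -> combined
    rank P < alpha -> no treatment-effect flag -> no BRCA-subgroup flag.
    Counts are non-increasing by construction. Candidates are ordered by
    ascending rank P.
    """
    required = set(required_datasets)
    funnel = {"total": len(evidence)}
    stage = [e for e in evidence if required <= set(e.p_by_dataset)]
    funnel["in_all_required_datasets"] = len(stage)
    stage = [e for e in stage if not math.isnan(e.rank_p) and e.rank_p < alpha]
    funnel["rank_p_below_alpha"] = len(stage)
    stage = [e for e in stage if "treatment_effect" not in e.flags]
    funnel["after_treatment_filter"] = len(stage)
    stage = [e for e in stage if "brca_subgroup" not in e.flags]
    funnel["after_brca_subgroup_filter"] = len(stage)
    stage.sort(key=lambda e: (e.rank_p, e.pathway))
    return stage, funnel


def _local_fdr(z: np.ndarray) -> np.ndarray:
    """Local FDR by central matching against an empirical Gaussian null.

    Null location/scale from the median and the central interquartile
    range; the marginal density by Gaussian KDE; pi0 by matching the
    densities at the null center. lfdr = min(1, pi0 f0(z) / f(z)).
    """
    mu0 = float(np.median(z))
    iqr = float(np.subtract(*np.percentile(z, [75, 25])))
    sd0 = max(iqr / 1.349, 1e-8)
    f0 = stats.norm.pdf(z, mu0, sd0)
    kde = stats.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    pi0 = min(1.0, float(kde(mu0)[0]) / stats.norm.pdf(mu0, mu0, sd0))
    return np.minimum(1.0, pi0 * f0 / f)


def mutation_expression_concordance(
    expr,
    gene_matrix,
    fdr_cutoff: float = 0.2,
) -> tuple[list[ConcordanceResult], int]:
    """Per-gene Spearman correlation of mutation status with expression.

    Computed over samples shared between the expression cohort and the
    gene-level mutation matrix; genes with a constant mutation vector are
    skipped (their count is returned). Correlations are Fisher-transformed
    to z-scores scaled by sqrt(n-3) and screened by local FDR; a gene is
    selected iff its local FDR <= ``fdr_cutoff``.
    """
    shared_samples = [s for s in expr.sample_ids if s in set(gene_matrix.sample_ids)]
    if len(shared_samples) < 5:
        raise ValueError("need >=5 shared samples")
    shared_genes = [g for g in expr.genes if g in set(gene_matrix.unit_ids)]
    E = expr.matrix.loc[shared_samples, shared_genes]
    M = gene_matrix.matrix.loc[shared_samples, shared_genes]
    n = len(shared_samples)
    genes, rhos = [], []
    skipped = 0
    for g in shared_genes:
        mv = M[g].to_numpy()
        if mv.min() == mv.max():
            skipped += 1
            continue
        rho = stats.spearmanr(mv, E[g].to_numpy()).statistic
        genes.append(g)
        rhos.append(float(rho))
    if not genes:
        return [], skipped
    rho_arr = np.clip(np.asarray(rhos), -0.999999, 0.999999)
    z = np.arctanh(rho_arr) * math.sqrt(max(n - 3, 1))
    if len(z) >= 10:
        lfdr = _local_fdr(z)
    else:
        warnings.warn("too few testable genes for local-FDR estimation; none selected", stacklevel=2)
        lfdr = np.ones(len(z))
    results = [
        ConcordanceResult(gene=g, rho=r, local_fdr=float(l), selected=bool(l <= fdr_cutoff))
        for g, r, l in zip(genes, rhos, lfdr)
    ]
    return results, skipped


def evidence_from_tables(
    p_matrix: pd.DataFrame,
    flags: Mapping[str, set[str]] | None = None,
    alt_methods: Sequence[str] = ("fisher", "wilkinson_min", "sum_p"),
) -> list[PathwayEvidence]:
    """Build PathwayEvidence records from a pathways x datasets P table."""
    flags = flags or {}
    rank_p = rank_consistency_p(p_matrix)
    records: list[PathwayEvidence] = []
    for pw in p_matrix.index:
        row = p_matrix.loc[pw].dropna()
        missing = set(p_matrix.columns) - set(row.index)
        f = set(flags.get(pw, flags.get(str(pw), set())))
        if missing:
            f.add("missing_in_dataset")
        alt = {m: combine_p(row.to_numpy(), m) for m in alt_methods} if len(row) else {}
        records.append(
            PathwayEvidence(
                pathway=str(pw),
                p_by_dataset=row.to_dict(),
                rank_p=float(rank_p.loc[pw]),
                alt_p=alt,
                flags=f,
            )
        )
    rank_ps = np.array([r.rank_p for r in records])
    ok = ~np.isnan(rank_ps)
    if ok.sum() >= 2:
        qs, _pi0 = storey_qvalues(rank_ps[ok])
        it = iter(qs)
        for r, good in zip(records, ok):
            if good:
                r.q_value = float(next(it))
    return records
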