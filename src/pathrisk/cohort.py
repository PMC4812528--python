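"""Sample annotations, cohort composition arithmetic, and the confounder screen.

Samples carry a family-history flag, BRCA1/2 mutation status and eventual
cancer status. Women with a family history but no known pathogenic BRCA1/2
mutation are labelled BRCAX; BRCA status other than ``none`` therefore
implies a family history. The confounder screen removes genes whose
expression tracks immune-cell counts or demographic/clinical survey fields
(multifactor ANCOVA, per-factor F-tests, raw P < 0.01 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BRCA_STATUSES = ("carrier", "BRCAX", "none")


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    cohort: str
    family_history: bool
    brca_status: str  # carrier | BRCAX | none
    developed_cancer: bool
    batch: str = "0"
    age_at_draw: float | None = None

    def __post_init__(self) -> None:
        if self.brca_status not in BRCA_STATUSES:
            raise ValueError(f"brca_status must be one of {BRCA_STATUSES}")
        if self.brca_status in ("carrier", "BRCAX") and not self.family_history:
            raise ValueError(
                f"{self.sample_id}: brca_status={self.brca_status} requires family_history=True"
            )


@dataclass
class ExpressionCohort:
    """Samples x genes expression matrix plus per-sample annotations."""

    matrix: pd.DataFrame  # index = sample_id, columns = gene symbols
    annotations: list[SampleAnnotation]

    def __post_init__(self) -> None:
        ids = [a.sample_id for a in self.annotations]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_ids in annotations")
        if list(self.matrix.index) != ids:
            raise ValueError("matrix row order must match annotation order")
        if self.matrix.isna().all(axis=0).any():
            raise ValueError("matrix contains all-missing gene columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.columns)

    def labels(self, which: str = "developed_cancer") -> np.ndarray:
        """Binary label vector (1 = positive class) for a given annotation field."""
        if which == "developed_cancer":
            return np.array([int(a.developed_cancer) for a in self.annotations])
        if which == "family_history":
            return np.array([int(a.family_history) for a in self.annotations])
        raise ValueError(which)

    def drop_genes(self, genes: Iterable[str]) -> "ExpressionCohort":
        drop = set(genes)
        keep = [g for g in self.matrix.columns if g not in drop]
        return ExpressionCohort(self.matrix[keep], self.annotations)

    def subset(self, mask: Sequence[bool]) -> "ExpressionCohort":
        mask = np.asarray(mask, dtype=bool)
        ann = [a for a, m in zip(self.annotations, mask) if m]
        return ExpressionCohort(self.matrix.loc[mask], ann)


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "cohort": [a.cohort for a in annotations],
            "family_history": [a.family_history for a in annotations],
            "brca_status": [a.brca_status for a in annotations],
            "developed_cancer": [a.developed_cancer for a in annotations],
            "batch": [a.batch for a in annotations],
            "age_at_draw": [a.age_at_draw for a in annotations],
        }
    ).set_index("sample_id")


def annotations_from_frame(df: pd.DataFrame) -> list[SampleAnnotation]:
    df = df.reset_index() if df.index.name == "sample_id" else df
    out = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age_at_draw", None)
        out.append(
            SampleAnnotation(
                sample_id=str(row.sample_id),
                cohort=str(row.cohort),
                family_history=bool(row.family_history),
                brca_status=str(row.brca_status),
                developed_cancer=bool(row.developed_cancer),
                batch=str(getattr(row, "batch", "0")),
                age_at_draw=None if age is None or (isinstance(age, float) and np.isnan(age)) else float(age),
            )
        )
    return out


def summarize_cohort(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    """Composition table: counts by family_history x brca_status x cancer.

    Returns one row per stratum (empty strata included with count 0) plus
    the fraction of the cohort in each stratum and the rounded percent.
    Counts always partition the cohort.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    total = len(annotations)
    rows = []
    for fh in (True, False):
        for brca in BRCA_STATUSES:
            if not fh and brca != "none":
                continue  # impossible stratum by construction
            for cancer in (True, False):
                n = sum(
                    1
                    for a in annotations
                    if a.family_history == fh and a.brca_status == brca and a.developed_cancer == cancer
                )
                rows.append(
                    {
                        "family_history": fh,
                        "brca_status": brca,
                        "developed_cancer": cancer,
                        "count": n,
                        "fraction": n / total,
                        "percent": round(100.0 * n / total),
                    }
                )
    table = pd.DataFrame(rows)
    assert int(table["count"].sum()) == total
    table.attrs["total"] = total
    return table


def carrier_percent(annotations: Sequence[SampleAnnotation]) -> float:
    """Percent of participants carrying a known pathogenic BRCA1/2 mutation, rounded."""
    n = sum(1 for a in annotations if a.brca_status == "carrier")
    return round(100.0 * n / len(annotations))


def _factor_groups(covariates: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """One design block per factor: numeric as-is, categoricals one-hot (drop-first)."""
    blocks: dict[str, pd.DataFrame] = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks[col] = s.to_frame()
        else:
            d = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True, dtype=float)
            d[s.isna().to_numpy()] = np.nan
            blocks[col] = d
    return blocks


def exclude_confounded_genes(
    cohort: ExpressionCohort,
    covariates: pd.DataFrame,
    alpha: float = 0.01,
) -> tuple[set[str], pd.Series]:
    """Blacklist genes whose expression associates with any covariate factor.

    For each factor, a joint linear model (ANCOVA-style) is fit on the
    samples where that factor is observed; co-adjusting covariates are
    included only when fully observed on those samples, so coverage blocks
    (e.g. a survey answered by a subset of the cohort) are handled without
    collapsing to a tiny joint complete-case set. The factor's P-value is a
    type-II F-test (extra sum of squares of the factor's block given the
    rest). A gene is blacklisted if any factor attains P < ``alpha``.

    Returns the blacklist and the per-gene minimum factor P-value.

    Covariate rows are aligned to the cohort by sample_id; samples missing
    from the covariate table are simply not used (the expected regime when
    surveys cover a subset).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    genes = cohort.genes
    min_p = pd.Series(np.ones(len(genes)), index=genes, dtype=float)
    if covariates.shape[1] == 0:
        return set(), min_p

    cov = covariates.reindex(cohort.sample_ids)
    blocks = _factor_groups(cov)
    # drop zero-variance factors
    for name in list(blocks):
        blk = blocks[name].dropna()
        if blk.shape[0] == 0 or np.allclose(blk.var(axis=0, ddof=0), 0):
            warnings.warn(f"covariate {name!r} has zero variance; dropped", stacklevel=2)
            del blocks[name]
    if not blocks:
        return set(), min_p

    Y_all = cohort.matrix.to_numpy(dtype=float)

    for name, blk in blocks.items():
        row_mask = ~blk.isna().any(axis=1).to_numpy()
        # co-adjust with factors fully observed on these rows
        co = [
            b
            for other, b in blocks.items()
            if other != name and not b.loc[row_mask].isna().any(axis=1).any()
        ]
        X_full = pd.concat([blk, *co], axis=1).loc[row_mask].to_numpy(dtype=float)
        n, k = X_full.shape
        df_factor = blk.shape[1]
        if n <= k + 1:
            raise ValueError(
                f"factor {name!r}: {n} complete samples but {k + 1} model parameters; reduce covariates"
            )
        ones = np.ones((n, 1))
        X1 = np.hstack([ones, X_full])
        X0 = np.hstack([ones, X_full[:, df_factor:]])  # without the factor's block
        Y = Y_all[row_mask]
        rss1 = _rss(X1, Y)
        rss0 = _rss(X0, Y)
        df_resid = n - X1.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss0 - rss1) / df_factor) / (rss1 / df_resid)
        f = np.where(rss1 <= 0, np.inf, f)
        p = stats.f.sf(f, df_factor, df_resid)
        p = np.where(np.isnan(p), 1.0, p)
        min_p = np.minimum(min_p, pd.Series(p, index=genes))

    blacklist = set(min_p.index[min_p < alpha])
    return blacklist, min_p


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y columns on X (least squares, vectorized)."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)
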