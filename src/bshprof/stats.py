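"""Cohort screening and association statistics.

Single-factor group contrasts use the two-sided Mann-Whitney U test (exact
null when both groups have n <= 8 and no ties, normal approximation with tie
correction otherwise) followed by Benjamini-Hochberg FDR across the declared
test family.  Phenotype correlations are Spearman (exact permutation null
for n <= 9).  Presence/absence contrasts use the Pearson chi-squared test.
Multivariable adjustment is OLS with partial-F per-factor p values and
partial R-squared as the "variance explained" statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IndividualMeta",
    "AssociationResult",
    "screen_individuals",
    "mann_whitney_fdr",
    "spearman_phenotype",
    "chisq_presence",
    "multivariable_adjust",
    "cohort_compare",
]

BMI_BOUNDS = (18.5, 29.9)  # strict inequalities
AGE_BOUNDS = (12.0, 75.0)  # strict inequalities


@dataclass(frozen=True)
class IndividualMeta:
    sample_id: str
    population: str
    gender: str | None = None
    age: float | None = None
    bmi: float | None = None
    status: str = "healthy"


@dataclass(frozen=True)
class AssociationResult:
    factor: str
    statistic: float
    p_raw: float
    q_fdr: float | None
    test_name: str
    variance_explained: float | None = None
    n_used: int | None = None


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def screen_individuals(
    meta: list[IndividualMeta],
    healthy_label: str = "healthy",
) -> tuple[list[IndividualMeta], list[tuple[str, str]]]:
    """Apply the healthy-cohort filters; returns (retained, exclusion log).

    Bounds are strict (18.5 < BMI < 29.9, 12 < age < 75); a missing BMI or
    age passes that criterion, mirroring cohorts that ship no metadata.
    Any non-healthy status is excluded.
    """
    retained: list[IndividualMeta] = []
    excluded: list[tuple[str, str]] = []
    lo_bmi, hi_bmi = BMI_BOUNDS
    lo_age, hi_age = AGE_BOUNDS
    for person in meta:
        if person.status != healthy_label:
            excluded.append((person.sample_id, f"status={person.status}"))
            continue
        if not _is_missing(person.bmi) and not (lo_bmi < person.bmi < hi_bmi):
            excluded.append((person.sample_id, f"bmi={person.bmi}"))
            continue
        if not _is_missing(person.age) and not (lo_age < person.age < hi_age):
            excluded.append((person.sample_id, f"age={person.age}"))
            continue
        retained.append(person)
    return retained, excluded


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 8 and len(y) <= 8 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mann_whitney_fdr(
    family: list[tuple[str, np.ndarray | list, np.ndarray | list]],
) -> list[AssociationResult]:
    """Two-sided Mann-Whitney U per (name, group_a, group_b), BH-q across the family."""
    if not family:
        return []
    stats_p = []
    for name, a, b in family:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group in comparison {name!r}")
        stats_p.append((name, *_mann_whitney(a, b), a.size + b.size))
    pvals = [p for _, _, p, _ in stats_p]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        AssociationResult(
            factor=name,
            statistic=stat,
            p_raw=p,
            q_fdr=float(q),
            test_name="mannwhitney",
            n_used=n,
        )
        for (name, stat, p, n), q in zip(stats_p, qvals)
    ]


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    perms = np.array(list(itertools.permutations(range(n))))
    r_all = (zx[perms] * zy).mean(axis=1)
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def spearman_phenotype(
    ra_by_population: dict[str, float],
    phenotype: pd.DataFrame,
    indicator: str,
) -> AssociationResult:
    """Spearman correlation of per-population family RA against an indicator.

    Populations are matched on the phenotype table's ``population`` column;
    ties are mid-ranked; p comes from the exact permutation null when the
    overlap has n <= 9, else from the t approximation.
    """
    if indicator not in phenotype.columns:
        raise ValueError(f"indicator {indicator!r} not in phenotype table")
    table = phenotype.set_index("population")
    common = sorted(set(ra_by_population) & set(table.index))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping populations; need >= 3")
    x = np.array([ra_by_population[p] for p in common], dtype=float)
    y = table.loc[common, indicator].to_numpy(dtype=float)
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    if len(common) <= 9:
        p = _spearman_exact_p(x, y, r)
    else:
        p = float(res.pvalue)
    return AssociationResult(
        factor=indicator,
        statistic=r,
        p_raw=p,
        q_fdr=None,
        test_name="spearman",
        n_used=len(common),
    )


def chisq_presence(presence_table: np.ndarray | list) -> AssociationResult:
    """Pearson chi-squared (no continuity correction) on a contingency table."""
    table = np.asarray(presence_table)
    if table.ndim != 2 or (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("presence table must be a 2-D array of nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in presence table; expected counts undefined")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return AssociationResult(
        factor="presence",
        statistic=float(stat),
        p_raw=float(p),
        q_fdr=None,
        test_name="chisq",
        n_used=int(table.sum()),
    )


_CATEGORICAL = ("gender", "population")
_FACTORS = ("gender", "age", "bmi", "population")


def _design_columns(data: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    pieces = [pd.Series(1.0, index=data.index, name="intercept")]
    for factor in factors:
        if factor in _CATEGORICAL:
            dummies = pd.get_dummies(data[factor], prefix=factor, drop_first=True, dtype=float)
            pieces.append(dummies)
        else:
            pieces.append(data[factor].astype(float))
    return pd.concat(pieces, axis=1)


def _sse(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def multivariable_adjust(
    data: pd.DataFrame,
    response: str = "ra",
    factors: tuple[str, ...] = _FACTORS,
) -> list[AssociationResult]:
    """Per-factor partial-F tests of an OLS model of *response* on all factors.

    Each factor's p value compares the full model against the model without
    it; variance explained is the partial R-squared
    (SSE_reduced - SSE_full) / SSE_reduced * 100.  Complete-case analysis
    per model; categorical factors are dummy-coded and need >= 2 levels.
    """
    rows = data.dropna(subset=[response, *factors])
    n = len(rows)
    for factor in factors:
        if factor in _CATEGORICAL and rows[factor].nunique() < 2:
            raise ValueError(f"categorical factor {factor!r} has < 2 levels")
    y = rows[response].to_numpy(dtype=float)
    X_full = _design_columns(rows, list(factors))
    p_full = X_full.shape[1]
    if n <= p_full:
        raise ValueError(f"n ({n}) must exceed number of model parameters ({p_full})")
    rank_full = np.linalg.matrix_rank(X_full.to_numpy())
    if rank_full < p_full:
        # identify aliased columns by rank-revealing greedy scan
        aliased = []
        kept: list[str] = []
        for col in X_full.columns:
            trial = X_full[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                aliased.append(col)
        raise ValueError(f"perfect collinearity; aliased terms: {aliased}")
    sse_full, _ = _sse(y, X_full.to_numpy())
    df_full = n - p_full
    results = []
    for factor in factors:
        reduced_factors = [f for f in factors if f != factor]
        X_red = _design_columns(rows, reduced_factors)
        sse_red, _ = _sse(y, X_red.to_numpy())
        df_diff = X_full.shape[1] - X_red.shape[1]
        if sse_full <= 0:
            f_stat, p = math.inf, 0.0
        else:
            f_stat = ((sse_red - sse_full) / df_diff) / (sse_full / df_full)
            p = float(sps.f.sf(f_stat, df_diff, df_full))
        partial_r2 = 100.0 * (sse_red - sse_full) / sse_red if sse_red > 0 else 0.0
        results.append(
            AssociationResult(
                factor=factor,
                statistic=float(f_stat),
                p_raw=p,
                q_fdr=None,
                test_name="linear",
                variance_explained=float(np.clip(partial_r2, 0.0, 100.0)),
                n_used=n,
            )
        )
    return results


def cohort_compare(
    phylotype_ra: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str] = ("healthy", "disease"),
    absence_threshold: float = 0.5,
) -> list[AssociationResult]:
    """Per-phylotype case/control contrasts on per-individual cumulative RA.

    *phylotype_ra* is samples x phylotypes; *meta* carries ``sample_id`` and
    ``status``.  Phylotypes absent (RA == 0) in more than
    ``absence_threshold`` of all individuals are tested by chi-squared on
    presence/absence; the rest by Mann-Whitney.  BH correction is applied
    within each test-type family separately.
    """
    meta_idx = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    healthy_label, disease_label = contrast
    status = meta_idx.loc[phylotype_ra.index, "status"]
    for label in contrast:
        if not (status == label).any():
            raise ValueError(f"contrast label {label!r} missing from metadata")
    arm_a = phylotype_ra.loc[status == healthy_label]
    arm_b = phylotype_ra.loc[status == disease_label]
    mw_family: list[tuple[str, np.ndarray, np.ndarray]] = []
    chisq_results: list[AssociationResult] = []
    chisq_ps: list[float] = []
    for phylotype in phylotype_ra.columns:
        absent_fraction = float((phylotype_ra[phylotype] == 0).mean())
        if absent_fraction > absence_threshold:
            table = np.array(
                [
                    [int((arm_a[phylotype] > 0).sum()), int((arm_a[phylotype] == 0).sum())],
                    [int((arm_b[phylotype] > 0).sum()), int((arm_b[phylotype] == 0).sum())],
                ]
            )
            try:
                res = chisq_presence(table)
            except ValueError:
                continue  # degenerate margin: phylotype absent/present everywhere
            chisq_results.append(
                AssociationResult(
                    factor=str(phylotype),
                    statistic=res.statistic,
                    p_raw=res.p_raw,
                    q_fdr=None,
                    test_name="chisq",
                    n_used=res.n_used,
                )
            )
            chisq_ps.append(res.p_raw)
        else:
            mw_family.append(
                (str(phylotype), arm_a[phylotype].to_numpy(), arm_b[phylotype].to_numpy())
            )
    results = mann_whitney_fdr(mw_family) if mw_family else []
    if chisq_ps:
        qvals = multipletests(chisq_ps, method="fdr_bh")[1]
        results.extend(
            AssociationResult(
                factor=r.factor,
                statistic=r.statistic,
                p_raw=r.p_raw,
                q_fdr=float(q),
                test_name="chisq",
                n_used=r.n_used,
            )
            for r, q in zip(chisq_results, qvals)
        )
    return results
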