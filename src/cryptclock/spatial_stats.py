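"""Spatial and group statistics on evolutionary distances.

Implements the within/between-biopsy divergence test, diversity
correlations, the physical-vs-evolutionary permutation test with
multiple-patient correction, the multivariate linear model of
biopsy-pair distances, and crypt alteration-vs-GEJ correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .profiles_io import SegmentProfile, ValidationError


@dataclass(frozen=True)
class PairRecord:
    patient_id: str
    sample1: str
    sample2: str
    evolutionary_distance: float
    same_biopsy: Optional[bool] = None
    physical_distance: Optional[float] = None
    time_point: Optional[int] = None
    max_gej_distance_cm: Optional[float] = None
    progressor: Optional[bool] = None

    def __post_init__(self):
        if self.evolutionary_distance < 0:
            raise ValidationError("evolutionary distance must be non-negative")


def within_vs_between_test(pairs: Sequence[PairRecord]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum on distances grouped by same-biopsy status.

    Exact p for small groups (scipy picks the exact method when feasible),
    normal approximation otherwise.
    """
    within = [p.evolutionary_distance for p in pairs if p.same_biopsy]
    between = [p.evolutionary_distance for p in pairs if p.same_biopsy is False]
    if not within or not between:
        raise ValidationError("both within- and between-biopsy pairs are required")
    res = stats.mannwhitneyu(within, between, alternative="two-sided",
                             method="exact" if max(len(within), len(between)) <= 20
                             else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def diversity_correlation(within_diversity: Sequence[float],
                          between_diversity: Sequence[float]
                          ) -> tuple[float, float]:
    """Squared Pearson correlation (R^2) and its two-sided t-test p-value."""
    x = np.asarray(within_diversity, dtype=float)
    y = np.asarray(between_diversity, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired patient summaries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in diversity summaries")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


def _spearman_perm_p(x: np.ndarray, y: np.ndarray, rho: float,
                     n_perm: int, rng: np.random.Generator) -> float:
    count = 0
    for _ in range(n_perm):
        perm_rho = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(perm_rho) >= abs(rho) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def physical_vs_evolutionary(pairs_per_patient: dict[str, Sequence[PairRecord]],
                             n_permutations: int = 10_000, seed: int = 0,
                             method: str = "holm") -> pd.DataFrame:
    """Per-patient Spearman rho with permutation p, corrected across patients.

    ``method`` is ``holm`` (default) or ``bonferroni``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for patient_id in sorted(pairs_per_patient):
        pairs = [p for p in pairs_per_patient[patient_id]
                 if p.physical_distance is not None]
        x = np.array([p.physical_distance for p in pairs], dtype=float)
        y = np.array([p.evolutionary_distance for p in pairs], dtype=float)
        if len(x) < 3 or len(set(x)) < 2 or len(set(y)) < 2:
            raise ValidationError(
                f"patient {patient_id}: constant or insufficient ranks"
            )
        rho = float(stats.spearmanr(x, y).statistic)
        p = _spearman_perm_p(x, y, rho, n_permutations, rng)
        rows.append((patient_id, rho, p))
    df = pd.DataFrame(rows, columns=["patient_id", "spearman_rho", "p_raw"])
    df["p_corrected"] = multipletests(df["p_raw"], method=method)[1]
    return df


def gej_regression(pairs: Sequence[PairRecord]) -> pd.DataFrame:
    """OLS of biopsy-pair evolutionary distance on design covariates.

    Predictors: progressor status, time point (second), maximum distance
    from the GEJ, physical distance between biopsies. Returns a
    coefficient table (estimate, SE, t, p).
    """
    rows = []
    for p in pairs:
        if None in (p.progressor, p.time_point, p.max_gej_distance_cm,
                    p.physical_distance):
            raise ValidationError("pair records must carry all four predictors")
        rows.append((p.evolutionary_distance, float(p.progressor),
                     float(p.time_point == 2), p.max_gej_distance_cm,
                     p.physical_distance))
    df = pd.DataFrame(rows, columns=[
        "distance", "progressor", "time_point_second",
        "max_gej_distance_cm", "biopsy_distance_cm",
    ])
    X = sm.add_constant(df.drop(columns="distance"), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        predictors = X.drop(columns="const", errors="ignore")
        constant = [c for c in predictors.columns if predictors[c].nunique() == 1]
        if constant:
            raise ValidationError(f"collinear design (constant: {constant})")
        corr = predictors.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValidationError(f"collinear design (e.g. {worst[0]} vs {worst[1]})")
    fit = sm.OLS(df["distance"], X).fit()
    return pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })


def alterations_vs_gej(records: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Pearson correlation of crypt alteration burden with GEJ distance.

    ``records`` needs columns ``patient_id``, ``alterations``,
    ``gej_distance_cm``. Patients with fewer than 3 crypts are skipped
    with a warning column. Returns (per-patient table, pooled r, pooled p).
    """
    import warnings

    rows = []
    for patient_id, grp in records.groupby("patient_id", sort=True):
        if len(grp) < 3:
            warnings.warn(f"patient {patient_id}: fewer than 3 crypts, skipped")
            continue
        if grp["gej_distance_cm"].nunique() < 2 or grp["alterations"].nunique() < 2:
            rows.append((patient_id, np.nan, np.nan, len(grp)))
            continue
        r, p = stats.pearsonr(grp["alterations"], grp["gej_distance_cm"])
        rows.append((patient_id, float(r), float(p), len(grp)))
    per_patient = pd.DataFrame(rows, columns=["patient_id", "r", "p", "n"])
    pooled_r, pooled_p = stats.pearsonr(records["alterations"],
                                        records["gej_distance_cm"])
    return per_patient, float(pooled_r), float(pooled_p)


def pct_genome_altered(profile: SegmentProfile) -> float:
    """Percent of covered genome length not in the diploid (1,1) state."""
    total = sum(s.length for s in profile.segments)
    if total == 0:
        return 0.0
    altered = sum(s.length for s in profile.segments if (s.cn1, s.cn2) != (1, 1))
    return 100.0 * altered / total
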