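"""Group statistics: Welch comparisons, cohort tables, reference agreement.

Genotype groups of similar age are compared with the heteroscedastic
(Welch) two-sample t-test -- the variance of lens size differs strongly
between normal and dysmorphic genotypes, so pooled-variance testing is
inappropriate. Significance is declared at p < 0.05 (two-sided). Cohort
masses can also be scored against an external growth reference table
(age vs dry weight) via the coefficient of determination of the
measurements about the interpolated reference curve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "GroupComparison",
    "welch_t_test",
    "compare_cohort",
    "r_squared_vs_reference",
    "DEFAULT_AGE_BINS",
    "MEASURE_COLUMNS",
]

ALPHA = 0.05

#: Default age bins (days), mirroring a 0-2.5 week / 2-6 month / 9-12 month
#: cohort structure.
DEFAULT_AGE_BINS: list[tuple[float, float]] = [(0, 17), (60, 180), (270, 365)]

MEASURE_COLUMNS = {
    "volume": ("volume_mm3",),
    "mass": ("mass_mg",),
    "diameter": ("equatorial_diameter_mm", "diameter_mm"),
}


@dataclass
class GroupComparison:
    """Result of one Welch two-sample comparison."""

    measure: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    df: float
    p_value: float
    significant: bool
    age_bin: str | None = None
    flag: str | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "age_bin", "measure", "group_a", "group_b", "n_a", "n_b",
            "mean_a", "mean_b", "sd_a", "sd_b", "t_statistic", "df",
            "p_value", "significant", "flag",
        )}


def welch_t_test(
    sample_a,
    sample_b,
    *,
    measure: str = "",
    group_a: str = "a",
    group_b: str = "b",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Heteroscedastic two-sample t-test (Welch-Satterthwaite df, two-sided p).

    Raises :class:`InsufficientDataError` if either sample has fewer than
    two values, and :class:`DegenerateVarianceError` if both sample
    variances are zero (the statistic is undefined).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 values per sample, got {a.size} and {b.size}"
        )
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateVarianceError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return GroupComparison(
        measure=measure,
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)),
        sd_b=float(np.sqrt(vb)),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=p,
        significant=bool(p < alpha),
    )


def _resolve_measure_column(table: pd.DataFrame, measure: str) -> str | None:
    for col in MEASURE_COLUMNS[measure]:
        if col in table.columns:
            return col
    return None


def _validate_bins(age_bins) -> list[tuple[float, float]]:
    bins = sorted((float(lo), float(hi)) for lo, hi in age_bins)
    for (lo, hi) in bins:
        if hi < lo:
            raise ValidationError(f"invalid age bin ({lo}, {hi})")
    for (_, hi_prev), (lo_next, _) in zip(bins, bins[1:]):
        if lo_next <= hi_prev:
            raise ValidationError("age bins must be non-overlapping")
    return bins


def compare_cohort(
    table: pd.DataFrame,
    age_bins=DEFAULT_AGE_BINS,
    *,
    measures=("volume", "mass", "diameter"),
    alpha: float = ALPHA,
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """All pairwise genotype comparisons per measure within each age bin.

    Pairs that fail the Welch preconditions (too few lenses, zero total
    variance) are returned flagged with NaN statistics rather than
    silently dropped. With ``bonferroni=True`` p-values are multiplied by
    the number of testable comparisons before the significance call.
    """
    if table.empty:
        raise ValidationError("empty cohort table")
    bins = _validate_bins(age_bins)
    results: list[GroupComparison] = []
    for lo, hi in bins:
        label = f"{lo:g}-{hi:g}d"
        sub = table[(table["age_days"] >= lo) & (table["age_days"] <= hi)]
        genotypes = sorted(sub["genotype"].unique())
        for ga, gb in itertools.combinations(genotypes, 2):
            for measure in measures:
                col = _resolve_measure_column(table, measure)
                if col is None:
                    continue
                xa = sub.loc[sub["genotype"] == ga, col].dropna().to_numpy()
                xb = sub.loc[sub["genotype"] == gb, col].dropna().to_numpy()
                try:
                    cmp_ = welch_t_test(
                        xa, xb, measure=measure, group_a=ga, group_b=gb, alpha=alpha
                    )
                except (InsufficientDataError, DegenerateVarianceError) as exc:
                    cmp_ = GroupComparison(
                        measure=measure, group_a=ga, group_b=gb,
                        n_a=int(xa.size), n_b=int(xb.size),
                        mean_a=float(np.mean(xa)) if xa.size else float("nan"),
                        mean_b=float(np.mean(xb)) if xb.size else float("nan"),
                        sd_a=float("nan"), sd_b=float("nan"),
                        t_statistic=float("nan"), df=float("nan"),
                        p_value=float("nan"), significant=False,
                        flag=type(exc).__name__,
                    )
                cmp_.age_bin = label
                results.append(cmp_)
    tested = [c for c in results if c.flag is None]
    if not tested:
        warnings.warn(
            "no age bin contained two genotypes with enough lenses to compare",
            stacklevel=2,
        )
    if bonferroni and tested:
        m = len(tested)
        for c in tested:
            c.p_value = min(1.0, c.p_value * m)
            c.significant = bool(c.p_value < alpha)
    return results


def r_squared_vs_reference(cohort: pd.DataFrame, reference) -> float:
    """R^2 of cohort masses about an interpolated reference growth curve.

    ``reference`` is a sequence of (age_days, weight_mg) pairs or a
    DataFrame with those columns. The reference is linearly interpolated
    at each cohort age; lenses with ages outside the reference range are
    excluded with a warning. This is agreement with an external curve,
    not a fitted regression, so R^2 can be negative when the cohort
    disagrees with the reference worse than its own mean does.
    """
    if isinstance(reference, pd.DataFrame):
        ref = reference[["age_days", "weight_mg"]].to_numpy(dtype=float)
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 2 or ref.shape[0] < 2:
        raise ValidationError("reference must be >= 2 (age_days, weight_mg) pairs")
    ref = ref[np.argsort(ref[:, 0])]
    ages = cohort["age_days"].to_numpy(dtype=float)
    masses = cohort["mass_mg"].to_numpy(dtype=float)
    in_range = (ages >= ref[0, 0]) & (ages <= ref[-1, 0]) & np.isfinite(masses)
    n_excluded = int((~in_range).sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} lens(es) outside the reference age range",
            stacklevel=2,
        )
    ages, masses = ages[in_range], masses[in_range]
    if ages.size < 3:
        raise InsufficientDataError(
            f"need >= 3 lenses within the reference age range, got {ages.size}"
        )
    predicted = np.interp(ages, ref[:, 0], ref[:, 1])
    ss_res = float(np.sum((masses - predicted) ** 2))
    ss_tot = float(np.sum((masses - masses.mean()) ** 2))
    if ss_tot == 0:
        # zero-variance cohort: perfect if it sits on the curve, else no
        # agreement beyond its own mean
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot
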