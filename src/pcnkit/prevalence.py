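"""Prevalence estimation, subgroup contrasts, age trends and age clustering.

Per-disease prevalence uses the normal-approximation (Wald) interval
``p +/- z * sqrt(p(1-p)/N)`` clipped to [0, 1]; Wilson is available behind
a flag.  The analysis panel keeps diseases whose prevalence is
statistically above 1% in at least one subgroup (one-sided score test,
P < .025).  Subgroup contrasts combine a symmetric relative difference
|p1 - p2| / mean(p1, p2) with a two-proportion Z-test under Bonferroni
correction; a significant contrast with a >= 1.5x prevalence ratio marks
the comorbidity *enriched* in the higher-prevalence group.  Age trends use
the Cochran-Armitage test across the five diagnosis-age bands, and
age-specific prevalence profiles are clustered with K-means (k selected by
silhouette by default).  Direct standardization re-weights age-band
prevalences by a standard population to remove age-structure differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.proportion import proportions_ztest

from .cohort import AGE_BANDS
from .comorbidity import ComorbidityMatrix

__all__ = [
    "PrevalenceEstimate",
    "SubgroupDiff",
    "CATrendResult",
    "ClusterResult",
    "prevalence_ci",
    "prevalence_table",
    "screen_above_1pct",
    "relative_difference",
    "signed_relative_difference",
    "subgroup_difference_tests",
    "age_standardize",
    "cochran_armitage",
    "age_profiles",
    "cluster_age_profiles",
    "round_half_up",
    "percent",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (report tables match printed values)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(n: int, total: int, ndigits: int = 1) -> float:
    """Percentage n/total rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * n / total, ndigits)


@dataclass(frozen=True)
class PrevalenceEstimate:
    code: str
    n: int
    total: int
    p: float
    ci_low: float
    ci_high: float

    def as_percent(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (
            round_half_up(100 * self.p, ndigits),
            round_half_up(100 * self.ci_low, ndigits),
            round_half_up(100 * self.ci_high, ndigits),
        )


def prevalence_ci(
    n: int, total: int, code: str = "", level: float = 0.95,
    method: str = "wald",
) -> PrevalenceEstimate:
    """Point prevalence with a two-sided confidence interval."""
    if total <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= n <= total:
        raise ValueError("numerator must lie in [0, total]")
    p = n / total
    z = stats.norm.ppf(0.5 + level / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / total)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1 + z * z / total
        center = (p + z * z / (2 * total)) / denom
        half = z * np.sqrt(p * (1 - p) / total + z * z / (4 * total**2)) / denom
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown CI method: {method}")
    return PrevalenceEstimate(
        code=code, n=n, total=total, p=p,
        ci_low=max(0.0, lo), ci_high=min(1.0, hi),
    )


def prevalence_table(matrix: ComorbidityMatrix,
                     level: float = 0.95) -> pd.DataFrame:
    """Per-disease prevalence estimates over the whole cohort."""
    rows = []
    for code, n in matrix.column_counts().items():
        est = prevalence_ci(int(n), matrix.n, code=code, level=level)
        rows.append({
            "code": code, "n": est.n, "N": est.total, "p": est.p,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
        })
    return pd.DataFrame(rows).sort_values("code").reset_index(drop=True)


# ---------------------------------------------------------------------------
# panel screening

def _one_sided_p_above(n: int, total: int, p0: float) -> float:
    """One-sided score test of H0: p = p0 vs Ha: p > p0 (null variance)."""
    z = (n / total - p0) / np.sqrt(p0 * (1 - p0) / total)
    return float(stats.norm.sf(z))


def screen_above_1pct(
    counts_by_subgroup: Mapping[str, tuple[Mapping[str, int], int]],
    threshold: float = 0.01,
    alpha_one_sided: float = 0.025,
) -> list[str]:
    """Diseases with prevalence significantly above ``threshold`` in >= 1
    subgroup.

    ``counts_by_subgroup`` maps a subgroup label to ``(per-code counts, N)``.
    """
    retained: set[str] = set()
    for counts, total in counts_by_subgroup.values():
        if total <= 0:
            continue
        for code, n in counts.items():
            if n == 0 or code in retained:
                continue
            if _one_sided_p_above(int(n), total, threshold) < alpha_one_sided:
                retained.add(code)
    return sorted(retained)


def subgroup_counts(
    matrix: ComorbidityMatrix, labels: pd.Series
) -> dict[str, tuple[pd.Series, int]]:
    """Per-level (counts, N) for a patient -> subgroup label mapping."""
    out: dict[str, tuple[pd.Series, int]] = {}
    aligned = labels.reindex(matrix.data.index)
    for level in sorted(aligned.dropna().unique()):
        sub = matrix.data.loc[aligned == level]
        out[str(level)] = (sub.sum(axis=0), len(sub))
    return out


# ---------------------------------------------------------------------------
# subgroup contrasts

def relative_difference(p1: float, p2: float) -> float:
    """Symmetric relative difference |p1 - p2| / mean(p1, p2)."""
    if p1 + p2 <= 0:
        raise ValueError("relative difference undefined for two zeros")
    return abs(p1 - p2) / ((p1 + p2) / 2)


def signed_relative_difference(p1: float, p2: float) -> float:
    """Signed variant (positive when p1 > p2)."""
    if p1 + p2 <= 0:
        raise ValueError("relative difference undefined for two zeros")
    return (p1 - p2) / ((p1 + p2) / 2)


@dataclass(frozen=True)
class SubgroupDiff:
    code: str
    group1: str
    group2: str
    n1: int
    n2: int
    total1: int
    total2: int
    p1: float
    p2: float
    abs_diff: float
    rel_diff: float
    z: float
    p_raw: float
    p_adj: float
    significant: bool
    enriched_in: str  # group label or "none"


def subgroup_difference_tests(
    matrix: ComorbidityMatrix,
    labels: pd.Series,
    groups: tuple[str, str] | None = None,
    alpha: float = 0.05,
    rel_diff_threshold: float = 0.1,
    enrichment_ratio: float = 1.5,
    m: int | None = None,
) -> list[SubgroupDiff]:
    """Two-proportion Z-tests per disease with Bonferroni correction.

    ``m`` defaults to the number of diseases in the matrix (the retained
    panel).  A disease is *significant* when the symmetric relative
    difference exceeds ``rel_diff_threshold`` and the Bonferroni-adjusted p
    is below ``alpha``; it is *enriched* in the higher-prevalence group when
    additionally the prevalence ratio is >= ``enrichment_ratio``.
    """
    by_group = subgroup_counts(matrix, labels)
    if groups is None:
        if len(by_group) != 2:
            raise ValueError("grouping must have exactly two levels")
        groups = tuple(by_group)  # type: ignore[assignment]
    g1, g2 = groups
    counts1, total1 = by_group[g1]
    counts2, total2 = by_group[g2]
    if total1 == 0 or total2 == 0:
        raise ValueError("both groups must be non-empty")
    m = m if m is not None else len(matrix.diseases)

    out: list[SubgroupDiff] = []
    for code in matrix.diseases:
        n1, n2 = int(counts1.get(code, 0)), int(counts2.get(code, 0))
        p1, p2 = n1 / total1, n2 / total2
        if n1 + n2 == 0:
            rel, z, p_raw = 0.0, 0.0, 1.0
        else:
            rel = relative_difference(p1, p2)
            if n1 + n2 in (0, total1 + total2):
                z, p_raw = 0.0, 1.0  # degenerate pooled variance
            else:
                z, p_raw = proportions_ztest(
                    [n1, n2], [total1, total2], alternative="two-sided"
                )
        p_adj = min(1.0, p_raw * m)
        significant = rel > rel_diff_threshold and p_adj < alpha
        enriched = "none"
        if significant and min(p1, p2) >= 0:
            ratio = np.inf if min(p1, p2) == 0 else max(p1, p2) / min(p1, p2)
            if ratio >= enrichment_ratio:
                enriched = g1 if p1 > p2 else g2
        out.append(SubgroupDiff(
            code=code, group1=g1, group2=g2,
            n1=n1, n2=n2, total1=total1, total2=total2,
            p1=p1, p2=p2, abs_diff=p1 - p2, rel_diff=rel,
            z=float(z), p_raw=float(p_raw), p_adj=float(p_adj),
            significant=bool(significant), enriched_in=enriched,
        ))
    return out


def diffs_frame(diffs: Sequence[SubgroupDiff]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in diffs])


# ---------------------------------------------------------------------------
# age structure

def age_standardize(
    p_by_age: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    standard_counts: Mapping[str, float],
) -> pd.Series:
    """Directly standardized prevalence per group.

    ``p_by_age``: group -> band -> prevalence (or a groups x bands frame);
    ``standard_counts``: band -> count in the standard population.
    """
    df = pd.DataFrame(p_by_age).T if not isinstance(p_by_age, pd.DataFrame) \
        else p_by_age
    std = pd.Series(standard_counts, dtype=float)
    if set(df.columns) != set(std.index):
        raise ValueError("age bands of groups and standard must match")
    w = std / std.sum()
    return df.mul(w.reindex(df.columns), axis=1).sum(axis=1)


@dataclass(frozen=True)
class CATrendResult:
    z: float
    p_two_sided: float
    p_one_sided_increasing: float


def cochran_armitage(
    successes: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
) -> CATrendResult:
    """Cochran-Armitage test for trend in proportions across ordered bands.

    Statistic ``T = sum_i s_i (x_i - n_i pbar)`` normalized by its null
    variance ``pbar (1-pbar) [sum n_i s_i^2 - (sum n_i s_i)^2 / N]``;
    positive z means prevalence increases with the band score.
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 ordered bands")
    s = np.arange(1, len(x) + 1, dtype=float) if scores is None \
        else np.asarray(scores, dtype=float)
    total = n.sum()
    if total == 0:
        raise ValueError("all totals zero")
    pbar = x.sum() / total
    t_stat = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s * s) - np.sum(n * s) ** 2 / total)
    if var <= 0:
        return CATrendResult(0.0, 1.0, 1.0)
    z = t_stat / np.sqrt(var)
    return CATrendResult(
        z=float(z),
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        p_one_sided_increasing=float(stats.norm.sf(z)),
    )


def age_profiles(
    matrix: ComorbidityMatrix, age_band_labels: pd.Series
) -> pd.DataFrame:
    """Diseases x age-band prevalence profile with the trend p-value."""
    by_band = subgroup_counts(matrix, age_band_labels)
    bands = [b for b in AGE_BANDS if b in by_band]
    rows = []
    for code in matrix.diseases:
        xs = [int(by_band[b][0].get(code, 0)) for b in bands]
        ns = [by_band[b][1] for b in bands]
        trend = cochran_armitage(xs, ns) if len(bands) >= 3 else None
        row = {"code": code}
        for b, x_, n_ in zip(bands, xs, ns):
            row[b] = x_ / n_ if n_ else 0.0
        row["trend_p"] = trend.p_one_sided_increasing if trend else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("code")


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series  # disease -> cluster id
    inertia: float
    criterion_by_k: dict[int, float]


def cluster_age_profiles(
    profiles: pd.DataFrame,
    k_range: Sequence[int] = (2, 3, 4, 5, 6, 7, 8),
    seed: int = 0,
    k: int | None = None,
) -> ClusterResult:
    """K-means over age-band prevalence vectors; k by silhouette unless fixed.

    Rows are fitted in sorted-index order so the result is invariant to the
    input row order (up to cluster label permutation nothing changes).
    """
    profiles = profiles.sort_index()
    X = profiles.to_numpy(dtype=float)
    if k is None:
        ks = [kk for kk in k_range if 2 <= kk < len(X)]
        if not ks:
            raise ValueError("k_range empty or too large for input size")
        scores: dict[int, float] = {}
        for kk in ks:
            lab = KMeans(n_clusters=kk, n_init=10,
                         random_state=seed).fit_predict(X)
            scores[kk] = (
                float(silhouette_score(X, lab)) if len(set(lab)) > 1
                else -1.0
            )
        k = max(scores, key=lambda kk: scores[kk])
    else:
        scores = {}
    if k >= len(X):
        raise ValueError("need at least k profiles")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return ClusterResult(
        k=k,
        labels=pd.Series(km.labels_, index=profiles.index, name="cluster"),
        inertia=float(km.inertia_),
        criterion_by_k=scores,
    )
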