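"""Cohort-level statistics for necrosis scoring.

Covers the summaries reported across genotypes and drug doses:
normalization of per-cell relative PS intensities to a reference condition,
the log-log regression between integrated Ca2+ and integrated PS signals,
grouped necrotic/apoptotic cell counts (mean of group means +/- s.e.m.),
PS-positive fractions among living cells, and dose-response tables.

Standard-error conventions follow the figure legends: intensities are
summarized over cells, counts over animal groups (10/15/25 animals per
group depending on the strain's scoring protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "CountSummary",
    "PSPositiveFraction",
    "normalize_to_reference",
    "log_integral_regression",
    "grouped_count_summary",
    "ps_positive_fraction",
    "dose_response_table",
    "ttest",
]


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(stats.sem(x)) if x.size > 1 else 0.0


def normalize_to_reference(
    values: pd.DataFrame, reference: str, value_col: str = "rps", condition_col: str = "condition"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide each cell's value by the reference cohort's mean.

    Returns ``(per_cell, summary)``: the input table with a ``normalized``
    column added, and a per-condition summary with mean, s.e.m. (over
    cells), and n. The reference condition's normalized mean is 1 by
    construction.
    """
    if condition_col not in values or value_col not in values:
        raise ValueError(f"table must have columns {condition_col!r} and {value_col!r}")
    ref = values.loc[values[condition_col] == reference, value_col]
    if ref.empty:
        raise ValueError(f"reference condition {reference!r} is missing or empty")
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError("reference cohort mean must be positive")
    per_cell = values.copy()
    per_cell["normalized"] = per_cell[value_col] / ref_mean
    summary = (
        per_cell.groupby(condition_col, sort=False)["normalized"]
        .agg(mean="mean", sem=lambda s: _sem(s.to_numpy()), n="count")
        .reset_index()
    )
    summary["reference"] = reference
    return per_cell, summary


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression on log-transformed pairs."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    n: int


def log_integral_regression(
    ca_integrals: np.ndarray, ps_integrals: np.ndarray
) -> RegressionResult:
    """OLS of ln(PS integral) on ln(Ca integral) with Pearson correlation.

    Natural logs are used; the correlation and slope are base-invariant for
    a log-log fit, only the intercept depends on the base.
    """
    x = np.asarray(ca_integrals, dtype=float)
    y = np.asarray(ps_integrals, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for regression")
    bad = np.nonzero((x <= 0) | (y <= 0))[0]
    if bad.size:
        pairs = [(int(i), float(x[i]), float(y[i])) for i in bad[:10]]
        raise ValueError(f"non-positive values cannot be log-transformed: pairs {pairs}")
    fit = stats.linregress(np.log(x), np.log(y))
    r = float(fit.rvalue)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept), r=r, r_squared=r * r, n=x.size
    )


@dataclass(frozen=True)
class CountSummary:
    """Grouped scoring of necrotic/apoptotic cell counts."""

    group_size: int
    group_means: tuple[float, ...]
    mean: float  # mean of group means
    sem: float  # s.e.m. over groups
    n_animals: int
    has_partial_group: bool


def grouped_count_summary(
    counts, group_size: int = 10, max_per_animal: int | None = None
) -> CountSummary:
    """Partition per-animal counts into consecutive groups and summarize.

    Animals are grouped in input order into groups of ``group_size``; a
    trailing partial group is kept and flagged. The reported mean is the
    mean of the group means, with its s.e.m. computed over groups.
    """
    counts = np.asarray(counts)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if counts.size == 0:
        raise ValueError("counts must be nonempty")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
        raise ValueError("counts must be nonnegative numbers")
    if max_per_animal is not None and np.any(counts > max_per_animal):
        raise ValueError(f"counts exceed the anatomical maximum {max_per_animal}")
    groups = [counts[i : i + group_size] for i in range(0, counts.size, group_size)]
    means = np.array([g.mean() for g in groups], dtype=float)
    return CountSummary(
        group_size=group_size,
        group_means=tuple(means),
        mean=float(means.mean()),
        sem=_sem(means),
        n_animals=int(counts.size),
        has_partial_group=counts.size % group_size != 0,
    )


@dataclass(frozen=True)
class PSPositiveFraction:
    """Fraction of living (non-swollen) cells with surface PS."""

    n_live: int
    n_positive: int
    percent: float
    sem: float  # binomial standard error of the percentage
    threshold: float


def ps_positive_fraction(live_rps, threshold: float = 1.5) -> PSPositiveFraction:
    """Percentage of live cells whose relative PS intensity exceeds the
    positivity threshold (default 1.5-fold over background)."""
    live_rps = np.asarray(live_rps, dtype=float)
    if live_rps.size == 0:
        raise ValueError("no live cells to score")
    n = live_rps.size
    k = int((live_rps > threshold).sum())
    p = k / n
    return PSPositiveFraction(
        n_live=n,
        n_positive=k,
        percent=100.0 * p,
        sem=100.0 * float(np.sqrt(p * (1.0 - p) / n)),
        threshold=threshold,
    )


def dose_response_table(
    measurements: pd.DataFrame,
    *,
    dose_col: str = "dose",
    rps_col: str = "rps",
    count_col: str | None = None,
    group_size: int = 10,
) -> pd.DataFrame:
    """Per-dose summary normalized to the vehicle (dose 0) cohort.

    ``measurements`` holds one row per cell (intensity) or per animal
    (count). Returns one row per dose with the normalized PS mean +/-
    s.e.m., optional grouped count summary, and a monotonicity report
    (sign of the trend of normalized means across doses).
    """
    if dose_col not in measurements:
        raise ValueError(f"missing dose column {dose_col!r}")
    doses = np.sort(measurements[dose_col].unique())
    if 0 not in doses:
        raise ValueError("a vehicle (dose 0) cohort is required")
    table = measurements.rename(columns={dose_col: "condition"})
    per_cell, summary = normalize_to_reference(
        table, reference=0, value_col=rps_col, condition_col="condition"
    )
    summary = summary.rename(columns={"condition": "dose"}).sort_values("dose")
    if count_col is not None:
        counts = []
        for dose in summary["dose"]:
            cs = grouped_count_summary(
                measurements.loc[measurements[dose_col] == dose, count_col].to_numpy(),
                group_size=group_size,
            )
            counts.append({"count_mean": cs.mean, "count_sem": cs.sem})
        summary = pd.concat([summary.reset_index(drop=True), pd.DataFrame(counts)], axis=1)
    diffs = np.diff(summary["mean"].to_numpy())
    summary.attrs["monotonic_non_increasing"] = bool(np.all(diffs <= 1e-12))
    summary.attrs["monotonic_non_decreasing"] = bool(np.all(diffs >= -1e-12))
    return summary


def ttest(a, b, equal_var: bool = True):
    """Thin convenience wrapper for a two-sample Student t-test."""
    return stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=equal_var)
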