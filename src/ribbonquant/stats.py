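"""Distributional statistics on volumes and counts, plus the acoustic
energy-dose utility.

Volume distributions are compared with the two-sided Wilcoxon/Mann-Whitney
rank-sum test (exact enumeration for small tie-free samples, normal
approximation with tie and continuity corrections otherwise); per-cell
counts against a baseline condition use Welch t-tests with Bonferroni
adjustment.  Volume summaries carry a Gaussian kernel density estimate
(Silverman bandwidth by default) as used for violin-plot style reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RankSumResult",
    "rank_sum_test",
    "compare_counts",
    "VolumeDistributionSummary",
    "volume_summary",
    "ExposureDose",
    "energy_ratio",
]

#: Combined sample size at or below which the exact null distribution of U
#: is enumerated (when there are no ties).
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    pvalue: float
    method: str  # "exact" | "asymptotic"


def rank_sum_test(sample_a, sample_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration of the U null distribution when the combined
    sample size is at most 12 and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.  If every
    value in both samples is identical the test is degenerate: p = 1 is
    returned with a logged warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.warning("rank_sum_test: all values identical; returning p = 1")
        return RankSumResult(statistic=a.size * b.size / 2.0, pvalue=1.0,
                             method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return RankSumResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), method=method
    )


def compare_counts(
    cell_counts: pd.DataFrame,
    value: str = "paired",
    condition_col: str = "condition",
    baseline: str = "control",
) -> pd.DataFrame:
    """Welch t-test of each condition against the baseline, Bonferroni
    adjusted.

    The Bonferroni factor is the number of non-baseline conditions; adjusted
    p-values are capped at 1.  Requires at least 2 cells per condition;
    zero variance in both groups of a comparison is an error (the t
    statistic is undefined).
    """
    groups = {
        str(cond): grp[value].to_numpy(dtype=float)
        for cond, grp in cell_counts.groupby(condition_col)
    }
    if baseline not in groups:
        raise ValueError(f"baseline condition {baseline!r} not present")
    base = groups[baseline]
    others = [c for c in groups if c != baseline]
    if not others:
        raise ValueError("no condition to compare against the baseline")
    if any(len(g) < 2 for g in groups.values()):
        raise ValueError("need at least 2 cells per condition")
    m = len(others)
    rows = []
    for cond in sorted(others):
        g = groups[cond]
        if base.var(ddof=1) == 0.0 and g.var(ddof=1) == 0.0:
            if np.allclose(base.mean(), g.mean()):
                raw = 1.0
            else:
                raise ValueError(
                    f"zero variance in both groups for {cond!r} vs "
                    f"{baseline!r}: Welch t is undefined"
                )
        else:
            raw = float(
                sps.ttest_ind(g, base, equal_var=False).pvalue
            )
        rows.append(
            {
                "condition": cond,
                "baseline": baseline,
                "n": len(g),
                "n_baseline": len(base),
                "mean": g.mean(),
                "mean_baseline": base.mean(),
                "p_raw": raw,
                "p_adjusted": min(1.0, raw * m),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VolumeDistributionSummary:
    """Summary of a volume distribution for one condition x frequency.

    ``variance`` is the unbiased (ddof=1) sample variance.  The KDE uses a
    Gaussian kernel; its grid spans the data plus three bandwidths each side
    so the density integrates to 1 (checked to 1e-3).  A degenerate
    (zero-variance) sample is reported as a point mass instead of a KDE.
    """

    condition: str
    frequency: str
    n: int
    mean: float
    variance: float
    quantiles: dict[float, float]
    kde_grid: np.ndarray
    kde_density: np.ndarray
    bandwidth: float
    bandwidth_rule: str
    point_mass: bool = False


def volume_summary(
    volumes,
    condition: str = "",
    frequency: str = "",
    kde_bandwidth: str | float = "silverman",
    grid_size: int = 256,
) -> VolumeDistributionSummary:
    """Distributional summary of component volumes (n >= 10 required)."""
    v = np.asarray(volumes, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 volumes for a distribution summary")
    qs = {round(q, 1): float(np.quantile(v, q)) for q in np.arange(0.1, 0.95, 0.1)}
    var = float(v.var(ddof=1))
    if np.ptp(v) == 0.0:  # all values identical: degenerate KDE
        return VolumeDistributionSummary(
            condition=condition, frequency=frequency, n=int(v.size),
            mean=float(v.mean()), variance=0.0, quantiles=qs,
            kde_grid=np.array([v[0]]), kde_density=np.array([np.inf]),
            bandwidth=0.0, bandwidth_rule=str(kde_bandwidth), point_mass=True,
        )
    kde = sps.gaussian_kde(v, bw_method=kde_bandwidth)
    h = float(kde.factor * v.std(ddof=1))
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_size)
    dens = kde(grid)
    return VolumeDistributionSummary(
        condition=condition, frequency=frequency, n=int(v.size),
        mean=float(v.mean()), variance=var, quantiles=qs,
        kde_grid=grid, kde_density=dens,
        bandwidth=h, bandwidth_rule=str(kde_bandwidth),
    )


@dataclass(frozen=True)
class ExposureDose:
    """An acoustic exposure: sound pressure level (dB SPL) and duration
    (minutes)."""

    level_db: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")

    @property
    def energy(self) -> float:
        """Relative acoustic energy: duration times 10^(level / 10)."""
        return self.duration_min * 10.0 ** (self.level_db / 10.0)


def energy_ratio(dose_a: ExposureDose, dose_b: ExposureDose) -> float:
    """Fold ratio of acoustic energies of two exposures.

    Sound energy scales linearly with duration and with 10^(dB/10) in
    intensity (equal source/spectrum assumed), so
    ``ratio = (t_a 10^(L_a/10)) / (t_b 10^(L_b/10))``.
    """
    return dose_a.energy / dose_b.energy
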