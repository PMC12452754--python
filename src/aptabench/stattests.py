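"""Statistical battery for library benchmarking.

One-way ANOVA across per-base count groups (full sum-of-squares
decomposition, not just the p-value), Shapiro–Wilk and Anderson–Darling
normality tests, and two-sample Kolmogorov–Smirnov comparisons.  The test
statistics themselves are delegated to scipy; the ANOVA decomposition is
computed from the classical formulas so the table mirrors standard
spreadsheet output (SS/df/MS/F/p/F-crit per source of variation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "NormalityResult",
    "KSResult",
    "anova_one_way",
    "normality_tests",
    "ks_two_sample",
    "SHAPIRO_MAX_N",
]

logger = logging.getLogger(__name__)

#: Above this sample size Shapiro–Wilk runs on a seeded subsample (the
#: classical test was calibrated for far smaller n; scipy warns above 5000).
SHAPIRO_MAX_N = 5000


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f_statistic: float
    p_value: float
    f_critical: float
    alpha: float
    significant: bool

    def to_frame(self) -> pd.DataFrame:
        """Spreadsheet-style ANOVA table (Between/Within/Total rows)."""
        return pd.DataFrame(
            [
                {
                    "Source of Variation": "Between Groups",
                    "SS": self.ss_between,
                    "df": self.df_between,
                    "MS": self.ms_between,
                    "F": self.f_statistic,
                    "p-Value": self.p_value,
                    "F Crit": self.f_critical,
                    "Significant": "Yes" if self.significant else "No",
                },
                {
                    "Source of Variation": "Within Groups",
                    "SS": self.ss_within,
                    "df": self.df_within,
                    "MS": self.ms_within,
                    "F": np.nan,
                    "p-Value": np.nan,
                    "F Crit": np.nan,
                    "Significant": "",
                },
                {
                    "Source of Variation": "Total",
                    "SS": self.ss_total,
                    "df": self.df_total,
                    "MS": np.nan,
                    "F": np.nan,
                    "p-Value": np.nan,
                    "F Crit": np.nan,
                    "Significant": "",
                },
            ]
        )


@dataclass(frozen=True)
class NormalityResult:
    n: int
    shapiro_statistic: float
    shapiro_p: float
    shapiro_n_used: int
    anderson_statistic: float
    anderson_critical_values: tuple[float, ...]
    anderson_significance_levels: tuple[float, ...]
    alpha: float
    degenerate: bool = False

    @property
    def shapiro_normal(self) -> bool:
        return not self.degenerate and self.shapiro_p >= self.alpha

    @property
    def anderson_normal(self) -> bool:
        if self.degenerate:
            return False
        # critical value at the ladder entry closest to alpha
        levels = np.asarray(self.anderson_significance_levels) / 100.0
        idx = int(np.argmin(np.abs(levels - self.alpha)))
        return self.anderson_statistic < self.anderson_critical_values[idx]


@dataclass(frozen=True)
class KSResult:
    label_a: str
    label_b: str
    d_statistic: float
    p_value: float


def anova_one_way(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA over named groups of real values.

    Sum-of-squares and degrees-of-freedom additivity are asserted on every
    call; the p-value and F-critical come from the F distribution.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} value(s); need >= 2")
    pooled = np.concatenate(list(arrays.values()))
    grand = pooled.mean()
    n_total = pooled.size
    g = len(arrays)

    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    ss_total = ((pooled - grand) ** 2).sum()
    df_between = g - 1
    df_within = n_total - g
    df_total = n_total - 1
    assert abs(ss_total - (ss_between + ss_within)) <= 1e-8 * max(1.0, ss_total)
    assert df_total == df_between + df_within

    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        # all groups internally constant: F is 0/0 when means agree, inf otherwise
        f_stat = 0.0 if ss_between <= 1e-12 else float("inf")
    else:
        f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within)) if np.isfinite(f_stat) else 0.0
    f_crit = float(stats.f.ppf(1 - alpha, df_between, df_within))
    return AnovaResult(
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        df_between=df_between,
        df_within=df_within,
        df_total=df_total,
        ms_between=float(ms_between),
        ms_within=float(ms_within),
        f_statistic=float(f_stat),
        p_value=p,
        f_critical=f_crit,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def normality_tests(
    sample: np.ndarray, alpha: float = 0.05, subsample_seed: int = 0
) -> NormalityResult:
    """Shapiro–Wilk and Anderson–Darling tests of normality.

    Constant samples get a flagged degenerate verdict instead of a numeric
    statistic.  Samples above ``SHAPIRO_MAX_N`` are subsampled (seeded) for
    Shapiro–Wilk only; Anderson–Darling always runs on the full sample.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 8:
        raise ValueError(f"normality tests require n >= 8, got {x.size}")
    if np.ptp(x) == 0.0:
        logger.warning("constant sample: normality verdict flagged degenerate")
        return NormalityResult(
            n=x.size,
            shapiro_statistic=float("nan"),
            shapiro_p=float("nan"),
            shapiro_n_used=0,
            anderson_statistic=float("nan"),
            anderson_critical_values=(),
            anderson_significance_levels=(),
            alpha=alpha,
            degenerate=True,
        )
    if x.size > SHAPIRO_MAX_N:
        rng = np.random.default_rng(subsample_seed)
        sw_sample = rng.choice(x, size=SHAPIRO_MAX_N, replace=False)
        logger.info(
            "Shapiro–Wilk on seeded subsample of %d (full n = %d)", SHAPIRO_MAX_N, x.size
        )
    else:
        sw_sample = x
    sw = stats.shapiro(sw_sample)
    ad = stats.anderson(x, dist="norm")
    return NormalityResult(
        n=x.size,
        shapiro_statistic=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        shapiro_n_used=int(sw_sample.size),
        anderson_statistic=float(ad.statistic),
        anderson_critical_values=tuple(float(c) for c in ad.critical_values),
        anderson_significance_levels=tuple(float(s) for s in ad.significance_level),
        alpha=alpha,
    )


def ks_two_sample(
    a: np.ndarray, b: np.ndarray, label_a: str = "a", label_b: str = "b"
) -> KSResult:
    """Two-sided two-sample Kolmogorov–Smirnov test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(
        label_a=label_a,
        label_b=label_b,
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
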