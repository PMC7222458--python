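"""Correlation screening and group comparison utilities.

The screen computes all pairwise Pearson correlations among the
measures, with two-tailed p-values from the exact t transform at
n - 2 df, and classifies each pair into three tiers: not significant,
p < 0.05, or below a Tukey-adjusted threshold 0.05 / sqrt(K).  Because
the correlation matrix of p measures over n < p units has at most n
positive eigenvalues, the effective number of tests K defaults to
C(min(n, p), 2) rather than C(p, 2).

Also here: Welch t-tests between defined school groups, partial
correlations for mediation-style arguments, simple OLS extrapolation,
and a Monte-Carlo null calibration of the screen's type-I behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .registry import SchoolMeasureMatrix

__all__ = [
    "CorrelationScreen",
    "CorrelationScreener",
    "correlation_screen",
    "tukey_threshold",
    "critical_r",
    "correlation_power",
    "GroupComparison",
    "group_compare",
    "PartialCorrelation",
    "partial_correlation",
    "linear_fit",
    "null_calibration",
]

TIER_NS = "ns"
TIER_P05 = "p05"
TIER_TUKEY = "tukey"


def tukey_threshold(n_tests: int) -> float:
    """Tukey-adjusted critical significance level 0.05 / sqrt(n_tests).

    Milder than Bonferroni's 0.05/n, appropriate when zero correlations
    are not a plausible prior for most pairs.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / float(np.sqrt(n_tests))


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for Pearson r via t = r sqrt((n-2)/(1-r^2))."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def critical_r(n_units: int, alpha: float) -> float:
    """Smallest |r| two-tailed significant at ``alpha`` for n units.

    Inverts the t transform: r = t / sqrt(t^2 + n - 2) with t the
    1 - alpha/2 quantile at n - 2 df.  E.g. n=29, alpha=0.05 -> 0.367.
    """
    if n_units < 4:
        raise ValueError("need at least 4 units")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, n_units - 2)
    return float(t / np.sqrt(t**2 + n_units - 2))


def correlation_power(rho: float, n_units: int, alpha: float = 0.05) -> float:
    """Textbook power of the two-tailed Pearson test via Fisher's z.

    Provided as a companion to :func:`critical_r`: the critical r at
    alpha=0.05 and n=29 is 0.37, but 80% power to *detect* a true
    correlation at that alpha needs rho near 0.50.
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must be in (0, 1) in absolute value")
    se = 1.0 / np.sqrt(n_units - 3)
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_rho = np.arctanh(rho)
    return float(
        stats.norm.sf(z_alpha - abs(z_rho) / se)
        + stats.norm.cdf(-z_alpha - abs(z_rho) / se)
    )


@dataclass
class CorrelationScreen:
    """Result of a full correlation screen."""

    r: pd.DataFrame
    p: pd.DataFrame
    tier: pd.DataFrame
    n_units: int
    n_pairs: int
    effective_tests: int
    tukey_alpha: float

    def tier_counts(self) -> dict[str, int]:
        iu = np.triu_indices(self.r.shape[0], k=1)
        tiers = self.tier.to_numpy()[iu]
        return {
            TIER_NS: int((tiers == TIER_NS).sum()),
            TIER_P05: int((tiers == TIER_P05).sum()),
            TIER_TUKEY: int((tiers == TIER_TUKEY).sum()),
        }

    def n_significant(self, level: str = TIER_P05) -> int:
        """Pairs at or beyond a tier (tukey pairs also count as p05)."""
        counts = self.tier_counts()
        if level == TIER_P05:
            return counts[TIER_P05] + counts[TIER_TUKEY]
        if level == TIER_TUKEY:
            return counts[TIER_TUKEY]
        raise ValueError(f"unknown tier {level!r}")

    def to_long(self) -> pd.DataFrame:
        """Long-format (measure_a, measure_b, r, p, tier) table."""
        names = list(self.r.columns)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "measure_a": names[i],
                        "measure_b": names[j],
                        "r": self.r.iat[i, j],
                        "p": self.p.iat[i, j],
                        "tier": self.tier.iat[i, j],
                    }
                )
        return pd.DataFrame(rows)


class CorrelationScreener(BaseEstimator):
    """Estimator interface to the correlation screen.

    Parameters
    ----------
    effective_tests : int or "auto"
        Denominator K of the Tukey threshold 0.05/sqrt(K); "auto" uses
        C(min(n_units, n_measures), 2).

    Attributes (after :meth:`fit`)
    ------------------------------
    r_, p_, tier_ : pandas.DataFrame
        Symmetric correlation, p-value and tier matrices.
    tukey_alpha_ : float
    screen_ : CorrelationScreen
    """

    def __init__(self, effective_tests: int | str = "auto"):
        self.effective_tests = effective_tests

    def fit(self, X: pd.DataFrame | SchoolMeasureMatrix, y=None):
        values = X.values if isinstance(X, SchoolMeasureMatrix) else X
        if values.isna().any().any():
            raise ValueError("correlation screen requires a complete matrix")
        n, p = values.shape
        if n < 4:
            raise ValueError("need at least 4 units")
        sd = values.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(
                f"constant columns: {values.columns[sd == 0].tolist()}"
            )
        r = values.corr()
        pmat = pd.DataFrame(
            _r_to_p(r.to_numpy(), n), index=r.index, columns=r.columns
        )
        np.fill_diagonal(pmat.values, 0.0)
        if self.effective_tests == "auto":
            m = min(n, p)
            k_eff = m * (m - 1) // 2
        else:
            k_eff = int(self.effective_tests)
        alpha_t = tukey_threshold(k_eff)
        tier = np.where(
            pmat.to_numpy() < alpha_t,
            TIER_TUKEY,
            np.where(pmat.to_numpy() < 0.05, TIER_P05, TIER_NS),
        )
        self.r_ = r
        self.p_ = pmat
        self.tier_ = pd.DataFrame(tier, index=r.index, columns=r.columns)
        self.tukey_alpha_ = alpha_t
        self.screen_ = CorrelationScreen(
            r=self.r_,
            p=self.p_,
            tier=self.tier_,
            n_units=n,
            n_pairs=p * (p - 1) // 2,
            effective_tests=k_eff,
            tukey_alpha=alpha_t,
        )
        return self


def correlation_screen(
    matrix: SchoolMeasureMatrix | pd.DataFrame,
    effective_measures: int | str = "auto",
) -> CorrelationScreen:
    """Screen all measure pairs; see :class:`CorrelationScreener`.

    ``effective_measures`` may be "auto", or the effective number of
    measures m (the test count becomes C(m, 2)).
    """
    if effective_measures == "auto":
        eff: int | str = "auto"
    else:
        m = int(effective_measures)
        eff = m * (m - 1) // 2
    return CorrelationScreener(effective_tests=eff).fit(matrix).screen_


# ---------------------------------------------------------------------------
# Group comparisons (Welch)


@dataclass
class GroupComparison:
    """Per-measure Welch t comparison of two school groups."""

    table: pd.DataFrame  # mean/sd/n per group, t, df, p, higher_group
    group_names: tuple[str, str]
    tukey_alpha: float

    def n_significant(self, alpha: float = 0.05) -> int:
        return int((self.table["p"] < alpha).sum())


def group_compare(
    matrix: SchoolMeasureMatrix | pd.DataFrame,
    group_flag: Sequence[bool] | pd.Series,
    group_names: tuple[str, str] = ("group1", "group0"),
    tukey_divisor: int | None = None,
) -> GroupComparison:
    """Welch t-test of every measure between two unit groups.

    ``group_flag`` marks membership of the first group.  Welch's t with
    Satterthwaite df allows unequal variances.  The Tukey threshold for
    the family of comparisons uses 0.05/sqrt(divisor); the divisor
    defaults to the number of compared measures but is exposed because
    published analyses sometimes use the comparable-measure count.
    """
    values = matrix.values if isinstance(matrix, SchoolMeasureMatrix) else matrix
    flag = np.asarray(group_flag, dtype=bool)
    if flag.shape[0] != values.shape[0]:
        raise ValueError("group_flag length must match the number of units")
    a, b = values.loc[flag], values.loc[~flag]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 units")
    rows = []
    for m in values.columns:
        x, y = a[m].dropna(), b[m].dropna()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"group with <2 observations for measure {m!r}")
        res = stats.ttest_ind(x, y, equal_var=False)
        mean1, mean0 = float(x.mean()), float(y.mean())
        rows.append(
            {
                "measure": m,
                "mean1": mean1,
                "sd1": float(x.std(ddof=1)),
                "n1": len(x),
                "mean0": mean0,
                "sd0": float(y.std(ddof=1)),
                "n0": len(y),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "higher_group": (
                    group_names[0]
                    if mean1 > mean0
                    else group_names[1] if mean0 > mean1 else ""
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("measure")
    divisor = tukey_divisor if tukey_divisor is not None else len(values.columns)
    return GroupComparison(
        table=table, group_names=group_names, tukey_alpha=tukey_threshold(divisor)
    )


# ---------------------------------------------------------------------------
# Partial correlation and OLS


@dataclass(frozen=True)
class PartialCorrelation:
    r_p: float
    df: int
    p: float
    x: str
    y: str
    controls: tuple[str, ...]


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), z])
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("collinear control set")
    return v - design @ coef


def partial_correlation(
    matrix: SchoolMeasureMatrix | pd.DataFrame,
    x: str,
    y: str,
    controls: Sequence[str] = (),
) -> PartialCorrelation:
    """Correlation of x and y after removing the controls from each.

    Both variables are residualized on the control set by least squares;
    the residual correlation is tested at df = n - 2 - #controls.  With
    no controls this reduces to the plain Pearson correlation.
    """
    values = matrix.values if isinstance(matrix, SchoolMeasureMatrix) else matrix
    controls = tuple(controls)
    if x in controls or y in controls:
        raise ValueError("controls must not include x or y")
    cols = [x, y, *controls]
    sub = values.loc[:, cols].dropna()
    n = sub.shape[0]
    df = n - 2 - len(controls)
    if df < 1:
        raise ValueError(f"not enough units (n={n}) for {len(controls)} controls")
    if controls:
        z = sub.loc[:, list(controls)].to_numpy()
        rx = _residualize(sub[x].to_numpy(), z)
        ry = _residualize(sub[y].to_numpy(), z)
    else:
        rx, ry = sub[x].to_numpy(), sub[y].to_numpy()
    r = float(np.corrcoef(rx, ry)[0, 1])
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r_p=r, df=df, p=p, x=x, y=y, controls=controls)


def linear_fit(
    matrix: SchoolMeasureMatrix | pd.DataFrame, y: str, x: str
) -> tuple[float, float, Callable[[float], float]]:
    """OLS of measure y on measure x at the unit level.

    Returns (intercept, slope, predict); predict evaluates the fitted
    line at arbitrary x, e.g. to extrapolate an outcome at a policy-
    relevant level of the predictor.
    """
    values = matrix.values if isinstance(matrix, SchoolMeasureMatrix) else matrix
    sub = values.loc[:, [x, y]].dropna()
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 units")
    xv, yv = sub[x].to_numpy(), sub[y].to_numpy()
    if np.std(xv) == 0:
        raise ValueError(f"zero variance in predictor {x!r}")
    slope, intercept = np.polyfit(xv, yv, 1)
    return (
        float(intercept),
        float(slope),
        lambda at: float(intercept + slope * at),
    )


# ---------------------------------------------------------------------------
# Null calibration


def null_calibration(
    n_units: int,
    n_measures: int,
    reps: int,
    seed: int,
    effective_measures: int | str = "auto",
) -> pd.Series:
    """Type-I behaviour of the screen on pure-noise matrices.

    Simulates ``reps`` independent Gaussian matrices, screens each, and
    returns the mean proportion of pairs reaching p < 0.05 and the
    Tukey tier.  On noise the p < 0.05 proportion should sit near 0.05
    and the Tukey proportion near the Tukey alpha itself.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    p05, tukey = [], []
    n_pairs = n_measures * (n_measures - 1) // 2
    for _ in range(reps):
        data = pd.DataFrame(
            rng.standard_normal((n_units, n_measures)),
            columns=[f"m{i}" for i in range(n_measures)],
        )
        scr = correlation_screen(data, effective_measures=effective_measures)
        p05.append(scr.n_significant(TIER_P05) / n_pairs)
        tukey.append(scr.n_significant(TIER_TUKEY) / n_pairs)
    return pd.Series(
        {
            "prop_p05": float(np.mean(p05)),
            "prop_tukey": float(np.mean(tukey)),
            "reps": reps,
        }
    )
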