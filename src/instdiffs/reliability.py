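"""Reliability of between-unit differences across occasions.

A measure observed on the same institutions in several years defines a
units x occasions panel; Cronbach's alpha over the occasions quantifies
how stable the *between-institution* differences are.  Unreliability
attenuates correlations: two measures with alphas a and b can correlate
empirically at most sqrt(a * b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import OccasionPanel

__all__ = [
    "ReliabilityResult",
    "cronbach_alpha",
    "attenuation_ceiling",
    "summarize_reliabilities",
]


@dataclass(frozen=True)
class ReliabilityResult:
    measure_name: str
    alpha: float
    n_occasions: int
    n_units: int
    n_dropped_units: int = 0


def cronbach_alpha(panel: OccasionPanel) -> ReliabilityResult:
    """Cronbach's alpha of between-unit differences across occasions.

    alpha = k/(k-1) * (1 - sum of per-occasion variances / variance of
    per-unit sums), with k occasions and variances taken over units
    (ddof=1).  Units with any missing occasion are dropped listwise and
    the count reported.  Alpha can be negative for pathological panels;
    it is reported unclipped with a warning.
    """
    if panel.n_occasions < 2:
        raise ValueError("at least 2 occasions required")
    complete = panel.values.dropna(axis=0, how="any")
    n_dropped = panel.n_units - complete.shape[0]
    if complete.shape[0] < 3:
        raise ValueError(
            f"fewer than 3 complete units ({complete.shape[0]}) in panel "
            f"{panel.measure_name!r}"
        )
    k = panel.n_occasions
    occ_var = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        # all unit sums identical: no between-unit signal at all
        alpha = 0.0
    else:
        alpha = (k / (k - 1)) * (1.0 - occ_var.sum() / total_var)
    if alpha < 0:
        warnings.warn(
            f"negative alpha ({alpha:.3f}) for {panel.measure_name!r}; "
            "between-unit differences are less consistent than chance",
            stacklevel=2,
        )
    return ReliabilityResult(
        measure_name=panel.measure_name,
        alpha=float(alpha),
        n_occasions=k,
        n_units=complete.shape[0],
        n_dropped_units=n_dropped,
    )


def attenuation_ceiling(alpha_a: float, alpha_b: float) -> float:
    """Maximum empirical correlation given the two reliabilities.

    sqrt(alpha_a * alpha_b); e.g. reliabilities 0.8 and 0.9 cap the
    observable correlation at 0.85.
    """
    if alpha_a <= 0 or alpha_b <= 0:
        raise ValueError("reliabilities must be positive")
    return float(np.sqrt(alpha_a * alpha_b))


def summarize_reliabilities(
    results: Sequence[ReliabilityResult | float],
) -> pd.Series:
    """Median, mean, sd, min, max and count of a set of alphas."""
    if len(results) == 0:
        raise ValueError("no reliability results to summarize")
    alphas = np.array(
        [r.alpha if isinstance(r, ReliabilityResult) else float(r) for r in results]
    )
    return pd.Series(
        {
            "median": float(np.median(alphas)),
            "mean": float(np.mean(alphas)),
            "sd": float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0,
            "min": float(np.min(alphas)),
            "max": float(np.max(alphas)),
            "count": int(len(alphas)),
        }
    )
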