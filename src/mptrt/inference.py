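"""Shared inferential machinery: chi-square tests and Akaike weights."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    """A chi-square-referenced test: statistic, degrees of freedom, p-value.

    ``kind`` is one of "G2" (likelihood-ratio goodness of fit), "DN"
    (Dzhaparidze-Nikulin goodness of fit) or "LRT" (nested model comparison).
    """

    statistic: float
    df: int
    pvalue: float
    kind: str

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError(f"df must be a positive integer, got {self.df}")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p": float(self.pvalue),
            "kind": self.kind,
        }


def chi2_test(statistic: float, df: int, kind: str) -> TestResult:
    statistic = max(float(statistic), 0.0)
    return TestResult(statistic, int(df), float(stats.chi2.sf(statistic, df)), kind)


def lrt(full, eq) -> TestResult:
    """Likelihood ratio test of a restricted (eq) against a full model fit.

    Both arguments must expose ``llf`` (maximized log-likelihood) and
    ``n_free_params``; the statistic 2*(llf_full - llf_eq) is floored at 0
    and referred to chi-square with df = difference in free parameters.
    """
    df = int(full.n_free_params) - int(eq.n_free_params)
    if df <= 0:
        raise ValueError(
            f"full model must have more free parameters than the restricted one "
            f"({full.n_free_params} vs {eq.n_free_params})"
        )
    return chi2_test(2.0 * (full.llf - eq.llf), df, "LRT")


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights: exp(-0.5 * (AIC_j - AIC_min)) normalized to sum to 1."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("need at least two AIC values")
    if not np.all(np.isfinite(aics)):
        raise ValueError("all AIC values must be finite")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()
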