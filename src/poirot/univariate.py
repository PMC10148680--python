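"""Single-trait variance-based POE comparator and multiple-trait corrections.

A parent-of-origin effect inflates the variance of a trait among
heterozygotes relative to homozygotes by (beta_M - beta_P)^2 / 4, so a
robust variance-heterogeneity test per trait (a Brown-Forsythe / median
Levene test, heterozygotes vs pooled homozygotes) detects POEs one trait at
a time.  With K traits the per-trait p-values are combined by comparing the
minimum against alpha/K (Bonferroni) or alpha/K_eff, where K_eff is the
effective number of independent traits: the minimum number of principal
components of the trait correlation matrix explaining at least 90% of the
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stat_core import MISSING, _as_geno, _as_pheno, median_center_by_genotype

__all__ = [
    "UnivariateResult",
    "brown_forsythe_poe",
    "effective_tests_keff",
    "univariate_decision",
    "univariate_poe_test",
]


@dataclass(frozen=True)
class UnivariateResult:
    """Per-trait Brown-Forsythe POE tests and their multi-trait summary."""

    statistics: np.ndarray
    pvalues: np.ndarray
    K: int
    K_eff: int
    min_pvalue: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "min_pvalue", float(np.min(self.pvalues)))
        if not 1 <= self.K_eff <= self.K:
            raise ValueError("K_eff must lie in [1, K]")

    def rejects(self, alpha: float, mode: str = "bonferroni_K") -> bool:
        return univariate_decision(self.pvalues, alpha, mode, self.K_eff)


def brown_forsythe_poe(y, g) -> tuple[float, float]:
    """Brown-Forsythe variance test for a POE on a single trait.

    The trait is median-centered within each genotype group (removing any
    marginal allelic effect), then absolute deviations from the comparison
    group's median are compared between heterozygotes and pooled
    homozygotes by one-way ANOVA; the F statistic is referred to F(1, n-2).

    Returns ``(statistic, pvalue)``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a single trait vector")
    g = _as_geno(g, y.shape[0])
    keep = g != MISSING
    y, g = y[keep], g[keep]
    x = median_center_by_genotype(y[:, None], g)[:, 0]
    het = x[g == 1]
    hom = x[g != 1]
    if het.size < 2 or hom.size < 2:
        raise ValueError("need >=2 heterozygotes and >=2 homozygotes")
    if np.ptp(het) == 0 and np.ptp(hom) == 0:
        raise ValueError("trait constant within both groups; statistic undefined")
    stat, pvalue = stats.levene(het, hom, center="median")
    return float(stat), float(pvalue)


def effective_tests_keff(Y=None, corr=None, threshold: float = 0.9) -> int:
    """Effective number of independent traits, K_eff.

    The smallest m such that the top-m eigenvalues of the K x K trait
    correlation matrix explain at least ``threshold`` of the total variance
    (trace K).  Using the correlation rather than the covariance matrix
    makes the count scale-free.

    Pass either raw traits ``Y`` (n x K; the sample correlation is used) or
    a correlation matrix ``corr`` directly.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if corr is None:
        Y = _as_pheno(Y)
        if Y.shape[1] < 2:
            raise ValueError("need K >= 2 traits")
        corr = np.corrcoef(Y, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    K = corr.shape[0]
    if K < 2 or corr.shape != (K, K):
        raise ValueError("correlation matrix must be square with K >= 2")
    eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    frac = np.cumsum(eigvals) / K
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def univariate_decision(pvals, alpha: float, mode: str, K_eff: int | None = None) -> bool:
    """Multi-trait rejection rule for the univariate comparator.

    True iff min(pvals) < alpha / K (``bonferroni_K``) or
    min(pvals) < alpha / K_eff (``bonferroni_Keff``).
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if mode == "bonferroni_K":
        denom = pvals.size
    elif mode == "bonferroni_Keff":
        if K_eff is None:
            raise ValueError("K_eff required for mode 'bonferroni_Keff'")
        denom = K_eff
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return bool(np.min(pvals) < alpha / denom)


def univariate_poe_test(Y, g) -> UnivariateResult:
    """Run the Brown-Forsythe POE test on every trait of Y."""
    Y = _as_pheno(Y)
    stats_, pvals = zip(*(brown_forsythe_poe(Y[:, k], g) for k in range(Y.shape[1])))
    return UnivariateResult(
        statistics=np.array(stats_),
        pvalues=np.array(pvals),
        K=Y.shape[1],
        K_eff=effective_tests_keff(Y),
    )
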