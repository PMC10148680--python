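"""Covariate adjustment of phenotypes and per-variant quality control.

Traits are adjusted once, before the genome scan, by ordinary least
squares against an intercept plus all covariates (categoricals
dummy-coded); the residuals are the phenotypes every downstream test sees.
Variants are filtered on minor-allele frequency, Hardy-Weinberg
equilibrium and missingness before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stat_core import MISSING

__all__ = ["QCThresholds", "VariantQC", "residualize", "variant_qc", "design_matrix"]


@dataclass(frozen=True)
class QCThresholds:
    """Variant filters: MAF > maf_min, HWE P > hwe_min, missingness < miss_max."""

    maf_min: float = 0.05
    hwe_min: float = 1e-8
    miss_max: float = 0.02


@dataclass(frozen=True)
class VariantQC:
    maf: float
    hwe_pvalue: float
    missing_rate: float
    passed: bool


def design_matrix(C: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric covariates + dummy-coded categoricals.

    Categorical (object/category/bool) columns are expanded with the first
    level dropped, e.g. a 4-level smoking factor contributes 3 columns.
    """
    if C.isna().any().any():
        raise ValueError("covariate table contains missing values; apply complete-case filtering first")
    if C.shape[1] == 0:
        X = pd.DataFrame(index=C.index)
    else:
        X = pd.get_dummies(C, drop_first=True, dtype=float)
    X.insert(0, "_intercept", 1.0)
    return X.astype(float)


def residualize(Y, C: pd.DataFrame) -> np.ndarray:
    """OLS-adjust each trait for covariates; returns the residual matrix.

    Raises on a rank-deficient design, naming the collinear columns, since
    silently dropping them would make the adjustment irreproducible.
    Residualizing is idempotent: applying it twice with the same covariates
    returns the same matrix.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != len(C):
        raise ValueError("Y must be n x K with n matching the covariate table")
    X = design_matrix(C)
    Xv = X.to_numpy()
    _, r = np.linalg.qr(Xv)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r).max() * 1e-10 * max(Xv.shape)))
    if rank < Xv.shape[1]:
        # pivoted QR exposes which columns fail to add rank
        from scipy.linalg import qr as pivoted_qr

        _, _, piv = pivoted_qr(Xv, mode="economic", pivoting=True)
        bad = sorted(X.columns[j] for j in piv[rank:])
        raise ValueError(f"collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    return Y - Xv @ beta


def variant_qc(g, thresholds: QCThresholds = QCThresholds()) -> VariantQC:
    """MAF / HWE / missingness metrics and pass flag for one variant.

    HWE is a 1-df chi-square goodness-of-fit of the genotype counts
    against the proportions implied by the estimated allele frequency.
    Symmetric in allele labels (swapping codes 0 and 2 changes nothing).
    """
    g = np.asarray(g)
    miss = g == MISSING
    missing_rate = float(miss.mean()) if g.size else 1.0
    gv = g[~miss]
    if gv.size == 0:
        return VariantQC(maf=np.nan, hwe_pvalue=np.nan, missing_rate=missing_rate, passed=False)
    n = gv.size
    counts = np.array([(gv == 0).sum(), (gv == 1).sum(), (gv == 2).sum()], dtype=float)
    p = (2 * counts[2] + counts[1]) / (2 * n)
    maf = float(min(p, 1 - p))
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    if maf == 0.0:
        hwe_p = 1.0  # monomorphic: trivially in equilibrium
    else:
        chi2 = float(np.sum((counts - expected) ** 2 / expected))
        hwe_p = float(stats.chi2.sf(chi2, df=1))
    passed = (
        maf > thresholds.maf_min
        and hwe_p > thresholds.hwe_min
        and missing_rate < thresholds.miss_max
    )
    return VariantQC(maf=maf, hwe_pvalue=hwe_p, missing_rate=missing_rate, passed=passed)
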