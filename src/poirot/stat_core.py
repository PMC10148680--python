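"""Robust covariance-equality test for parent-of-origin effects (POEs).

A variant with a POE inflates the phenotypic covariance matrix of
heterozygotes relative to homozygotes by a rank-one term
``1/4 (beta_M - beta_P)(beta_M - beta_P)'``, where ``beta_M`` and ``beta_P``
are the maternal and paternal effect vectors of the alternative allele on
the K traits.  POIROT therefore tests ``H0: Sigma_het = Sigma_hom`` with a
robust omnibus procedure: phenotypes are median-centered within each
genotype group, per-subject cross-product features are formed for every
trait pair, square-root standardized, and the two groups are compared with
a two-sample Hotelling's T^2 test on the p = K(K+1)/2 feature means.

The same machinery restricted to the two homozygote classes (AA vs BB)
yields a post hoc test that separates pure POEs (homozygote covariances
equal) from general gene-gene / gene-environment interaction effects
(homozygote covariances differ).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "MISSING",
    "TestStatus",
    "CovTestResult",
    "pair_index",
    "median_center_by_genotype",
    "w_features",
    "hotelling_two_sample",
    "poirot_test",
    "posthoc_interaction_test",
]

#: Missing-genotype marker used throughout (genotypes are int codes 0/1/2).
MISSING = -1


class TestStatus(str, Enum):
    """Outcome state of a covariance-equality test."""

    OK = "ok"
    SINGULAR = "singular"
    INSUFFICIENT_N = "insufficient_n"


@dataclass(frozen=True)
class CovTestResult:
    """Result of a two-group robust covariance-equality test.

    Attributes
    ----------
    t2 : float
        Hotelling's T^2 statistic (NaN unless status is ``ok``).
    f_stat : float
        The exact F transform of ``t2``.
    df1, df2 : int
        F numerator/denominator degrees of freedom; ``df1 = p`` and
        ``df2 = n_group1 + n_group2 - p - 1``.
    pvalue : float
        Upper tail of F(df1, df2); valid only when status is ``ok``.
    n_group1, n_group2 : int
        Group sizes actually used.
    status : TestStatus
        ``ok``, ``singular`` (pooled covariance not invertible) or
        ``insufficient_n``.
    """

    t2: float
    f_stat: float
    df1: int
    df2: int
    pvalue: float
    n_group1: int
    n_group2: int
    status: TestStatus = TestStatus.OK

    def __post_init__(self):
        if self.status == TestStatus.OK and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"invalid p-value {self.pvalue}")


def _failed(status: TestStatus, p: int, n1: int, n2: int) -> CovTestResult:
    return CovTestResult(
        t2=np.nan, f_stat=np.nan, df1=p, df2=n1 + n2 - p - 1,
        pvalue=np.nan, n_group1=n1, n_group2=n2, status=status,
    )


def _as_pheno(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("phenotype matrix must be 2-dimensional (n x K)")
    if not np.all(np.isfinite(Y)):
        raise ValueError("phenotype matrix contains missing/non-finite entries")
    return Y


def _as_geno(g, n: int) -> np.ndarray:
    g = np.asarray(g)
    if g.shape != (n,):
        raise ValueError(f"genotype vector length {g.shape} does not match n={n}")
    g = g.astype(np.int64, copy=False)
    valid = (g == MISSING) | ((g >= 0) & (g <= 2))
    if not np.all(valid):
        raise ValueError("genotypes must be coded 0/1/2 with -1 for missing")
    return g


def pair_index(K: int) -> list[tuple[int, int]]:
    """Ordered trait pairs (k, k') with k <= k'.

    Row-major upper triangle including the diagonal:
    (0,0),(0,1),...,(0,K-1),(1,1),...,(K-1,K-1).  This ordering is fixed so
    that feature matrices are reproducible across runs.
    """
    return [(k, kp) for k in range(K) for kp in range(k, K)]


def median_center_by_genotype(Y, g) -> np.ndarray:
    """Center each trait by its median within each genotype group.

    Removes any marginal (non-parent-of-origin) allelic effect, which would
    otherwise inflate the pooled-homozygote covariance: a shift common to a
    genotype group is absorbed by that group's median.

    Rows with missing genotype are returned unchanged (they are excluded
    from every downstream computation anyway).
    """
    Y = _as_pheno(Y)
    g = _as_geno(g, Y.shape[0])
    out = Y.copy()
    for code in (0, 1, 2):
        rows = g == code
        if rows.any():
            out[rows] -= np.median(Y[rows], axis=0)
    return out


def w_features(Xc, group_mask) -> np.ndarray:
    """Square-root-standardized cross-product features for one group.

    For each selected subject i and trait pair (k, k') the raw feature is
    ``Z = (x_ik - M_k)(x_ik' - M_k')`` where ``M_k`` is the group median of
    trait k over the selected rows; the returned feature is
    ``W = sign(Z) * sqrt(|Z|)`` (the continuous extension W = 0 at Z = 0).
    Group means of W estimate robust variance/covariance summaries, so
    comparing them between genotype groups compares covariance matrices.

    Parameters
    ----------
    Xc : array (n, K)
        Phenotypes already median-centered per genotype group.
    group_mask : boolean array (n,)
        Selects the rows of one pooled group.

    Returns
    -------
    array (m, p) with p = K(K+1)/2, columns ordered as :func:`pair_index`.
    """
    Xc = _as_pheno(Xc)
    group_mask = np.asarray(group_mask, dtype=bool)
    X = Xc[group_mask]
    if X.shape[0] < 2:
        raise InsufficientGroupError("need at least 2 subjects in a group")
    D = X - np.median(X, axis=0)
    K = X.shape[1]
    idx = np.array(pair_index(K))
    Z = D[:, idx[:, 0]] * D[:, idx[:, 1]]
    return np.sign(Z) * np.sqrt(np.abs(Z))


class InsufficientGroupError(ValueError):
    """A genotype group is too small for the requested test."""


def hotelling_two_sample(W1, W2) -> CovTestResult:
    """Two-sample Hotelling's T^2 test on feature means.

    t^2 = n1 n2 / (n1 + n2) * (Wbar1 - Wbar2)' S^{-1} (Wbar1 - Wbar2)
    with S the pooled covariance (denominator n1 + n2 - 2).  Under the null
    t^2 follows T^2(p, n1+n2-2); the p-value is taken from the exact F
    transform F = (n1+n2-p-1) / (p (n1+n2-2)) * t^2 ~ F(p, n1+n2-p-1).

    A singular pooled covariance is reported as ``status=singular`` rather
    than silently pseudo-inverted, because a pseudo-inverse changes the
    null distribution of the statistic.
    """
    W1 = np.asarray(W1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    if W1.ndim != 2 or W2.ndim != 2 or W1.shape[1] != W2.shape[1]:
        raise ValueError("feature matrices must be 2-d with equal column count")
    n1, p = W1.shape
    n2 = W2.shape[0]
    if n1 + n2 <= p + 1 or n1 < 2 or n2 < 2:
        return _failed(TestStatus.INSUFFICIENT_N, p, n1, n2)
    d = W1.mean(axis=0) - W2.mean(axis=0)
    S = ((n1 - 1) * np.cov(W1, rowvar=False) + (n2 - 1) * np.cov(W2, rowvar=False)) / (
        n1 + n2 - 2
    )
    S = np.atleast_2d(S)
    try:
        c, low = _cho_factor(S)
        x = _cho_solve((c, low), d)
    except np.linalg.LinAlgError:
        return _failed(TestStatus.SINGULAR, p, n1, n2)
    t2 = (n1 * n2 / (n1 + n2)) * float(d @ x)
    df1 = p
    df2 = n1 + n2 - p - 1
    f_stat = df2 / (df1 * (n1 + n2 - 2)) * t2
    pvalue = float(stats.f.sf(f_stat, df1, df2))
    return CovTestResult(
        t2=t2, f_stat=f_stat, df1=df1, df2=df2, pvalue=pvalue,
        n_group1=n1, n_group2=n2, status=TestStatus.OK,
    )


def _cho_factor(S):
    # scipy's cho_factor raises scipy.linalg.LinAlgError; normalise to numpy's
    from scipy.linalg import cho_factor as cf, LinAlgError as SciLinAlgError

    try:
        return cf(S, lower=True)
    except (SciLinAlgError, ValueError) as exc:  # ValueError on NaN/inf
        raise np.linalg.LinAlgError(str(exc))


def _cho_solve(factor, b):
    from scipy.linalg import cho_solve as cs

    return cs(factor, b)


def _prepare(Y, g):
    """Complete-case filter on genotype followed by per-genotype centering."""
    Y = _as_pheno(Y)
    g = _as_geno(g, Y.shape[0])
    keep = g != MISSING
    Y, g = Y[keep], g[keep]
    Xc = median_center_by_genotype(Y, g)
    return Xc, g


def _min_group(K: int, min_group: int | None) -> int:
    # default guarantees df2 = n1 + n2 - p - 1 > 0 with margin
    p = K * (K + 1) // 2
    return p + 2 if min_group is None else int(min_group)


def poirot_test(Y, g, min_group: int | None = None) -> CovTestResult:
    """POIROT test of covariance equality, heterozygotes vs homozygotes.

    Rejection indicates that the phenotypic covariance matrix of
    heterozygotes differs from that of pooled homozygotes, as expected at a
    variant with a parent-of-origin effect on one or more of the K traits.

    Parameters
    ----------
    Y : array (n, K)
        Complete covariate-adjusted phenotypes.
    g : array (n,)
        Genotypes coded 0 (AA), 1 (AB), 2 (BB); -1 for missing (those rows
        are dropped for this variant only).
    min_group : int, optional
        Minimum size required of each compared group; defaults to p + 2
        with p = K(K+1)/2.
    """
    Xc, g = _prepare(Y, g)
    K = Xc.shape[1]
    p = K * (K + 1) // 2
    het = g == 1
    hom = ~het
    lo = _min_group(K, min_group)
    n1, n2 = int(het.sum()), int(hom.sum())
    if n1 < lo or n2 < lo:
        return _failed(TestStatus.INSUFFICIENT_N, p, n1, n2)
    return hotelling_two_sample(w_features(Xc, het), w_features(Xc, hom))


def posthoc_interaction_test(Y, g, min_group: int | None = None) -> CovTestResult:
    """Post hoc AA-vs-BB covariance test to flag interaction effects.

    Under a pure POE the two homozygote groups share a covariance matrix
    (after per-genotype median centering), so this test stays null; under a
    gene-gene or gene-environment interaction their covariances differ and
    the test rejects.  Applied to variants already flagged by
    :func:`poirot_test` it discriminates POEs from general interactions.
    """
    Xc, g = _prepare(Y, g)
    K = Xc.shape[1]
    p = K * (K + 1) // 2
    aa = g == 0
    bb = g == 2
    lo = _min_group(K, min_group)
    n1, n2 = int(aa.sum()), int(bb.sum())
    if min(n1, n2) < lo:
        return _failed(TestStatus.INSUFFICIENT_N, p, n1, n2)
    return hotelling_two_sample(w_features(Xc, aa), w_features(Xc, bb))
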