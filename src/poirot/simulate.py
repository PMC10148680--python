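"""Synthetic cohorts with parent-of-origin effects, and study drivers.

The generator reproduces the canonical POE simulation design:

* Parental genotypes at one biallelic SNP are drawn as two Bernoulli(MAF)
  alleles per parent; each parent transmits one allele chosen by a fair
  coin, so offspring genotypes are in Hardy-Weinberg proportions and the
  maternal/paternal origin of a heterozygote's B allele is known to the
  generator (Bernoulli(1/2)) even though analysis methods never see it.
* K quantitative traits have intercepts mu_k ~ N(0,1), unit error
  variances, and pairwise error correlations drawn Uniform(0, 0.3) /
  (0.3, 0.5) / (0.5, 0.7) for low/medium/high correlation levels.
* Trait vectors follow y = mu + eps (AA), y = mu + beta_M + beta_P + eps
  (BB), and y = mu + pi*beta_M + (1-pi)*beta_P + eps (AB) with pi the
  maternal-origin indicator.
* Optionally the errors are made non-normal by the Vale-Maurelli
  construction: a Fleishman cubic polynomial of correlated standard
  normals, with intermediate correlations adjusted so the transformed
  variables hit the target correlation matrix.

Study drivers estimate type-I error and power for the POIROT covariance
test, the univariate Brown-Forsythe comparator, and the trio mean-based
MANOVA benchmark, including the sample-size ratio between the unrelated
and trio designs at matched power.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import optimize

from .stat_core import TestStatus, hotelling_two_sample, poirot_test, posthoc_interaction_test
from .univariate import univariate_poe_test

__all__ = [
    "CORRELATION_RANGES",
    "SimScenario",
    "CohortData",
    "StudySummary",
    "FleishmanFit",
    "draw_trait_covariance",
    "simulate_trio_genotypes",
    "fleishman_coefficients",
    "vale_maurelli_errors",
    "simulate_phenotypes",
    "simulate_gxe_phenotypes",
    "simulate_cohort",
    "run_null_study",
    "run_power_study",
    "trio_meanbased_test",
    "relative_efficiency",
    "null_grid",
    "power_grid",
]

#: Uniform ranges the pairwise trait correlations are drawn from.
CORRELATION_RANGES = {"low": (0.0, 0.3), "medium": (0.3, 0.5), "high": (0.5, 0.7)}

#: Nominal levels reported by the null study driver.
NULL_ALPHAS = (0.05, 0.005, 5e-4, 5e-5)

#: Nominal levels reported by the power study driver.
POWER_ALPHAS = (0.005, 5e-4)


@dataclass
class SimScenario:
    """One simulation setting.

    Parameters
    ----------
    K : number of traits (>= 2 for the covariance test).
    n : number of unrelated offspring per replicate.
    maf : minor (alternative B) allele frequency.
    corr_level : 'low' | 'medium' | 'high' pairwise trait correlation.
    beta_M, beta_P : K-vectors of maternal/paternal allele effects.
    error_model : 'normal' or 'vale_maurelli' (skewed errors).
    skew, excess_kurtosis : marginal targets for the skewed error model.
    replicates, seed : Monte-Carlo size and base seed.
    """

    K: int = 3
    n: int = 5000
    maf: float = 0.25
    corr_level: str = "medium"
    beta_M: np.ndarray | Sequence[float] | float = 0.0
    beta_P: np.ndarray | Sequence[float] | float = 0.0
    error_model: str = "normal"
    skew: float = 2.0
    excess_kurtosis: float = 2.0
    replicates: int = 2000
    seed: int = 0

    def __post_init__(self):
        self.beta_M = np.broadcast_to(np.asarray(self.beta_M, float), (self.K,)).copy()
        self.beta_P = np.broadcast_to(np.asarray(self.beta_P, float), (self.K,)).copy()
        if self.corr_level not in CORRELATION_RANGES:
            raise ValueError(f"unknown corr_level {self.corr_level!r}")
        if not 0 < self.maf < 1:
            raise ValueError("maf must be in (0, 1)")
        if self.error_model not in ("normal", "vale_maurelli"):
            raise ValueError(f"unknown error_model {self.error_model!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_M"] = list(map(float, self.beta_M))
        d["beta_P"] = list(map(float, self.beta_P))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        return cls(**d)


@dataclass
class CohortData:
    """One simulated replicate: traits, genotypes, and generator truth."""

    Y: np.ndarray
    g: np.ndarray
    origin: np.ndarray  # 1 maternal B, 0 paternal B, -1 where g != 1
    Sigma_true: np.ndarray
    mu_true: np.ndarray


@dataclass
class StudySummary:
    """Rejection frequencies with Monte-Carlo standard errors."""

    scenario: SimScenario
    alphas: tuple[float, ...]
    rejection: dict[str, dict[float, float]]
    mcse: dict[str, dict[float, float]]
    pvalues: dict[str, np.ndarray]
    n_effective: int

    @staticmethod
    def from_pvalues(scenario, alphas, pvalues: dict[str, np.ndarray]) -> "StudySummary":
        rejection, mcse = {}, {}
        n_eff = 0
        for method, pv in pvalues.items():
            pv = np.asarray(pv, float)
            pv = pv[np.isfinite(pv)]
            n_eff = max(n_eff, pv.size)
            rejection[method] = {a: float(np.mean(pv < a)) for a in alphas}
            mcse[method] = {
                a: float(np.sqrt(r * (1 - r) / max(pv.size, 1)))
                for a, r in rejection[method].items()
            }
        return StudySummary(scenario, tuple(alphas), rejection, mcse, pvalues, n_eff)


# ---------------------------------------------------------------------------
# building blocks


def _nearest_correlation(A: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped projection of a symmetric matrix to a PD correlation."""
    w, V = np.linalg.eigh((A + A.T) / 2)
    w = np.clip(w, eig_floor, None)
    B = (V * w) @ V.T
    d = np.sqrt(np.diag(B))
    B = B / np.outer(d, d)
    np.fill_diagonal(B, 1.0)
    return B


def draw_trait_covariance(K: int, corr_level: str, rng: np.random.Generator,
                          max_retries: int = 100) -> np.ndarray:
    """Random unit-diagonal trait correlation matrix for one replicate.

    Off-diagonal entries are i.i.d. Uniform over the level's range; draws
    are repeated until the matrix is positive definite (up to
    ``max_retries``), after which the last draw is projected to the nearest
    PD correlation matrix with eigenvalue floor 1e-8.
    """
    if K < 2:
        raise ValueError("need K >= 2")
    lo, hi = CORRELATION_RANGES[corr_level]
    iu = np.triu_indices(K, 1)
    for _ in range(max_retries):
        Sigma = np.eye(K)
        offdiag = rng.uniform(lo, hi, size=len(iu[0]))
        Sigma[iu] = offdiag
        Sigma.T[iu] = offdiag
        if np.linalg.eigvalsh(Sigma)[0] > 0:
            return Sigma
    return _nearest_correlation(Sigma)


def simulate_trio_genotypes(n: int, maf: float, rng: np.random.Generator):
    """Offspring genotypes from random-mating parents at one SNP.

    Each parent carries two alleles ~ Bernoulli(maf) (1 = alternative B)
    and transmits one chosen by a fair coin.  Returns ``(g, origin)`` with
    g in {0,1,2} (B-allele count) and origin = 1 where a heterozygote's B
    allele is maternal, 0 where paternal, -1 for homozygotes.
    """
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    mother = rng.binomial(1, maf, size=(n, 2))
    father = rng.binomial(1, maf, size=(n, 2))
    pick_m = rng.integers(0, 2, size=n)
    pick_f = rng.integers(0, 2, size=n)
    mat = mother[np.arange(n), pick_m]
    pat = father[np.arange(n), pick_f]
    g = (mat + pat).astype(np.int8)
    origin = np.full(n, -1, dtype=np.int8)
    het = g == 1
    origin[het] = mat[het]
    return g, origin


@dataclass(frozen=True)
class FleishmanFit:
    """Fleishman cubic ``Y = a + bZ + cZ^2 + dZ^3`` fitted to target moments.

    ``a = -c`` so E[Y] = 0 and the variance equation is solved exactly;
    ``residual`` is the remaining (skewness, excess kurtosis) equation
    error.  ``feasible`` is False when the residual exceeds tolerance —
    some (skew, kurtosis) targets lie outside the cubic's attainable
    region, in which case the coefficients are the least-squares closest
    match and ``achieved_skew`` / ``achieved_excess_kurtosis`` report what
    the polynomial actually produces.
    """

    a: float
    b: float
    c: float
    d: float
    residual: float
    feasible: bool
    achieved_skew: float
    achieved_excess_kurtosis: float

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def _fleishman_moments(b: float, c: float, d: float) -> tuple[float, float, float]:
    """(variance, skewness, excess kurtosis) of a + bZ + cZ^2 + dZ^3, a=-c.

    The skewness/kurtosis expressions are the classical Fleishman moment
    equations, exact when the variance equals one; callers enforce the
    unit-variance constraint before using them.
    """
    var = b * b + 6 * b * d + 2 * c * c + 15 * d * d
    skew = 2 * c * (b * b + 24 * b * d + 105 * d * d + 2)
    kurt = 24 * (
        b * d
        + c * c * (1 + b * b + 28 * b * d)
        + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)
    )
    return var, skew, kurt


@lru_cache(maxsize=64)
def fleishman_coefficients(skew: float, excess_kurtosis: float,
                           tol: float = 1e-8) -> FleishmanFit:
    """Solve the Fleishman moment system for given skewness/excess kurtosis.

    The variance-1 constraint is enforced exactly by solving for b given
    (c, d); (c, d) are then fitted by least squares to the skewness and
    kurtosis equations.  Targets outside the cubic's feasible region (for
    instance any point at or below the universal bound
    excess kurtosis = skew^2 - 2) are flagged infeasible and the closest
    attainable moments are reported.
    """

    def b_of(c, d):
        # b^2 + 6bd + (2c^2 + 15d^2 - 1) = 0  =>  b = -3d + sqrt(1 - 2c^2 - 6d^2)
        disc = 1.0 - 2 * c * c - 6 * d * d
        if disc <= 0:
            return None
        return -3 * d + np.sqrt(disc)

    def residuals(x):
        c, d = x
        b = b_of(c, d)
        if b is None:
            return [1e3 * (1 + abs(c)), 1e3 * (1 + abs(d))]
        _, s, k = _fleishman_moments(b, c, d)
        return [s - skew, k - excess_kurtosis]

    x0 = np.array([np.clip(skew / 6.0, -0.6, 0.6), np.clip(excess_kurtosis / 50.0, -0.2, 0.2)])
    sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    c, d = sol.x
    b = b_of(c, d)
    if b is None:  # pragma: no cover - guarded by the solver penalty
        b, c, d = 1.0, 0.0, 0.0
    var, s_ach, k_ach = _fleishman_moments(b, c, d)
    resid = float(np.hypot(s_ach - skew, k_ach - excess_kurtosis))
    return FleishmanFit(
        a=-c, b=float(b), c=float(c), d=float(d),
        residual=resid, feasible=resid < tol,
        achieved_skew=float(s_ach), achieved_excess_kurtosis=float(k_ach),
    )


def _intermediate_correlation(rho_target: float, fit: FleishmanFit) -> float:
    """Normal-scale correlation giving ``rho_target`` after the cubic map.

    For identical marginal transforms the relation is
    rho_Y = rho (b^2 + 6bd + 9d^2) + 2 rho^2 c^2 + 6 rho^3 d^2.
    """
    b, c, d = fit.b, fit.c, fit.d

    def f(rho):
        return (
            rho * (b * b + 6 * b * d + 9 * d * d)
            + 2 * rho * rho * c * c
            + 6 * rho ** 3 * d * d
            - rho_target
        )

    if rho_target == 0.0:
        return 0.0
    return float(optimize.brentq(f, -1.0, 1.0, xtol=1e-12))


def vale_maurelli_errors(n: int, Sigma: np.ndarray, skew: float,
                         excess_kurtosis: float, rng: np.random.Generator,
                         fit: FleishmanFit | None = None) -> np.ndarray:
    """Correlated non-normal errors with unit variances.

    Standard normals with an adjusted ("intermediate") correlation matrix
    are pushed through a shared Fleishman cubic so the outputs have mean
    ~0, variance 1, the (closest attainable) target skewness and excess
    kurtosis, and correlation approximately ``Sigma``.
    """
    Sigma = np.asarray(Sigma, float)
    K = Sigma.shape[0]
    if fit is None:
        fit = fleishman_coefficients(skew, excess_kurtosis)
    R = np.eye(K)
    iu = np.triu_indices(K, 1)
    for i, j in zip(*iu):
        R[i, j] = R[j, i] = _intermediate_correlation(Sigma[i, j], fit)
    w = np.linalg.eigvalsh(R)
    if w[0] <= 0:
        R = _nearest_correlation(R)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, K)) @ L.T
    a, b, c, d = fit.coefficients
    return a + Z * (b + Z * (c + Z * d))


def _draw_errors(n: int, Sigma: np.ndarray, rng: np.random.Generator,
                 error_model: str = "normal", skew: float = 2.0,
                 excess_kurtosis: float = 2.0) -> np.ndarray:
    if error_model == "vale_maurelli":
        return vale_maurelli_errors(n, Sigma, skew, excess_kurtosis, rng)
    L = np.linalg.cholesky(Sigma)
    return rng.standard_normal((n, Sigma.shape[0])) @ L.T


def simulate_phenotypes(g, origin, mu, Sigma, beta_M, beta_P,
                        rng: np.random.Generator, error_model: str = "normal",
                        skew: float = 2.0, excess_kurtosis: float = 2.0,
                        eps: np.ndarray | None = None) -> np.ndarray:
    """Trait matrix under the POE phenotype model.

    AA: y = mu + eps; BB: y = mu + beta_M + beta_P + eps;
    AB: y = mu + pi*beta_M + (1-pi)*beta_P + eps with pi the maternal-origin
    indicator.  Errors have covariance Sigma (normal, or Vale-Maurelli
    skewed); a pre-drawn ``eps`` can be supplied to share a random stream
    across effect settings.
    """
    g = np.asarray(g)
    n = g.shape[0]
    mu = np.asarray(mu, float)
    beta_M = np.asarray(beta_M, float)
    beta_P = np.asarray(beta_P, float)
    K = mu.shape[0]
    if eps is None:
        eps = _draw_errors(n, np.asarray(Sigma, float), rng, error_model,
                           skew, excess_kurtosis)
    shift = np.zeros((n, K))
    shift[g == 2] = beta_M + beta_P
    het = g == 1
    if het.any():
        origin = np.asarray(origin)
        pi = origin[het, None].astype(float)
        shift[het] = pi * beta_M + (1.0 - pi) * beta_P
    return mu + shift + eps


def simulate_gxe_phenotypes(g, covariate, main_effects, interaction_fractions,
                            mu, Sigma, rng: np.random.Generator,
                            maf: float) -> np.ndarray:
    """Traits with a covariate main effect and gene-covariate interactions.

    ``main_effects`` (K-vector) multiplies the standard-normal covariate;
    ``interaction_fractions`` (K-vector, each in [0, 0.05]) give the share
    of each trait's total variance explained by a (genotype - 2*maf) x
    covariate interaction.  Interaction coefficients are scaled
    analytically using Var(g) = 2*maf*(1-maf) and Var(covariate) = 1.
    """
    g = np.asarray(g, float)
    covariate = np.asarray(covariate, float)
    alpha = np.asarray(main_effects, float)
    frac = np.asarray(interaction_fractions, float)
    if np.any((frac < 0) | (frac >= 0.05 + 1e-12)):
        raise ValueError("interaction fractions must lie in [0, 0.05]")
    mu = np.asarray(mu, float)
    n, K = g.shape[0], mu.shape[0]
    eps = _draw_errors(n, np.asarray(Sigma, float), rng)
    var_g = 2 * maf * (1 - maf)
    base_var = 1.0 + alpha ** 2  # unit error variance + covariate main effect
    gamma = np.sqrt(frac * base_var / ((1.0 - frac) * var_g))
    gc = (g - 2 * maf)[:, None] * covariate[:, None]
    return mu + covariate[:, None] * alpha + gc * gamma + eps


def simulate_cohort(scenario: SimScenario, rng: np.random.Generator) -> CohortData:
    """One full replicate: correlation draw, trios, traits.

    The random stream is consumed in a fixed order (Sigma, mu, genotypes,
    errors) that does not depend on the effect vectors, so two scenarios
    differing only in (beta_M, beta_P) share every random draw.
    """
    Sigma = draw_trait_covariance(scenario.K, scenario.corr_level, rng)
    mu = rng.standard_normal(scenario.K)
    g, origin = simulate_trio_genotypes(scenario.n, scenario.maf, rng)
    Y = simulate_phenotypes(
        g, origin, mu, Sigma, scenario.beta_M, scenario.beta_P, rng,
        error_model=scenario.error_model, skew=scenario.skew,
        excess_kurtosis=scenario.excess_kurtosis,
    )
    return CohortData(Y=Y, g=g, origin=origin, Sigma_true=Sigma, mu_true=mu)


def _replicate_rngs(scenario: SimScenario) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(scenario.seed)
    return [np.random.default_rng(s) for s in ss.spawn(scenario.replicates)]


# ---------------------------------------------------------------------------
# study drivers


def run_null_study(scenario: SimScenario, alphas=NULL_ALPHAS,
                   posthoc: bool = False) -> StudySummary:
    """Monte-Carlo type-I error of the POIROT test under beta_M = beta_P.

    Each replicate draws a fresh correlation matrix, intercepts, trio
    genotypes and errors, then runs the covariance test (and optionally the
    post hoc AA-vs-BB test).  Raw p-values are retained for QQ plots.
    """
    if not np.array_equal(scenario.beta_M, scenario.beta_P):
        raise ValueError("null study requires beta_M == beta_P")
    pv_main, pv_post = [], []
    for rng in _replicate_rngs(scenario):
        cohort = simulate_cohort(scenario, rng)
        res = poirot_test(cohort.Y, cohort.g)
        pv_main.append(res.pvalue if res.status == TestStatus.OK else np.nan)
        if posthoc:
            rp = posthoc_interaction_test(cohort.Y, cohort.g)
            pv_post.append(rp.pvalue if rp.status == TestStatus.OK else np.nan)
    pvalues = {"poirot": np.array(pv_main)}
    if posthoc:
        pvalues["posthoc"] = np.array(pv_post)
    return StudySummary.from_pvalues(scenario, alphas, pvalues)


def run_power_study(scenario: SimScenario,
                    methods: Iterable[str] = ("poirot", "univariate_bonfK", "univariate_bonfKeff"),
                    alphas=POWER_ALPHAS) -> StudySummary:
    """Monte-Carlo power of POIROT and the univariate comparator.

    The univariate comparator rejects when its minimum per-trait
    Brown-Forsythe p-value falls below alpha/K (``univariate_bonfK``) or
    alpha/K_eff (``univariate_bonfKeff``); K_eff is re-estimated from each
    replicate's traits.  Rejection indicators are encoded as pseudo
    p-values (0/1) so every method shares the StudySummary bookkeeping.
    """
    methods = tuple(methods)
    need_uni = any(m.startswith("univariate") for m in methods)
    pv: dict[str, list[float]] = {m: [] for m in methods}
    for rng in _replicate_rngs(scenario):
        cohort = simulate_cohort(scenario, rng)
        if "poirot" in methods:
            res = poirot_test(cohort.Y, cohort.g)
            pv["poirot"].append(res.pvalue if res.status == TestStatus.OK else np.nan)
        if need_uni:
            uni = univariate_poe_test(cohort.Y, cohort.g)
            for m, mode in (
                ("univariate_bonfK", "bonferroni_K"),
                ("univariate_bonfKeff", "bonferroni_Keff"),
            ):
                if m in methods:
                    # store the Bonferroni-adjusted minimum so thresholding at
                    # alpha reproduces the min-p decision rule exactly
                    denom = uni.K if mode == "bonferroni_K" else uni.K_eff
                    pv[m].append(min(uni.min_pvalue * denom, 1.0))
    return StudySummary.from_pvalues(scenario, alphas, {m: np.array(v) for m, v in pv.items()})


def trio_meanbased_test(Y_het, origin) -> float:
    """One-way MANOVA comparing heterozygotes by parental origin.

    The benchmark available when parental transmissions are observed (trio
    designs): heterozygous offspring are grouped by whether the B allele is
    maternal or paternal and their mean trait vectors compared.  Returns
    the p-value (two-group MANOVA == Hotelling's T^2 with the exact F
    transform).
    """
    Y_het = np.asarray(Y_het, float)
    origin = np.asarray(origin)
    m = origin == 1
    if m.all() or (~m).all():
        raise ValueError("both parental-origin classes must be non-empty")
    res = hotelling_two_sample(Y_het[m], Y_het[~m])
    if res.status != TestStatus.OK:
        raise ValueError(f"trio MANOVA failed: {res.status}")
    return res.pvalue


def _power_at(method: Callable[[CohortData], float], scenario: SimScenario,
              n: int, alpha: float) -> float:
    sc = SimScenario(**{**scenario.to_dict(), "n": int(n)})
    hits, total = 0, 0
    for rng in _replicate_rngs(sc):
        cohort = simulate_cohort(sc, rng)
        p = method(cohort)
        if np.isfinite(p):
            hits += p < alpha
            total += 1
    return hits / max(total, 1)


def _poirot_pvalue(cohort: CohortData) -> float:
    res = poirot_test(cohort.Y, cohort.g)
    return res.pvalue if res.status == TestStatus.OK else np.nan


def _trio_pvalue(cohort: CohortData) -> float:
    het = cohort.g == 1
    try:
        return trio_meanbased_test(cohort.Y[het], cohort.origin[het])
    except ValueError:
        return np.nan


def _bisect_sample_size(power_fn: Callable[[int], float], target: float,
                        n_lo: int, n_hi: int, max_n: int, iters: int = 8) -> int:
    """Smallest n (by bisection on a Monte-Carlo power curve) with power >= target."""
    p_hi = power_fn(n_hi)
    while p_hi < target:
        n_lo, n_hi = n_hi, n_hi * 2
        if n_hi > max_n:
            raise RuntimeError(
                f"power {p_hi:.3f} at n={n_lo} never reached target {target} within budget {max_n}"
            )
        p_hi = power_fn(n_hi)
    for _ in range(iters):
        if n_hi - n_lo <= max(2, n_lo // 50):
            break
        mid = (n_lo + n_hi) // 2
        if power_fn(mid) >= target:
            n_hi = mid
        else:
            n_lo = mid
    return n_hi


def relative_efficiency(scenario: SimScenario, target_power: float = 0.8,
                        alpha: float = 5e-4, max_n: int = 200_000,
                        n_lo_trio: int = 50, n_hi_trio: int = 200,
                        n_lo_poirot: int = 500, n_hi_poirot: int = 2000) -> dict:
    """Sample-size ratio of the unrelated-sample covariance test vs the trio test.

    Bisects the Monte-Carlo power curve of each method over the total
    number of simulated offspring to the smallest n reaching
    ``target_power`` at level ``alpha`` and returns
    ``n_poirot / n_trio`` together with both sample sizes.  The trio
    design simulates the same offspring cohorts but analyses only the
    heterozygotes, grouped by (known) parental origin.
    """
    n_trio = _bisect_sample_size(
        lambda n: _power_at(_trio_pvalue, scenario, n, alpha),
        target_power, n_lo_trio, n_hi_trio, max_n,
    )
    n_poirot = _bisect_sample_size(
        lambda n: _power_at(_poirot_pvalue, scenario, n, alpha),
        target_power, n_lo_poirot, n_hi_poirot, max_n,
    )
    return {
        "ratio": n_poirot / n_trio,
        "n_poirot": n_poirot,
        "n_trio": n_trio,
        "target_power": target_power,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# factorial grids


def null_grid(replicates: int = 2000, seed: int = 0) -> list[SimScenario]:
    """The 27 null settings: K x n x correlation level."""
    out = []
    for K in (3, 6, 10):
        for n in (3000, 5000, 10000):
            for level in ("low", "medium", "high"):
                out.append(SimScenario(K=K, n=n, maf=0.25, corr_level=level,
                                       replicates=replicates, seed=seed))
    return out


def power_grid(replicates: int = 5000, seed: int = 0) -> list[SimScenario]:
    """The 162 power settings: K x #affected x effect size x correlation x n.

    beta_P = 0 and the first 1, 2 or 3 traits get a maternal effect of 0.5,
    0.6 or 0.75; MAF 0.25; n in {5000, 10000}.
    """
    out = []
    for K in (3, 6, 10):
        for m in (1, 2, 3):
            for b in (0.5, 0.6, 0.75):
                for level in ("low", "medium", "high"):
                    for n in (5000, 10000):
                        beta_M = np.zeros(K)
                        beta_M[:m] = b
                        out.append(SimScenario(
                            K=K, n=n, maf=0.25, corr_level=level,
                            beta_M=beta_M, beta_P=np.zeros(K),
                            replicates=replicates, seed=seed,
                        ))
    return out
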