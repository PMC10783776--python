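"""Power-based study design: minimum m_e and k, thresholds, degree calls.

The design problem: across N = sum_{i<j} n_i n_j cross-cohort pairs,
detect pairs of relatedness theta against unrelated pairs, holding the
experiment-wise type-I error at alpha and the type-II error at beta.
Under the normal approximation of the score distributions this is a
one-sided two-sample power calculation, giving lower bounds on the
effective marker number m_e and the projection dimension k:

    m_e > ((z_{1-a} + z_{1-b} sqrt(1 + theta^2)) / theta)^2
    k   > 1 / ((theta / (z_{1-b} sqrt(1 - theta^2) + z_{1-a}))^2 - 1/m_e)

where z_. are standard-normal quantiles at the Bonferroni-corrected
per-test level a = alpha / N.  Practical marker budgets default to twice
the m_e bound so that the realized (LD-adjusted) m_e stays above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


class InfeasibleDesign(ValueError):
    """The requested k bound is unattainable at the given m_e."""


@dataclass(frozen=True)
class ThetaConvention:
    """Effective relatedness theta(r) = deflation * 2^-r.

    The deflation (default 0.9) discounts the pedigree expectation for
    the attenuation observed in practice (imperfect genotypes, residual
    LD), so designs are powered against a slightly weaker signal than
    the idealized 2^-r.
    """

    deflation: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.deflation <= 1.0:
            raise ValueError("deflation must lie in (0, 1]")

    def theta(self, r: int) -> float:
        if r < 0 or r != int(r):
            raise ValueError("degree r must be a non-negative integer")
        return self.deflation * 2.0 ** (-r)


@dataclass
class DegreeDesign:
    """Resolved design for one target degree."""

    r: int
    theta_eff: float
    me_min: int
    me_practical: int
    k_min: int
    threshold: float


@dataclass
class DesignParams:
    """Full design: error rates, comparison count, per-degree parameters."""

    alpha_exp: float
    beta: float
    n_comparisons: int
    degrees: list[DegreeDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_exp < 1.0:
            raise ValueError("alpha_exp must lie in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.n_comparisons < 1:
            raise ValueError("comparison count must be >= 1")

    @property
    def alpha_test(self) -> float:
        return self.alpha_exp / self.n_comparisons

    def degree(self, r: int) -> DegreeDesign:
        for d in self.degrees:
            if d.r == r:
                return d
        raise KeyError(f"degree {r} not designed")


def z_quantile(p: float) -> float:
    """Inverse standard-normal CDF, accurate deep into the tails."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    return float(norm.ppf(p))


def effective_theta(r: int, convention: ThetaConvention | None = None) -> float:
    """Effective relatedness for degree r under the deflation convention."""
    return (convention or ThetaConvention()).theta(r)


def _strict_ceil(x: float) -> int:
    """Smallest integer strictly greater than x (bounds are strict inequalities)."""
    c = math.ceil(x)
    return c + 1 if c == x else c


def min_me(alpha: float, beta: float, theta: float) -> int:
    """Minimum effective marker number detecting relatedness theta.

    ``alpha`` is the per-test (Bonferroni-corrected) type-I error.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]; unrelated is not designable")
    za = z_quantile(1.0 - alpha)
    zb = z_quantile(1.0 - beta)
    return _strict_ceil(((za + zb * math.sqrt(1.0 + theta**2)) / theta) ** 2)


def min_k(alpha: float, beta: float, theta: float, m_e: float) -> int:
    """Minimum projection dimension k given the panel's effective m_e."""
    if not 0.0 < theta < 1.0 + 1e-12:
        raise ValueError("theta must lie in (0, 1]")
    if m_e <= 0:
        raise ValueError("m_e must be positive")
    za = z_quantile(1.0 - alpha)
    zb = z_quantile(1.0 - beta)
    denom = (theta / (zb * math.sqrt(max(1.0 - theta**2, 0.0)) + za)) ** 2 - 1.0 / m_e
    if denom <= 0.0:
        bound = _strict_ceil(((zb * math.sqrt(1.0 - theta**2) + za) / theta) ** 2)
        raise InfeasibleDesign(
            f"m_e = {m_e:g} too small for theta = {theta:g}: "
            f"increase m_e above {bound}"
        )
    return _strict_ceil(1.0 / denom)


def total_comparisons(sizes: list[int]) -> int:
    """N = sum over cohort pairs of n_i * n_j."""
    if len(sizes) < 2:
        raise ValueError("need at least two cohorts")
    if any(n < 1 for n in sizes):
        raise ValueError("all cohort sizes must be >= 1")
    total = sum(sizes)
    return (total * total - sum(n * n for n in sizes)) // 2


def detection_threshold(alpha_exp: float, n_comparisons: int, m_e: float, k: float) -> float:
    """Null-rejection threshold z_{1 - alpha/N} * sqrt(1/m_e + 1/k)."""
    if m_e <= 0 or k <= 0:
        raise ValueError("m_e and k must be positive")
    a = alpha_exp / n_comparisons
    if not 0.0 < a < 1.0:
        raise ValueError("alpha_exp / N must lie in (0, 1)")
    return z_quantile(1.0 - a) * math.sqrt(1.0 / m_e + 1.0 / k)


def build_design(
    alpha_exp: float,
    beta: float,
    sizes: list[int],
    degrees: list[int],
    empirical_me: dict[int, float] | None = None,
    convention: ThetaConvention | None = None,
    practical_factor: float = 2.0,
) -> DesignParams:
    """Resolve a full per-degree design from cohort sizes and target degrees.

    For each degree the m_e bound is evaluated at the effective theta; the
    practical marker budget defaults to ``practical_factor`` times the
    bound (markers are usually in surplus), and k is then bound at the
    empirical m_e when one is supplied, else at the practical budget.
    """
    convention = convention or ThetaConvention()
    n = total_comparisons(sizes)
    params = DesignParams(alpha_exp=alpha_exp, beta=beta, n_comparisons=n)
    a = params.alpha_test
    for r in sorted(degrees):
        theta = convention.theta(r)
        me_bound = min_me(a, beta, theta)
        me_prac = int(math.ceil(practical_factor * me_bound))
        me_for_k = (empirical_me or {}).get(r, me_prac)
        k = min_k(a, beta, theta, me_for_k)
        params.degrees.append(
            DegreeDesign(
                r=r,
                theta_eff=theta,
                me_min=me_bound,
                me_practical=me_prac,
                k_min=k,
                threshold=detection_threshold(alpha_exp, n, me_for_k, k),
            )
        )
    return params


def classify_degree(score: float, design: DesignParams) -> str:
    """Assign a degree label ('identical', '1st-degree', ...) or 'unrelated'.

    A score must clear the null threshold of the deepest designed degree
    to be called related at all; the degree is then the designed r whose
    pedigree expectation 2^-r is nearest on the log2 scale, with the
    identical class additionally gated by its own (k_0-based) threshold.
    """
    if not design.degrees:
        raise ValueError("design has no degrees")
    deepest = max(design.degrees, key=lambda d: d.r)
    if not math.isfinite(score) or score <= deepest.threshold:
        return "unrelated"
    candidates = sorted(design.degrees, key=lambda d: d.r)
    rs = np.array([d.r for d in candidates])
    dist = np.abs(np.log2(score) + rs)  # |log2(score) - log2(2^-r)|
    best = candidates[int(np.argmin(dist))]
    if best.r == 0 and score <= best.threshold:
        best = candidates[min(1, len(candidates) - 1)]
    return degree_label(best.r)


def degree_label(r: int) -> str:
    names = {0: "identical", 1: "1st-degree", 2: "2nd-degree", 3: "3rd-degree"}
    return names.get(r, f"{r}th-degree")


# ---------------------------------------------------------------------------
# effective-marker estimation


def estimate_me(data: np.ndarray, method: str = "grm_offdiag") -> float:
    """Estimate the effective number of markers of a SNP panel.

    ``grm_offdiag``: data is a reference-panel self-GRM (n x n); the
    estimate is 1 / var(off-diagonal entries).  ``ld_r2``: data is the
    m x m squared-correlation matrix of the panel; the estimate is
    m^2 / (m + sum of off-diagonal rho^2).
    """
    data = np.asarray(data, dtype=np.float64)
    if method == "grm_offdiag":
        if data.ndim != 2 or data.shape[0] != data.shape[1] or data.shape[0] < 2:
            raise ValueError("grm_offdiag needs a square GRM with >= 2 individuals")
        off = data[~np.eye(data.shape[0], dtype=bool)]
        v = float(off.var(ddof=1))
        if v <= 0.0:
            raise ValueError("degenerate off-diagonal variance 0")
        return 1.0 / v
    if method == "ld_r2":
        if data.ndim != 2 or data.shape[0] != data.shape[1]:
            raise ValueError("ld_r2 needs the square rho^2 matrix of the panel")
        m = data.shape[0]
        off_sum = float(data.sum() - np.trace(data))
        return m * m / (m + off_sum)
    raise ValueError(f"unknown m_e estimation method {method!r}")


def self_grm(z: np.ndarray) -> np.ndarray:
    """Self-GRM (1/m) Z Z^T of a standardized reference panel."""
    z = np.asarray(z, dtype=np.float64)
    return z @ z.T / z.shape[1]


def ld_r2_matrix(dosages: np.ndarray, adjusted: bool = True) -> np.ndarray:
    """Pairwise squared Pearson correlations between SNP columns.

    With ``adjusted`` (default) each off-diagonal rho^2 is corrected for
    its finite-sample bias, rho^2_adj = rho^2 - (1 - rho^2)/(n - 2), so
    that independent SNPs contribute ~0 instead of ~1/n and the m_e
    estimate is not dragged down when m approaches or exceeds n.
    """
    x = np.asarray(dosages, dtype=np.float64)
    r2 = np.corrcoef(x, rowvar=False) ** 2
    if adjusted:
        n = x.shape[0]
        if n <= 2:
            raise ValueError("bias adjustment needs more than 2 individuals")
        adj = r2 - (1.0 - r2) / (n - 2)
        np.fill_diagonal(adj, 1.0)
        return adj
    return r2


def design_report(params: DesignParams):
    """Tabulate a design as the report TSV schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "DEGREE": d.r,
                "THETA_EFF": d.theta_eff,
                "MIN_ME": d.me_min,
                "M_PRACTICAL": d.me_practical,
                "MIN_K": d.k_min,
                "THRESHOLD": d.threshold,
            }
            for d in params.degrees
        ]
    )
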