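"""Relatedness estimators: plain cross-cohort GRM, encrypted GRM, encG-reg.

All three estimators share the expectation E = theta_r = 2^-r for an
r-th-degree relative pair but differ in sampling variance (per marker
panel of effective size m_e and projection dimension k):

    GRM        (1 + theta^2) / m_e
    encGRM     (1 + theta^2) / k + (1 + theta^2) / m_e
    encG-reg   (1 - theta^2) / k + (1 - theta^2) / m_e

The regression slope trades the (1 + theta^2) factor for (1 - theta^2),
which is why it is the preferred detector at high relatedness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, EncryptedMatrix, GenotypeMatrix

ESTIMATORS = ("grm", "encgrm", "encg_reg")


class ProtocolMismatch(ValueError):
    """Two encrypted matrices were not built from the same S / SNP list."""


@dataclass
class StandardizedMatrix:
    """Frequency-standardized genotypes; missing cells are exactly zero."""

    values: np.ndarray  # float64 (n, m)
    freqs_used: np.ndarray  # (m,)
    m: int

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ScoreMatrix:
    """Pairwise scores between two cohorts for one estimator."""

    scores: np.ndarray  # (n1, n2)
    estimator: str
    sds: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if (self.sds is not None) != (self.estimator == "encg_reg"):
            raise ValueError("sds present iff estimator is encg_reg")


@dataclass(frozen=True)
class TheoreticalMoments:
    mean: float
    variance: float


def standardize(
    g: GenotypeMatrix, freqs: np.ndarray | None = None
) -> StandardizedMatrix:
    """Standardize dosages to z = (x - 2p) / sqrt(2 p (1-p)); missing -> 0.

    ``freqs`` is the per-SNP A1-frequency basis, in the SNP order of ``g``.
    When omitted, the cohort's own observed frequencies are used (the
    protocol default: only summaries cross sites).  Every p must lie
    strictly inside (0, 1).
    """
    if freqs is None:
        freqs = np.array([s.freq_a1 for s in g.snps], dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.shape != (g.m,):
        raise ValueError(f"freqs length {freqs.shape} does not match m={g.m}")
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        bad = [g.snps[j].snp_id for j in np.flatnonzero((freqs <= 0) | (freqs >= 1))]
        raise ValueError(f"monomorphic frequency basis for SNPs {bad[:5]}")
    x = g.dosages.astype(np.float64)
    z = (x - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    z[g.dosages == MISSING] = 0.0
    return StandardizedMatrix(values=z, freqs_used=freqs, m=g.m)


def grm_cross(z1: StandardizedMatrix, z2: StandardizedMatrix) -> ScoreMatrix:
    """Plain cross-cohort GRM: G12 = (1/m) Z1 Z2^T."""
    if z1.m != z2.m:
        raise ValueError("cohorts standardized over different marker counts")
    scores = (z1.values @ z2.values.T) / z1.m
    return ScoreMatrix(scores=scores, estimator="grm", meta={"m": z1.m})


def _check_pairable(e1: EncryptedMatrix, e2: EncryptedMatrix) -> None:
    if e1.k != e2.k:
        raise ProtocolMismatch(f"projection dimensions differ: {e1.k} != {e2.k}")
    if e1.seed_fingerprint != e2.seed_fingerprint:
        raise ProtocolMismatch("seed fingerprints differ: cohorts used different S")
    if e1.snp_list_hash != e2.snp_list_hash:
        raise ProtocolMismatch("SNP list hashes differ: cohorts used different panels")


def encgrm_cross(e1: EncryptedMatrix, e2: EncryptedMatrix) -> ScoreMatrix:
    """Encrypted GRM: (1/k) (Z1 S)(Z2 S)^T, with S entries N(0, 1/m)."""
    _check_pairable(e1, e2)
    scores = (e1.values @ e2.values.T) / e1.k
    return ScoreMatrix(
        scores=scores, estimator="encgrm", meta={"k": e1.k, "m": e1.m_used}
    )


def encg_reg_cross(e1: EncryptedMatrix, e2: EncryptedMatrix) -> ScoreMatrix:
    """encG-reg: per-pair slope of cohort-2 encrypted row on cohort-1 row.

    b_ij = cov(x1_i, x2_j) / var(x1_i) over the k projected columns
    (centered sample moments; the divisor cancels in the ratio).  The
    reported per-pair SD is sqrt((1 - b^2) / k), clipped below at zero.
    """
    _check_pairable(e1, e2)
    k = e1.k
    c1 = e1.values - e1.values.mean(axis=1, keepdims=True)
    c2 = e2.values - e2.values.mean(axis=1, keepdims=True)
    var1 = np.einsum("ij,ij->i", c1, c1) / k
    if np.any(var1 <= 0.0):
        bad = np.flatnonzero(var1 <= 0.0)
        raise ValueError(
            f"zero-variance encrypted rows in cohort 1: indices {bad[:5].tolist()}"
        )
    cov = (c1 @ c2.T) / k
    slopes = cov / var1[:, None]
    sds = np.sqrt(np.clip(1.0 - slopes**2, 0.0, None) / k)
    return ScoreMatrix(
        scores=slopes,
        estimator="encg_reg",
        sds=sds,
        meta={"k": k, "m": e1.m_used},
    )


def joint_nonmissing_fraction(
    callrates1: np.ndarray, callrates2: np.ndarray
) -> np.ndarray:
    """Pairwise joint non-missing fraction from per-individual call rates.

    Missingness is treated as independent between the two individuals
    (missing-completely-at-random), so the joint fraction is the product
    of the two call rates over the shared SNP list.
    """
    c1 = np.atleast_1d(np.asarray(callrates1, dtype=np.float64))
    c2 = np.atleast_1d(np.asarray(callrates2, dtype=np.float64))
    return np.outer(c1, c2)


def adjust_missing(
    score: np.ndarray | float,
    joint_fraction: np.ndarray | float,
    sd: np.ndarray | float | None = None,
):
    """Rescale scores (and SDs) for missing data: adjusted = score / fraction.

    Mean-imputed (zero) cells shrink the cross-moment proportionally to
    the joint non-missing fraction; dividing by it undoes the shrinkage.
    This is an approximation for the regression slope (see docs/methods.md).
    """
    frac = np.asarray(joint_fraction, dtype=np.float64)
    if np.any(frac <= 0.0) or np.any(frac > 1.0):
        raise ValueError("joint non-missing fraction must lie in (0, 1]")
    adjusted = np.asarray(score, dtype=np.float64) / frac
    if sd is None:
        return adjusted
    return adjusted, np.asarray(sd, dtype=np.float64) / frac


def theoretical_moments(
    estimator: str, theta: float, m_e: float, k: float | None = None
) -> TheoreticalMoments:
    """Expectation and sampling variance of an estimator at relatedness theta."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if m_e <= 0:
        raise ValueError("m_e must be positive")
    if estimator == "grm":
        var = (1.0 + theta**2) / m_e
    elif estimator in ("encgrm", "encg_reg"):
        if k is None or k <= 0:
            raise ValueError(f"{estimator} requires positive k")
        factor = (1.0 + theta**2) if estimator == "encgrm" else (1.0 - theta**2)
        var = factor / k + factor / m_e
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return TheoreticalMoments(mean=theta, variance=var)


def slope_sd(slope: float | np.ndarray, k: int) -> np.ndarray:
    """Reported SD of an encG-reg slope: sqrt((1 - b^2)/k), floored at 0."""
    b = np.asarray(slope, dtype=np.float64)
    return np.sqrt(np.clip(1.0 - b**2, 0.0, None) / k)


def relatedness_report(
    score: ScoreMatrix,
    cohort1: str,
    ids1: list[str],
    cohort2: str,
    ids2: list[str],
    joint_fraction: np.ndarray | None = None,
    degree_labels: np.ndarray | None = None,
    pairs: list[tuple[int, int]] | None = None,
):
    """Tabulate scores as the report TSV schema.

    ``pairs`` restricts the report to selected (i, j) index pairs;
    otherwise every pair is reported.
    """
    import pandas as pd

    if pairs is None:
        pairs = [(i, j) for i in range(len(ids1)) for j in range(len(ids2))]
    rows = []
    for i, j in pairs:
        s = float(score.scores[i, j])
        sd = float(score.sds[i, j]) if score.sds is not None else math.nan
        if joint_fraction is not None:
            f = float(joint_fraction[i, j])
            adj, adj_sd = s / f, sd / f
        else:
            adj, adj_sd = s, sd
        rows.append(
            {
                "COHORT1": cohort1,
                "ID1": ids1[i],
                "COHORT2": cohort2,
                "ID2": ids2[j],
                "SCORE": s,
                "SD": sd,
                "ADJ_SCORE": adj,
                "ADJ_SD": adj_sd,
                "DEGREE": (
                    degree_labels[i, j] if degree_labels is not None else ""
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "COHORT1",
            "ID1",
            "COHORT2",
            "ID2",
            "SCORE",
            "SD",
            "ADJ_SCORE",
            "ADJ_SD",
            "DEGREE",
        ],
    )
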