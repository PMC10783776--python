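"""Synthetic cohorts with planted relatives, and the validation harnesses.

Founder genotypes are Binomial(2, p) draws at independent SNPs whose
minor-allele frequencies follow U(0.05, 0.5) by default (so the
effective marker number equals the marker count).  Relatives are made
by gene-dropping: a chain of r meiosis steps, each transmitting one
uniformly-chosen allele from the current ancestor and drawing the other
fresh from the population, which yields genuine Mendelian segregation
and expected pairwise relatedness 2^-r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core, design as design_mod, encryption
from .io import MISSING, GenotypeMatrix, SnpMeta


@dataclass(frozen=True)
class MafLaw:
    """Marker-frequency law: uniform(a, b) or fixed(p)."""

    kind: str = "uniform"
    a: float = 0.05
    b: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "fixed"):
            raise ValueError("maf law must be 'uniform' or 'fixed'")
        lo = self.a if self.kind == "uniform" else self.a
        hi = self.b if self.kind == "uniform" else self.a
        if not (0.0 < lo and hi <= 0.5):
            raise ValueError("MAF bounds must lie within (0, 0.5]")

    def draw(self, m: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(m, self.a)
        return rng.uniform(self.a, self.b, m)


@dataclass(frozen=True)
class ScenarioSpec:
    """A two-cohort scenario: sizes, marker panel, planted pairs, missingness."""

    n1: int = 200
    n2: int = 200
    m: int = 1000
    maf_law: MafLaw = field(default_factory=MafLaw)
    planted_pairs: tuple[tuple[int, int], ...] = ()  # (degree r, count)
    missing_rate1: float = 0.0
    missing_rate2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c for _, c in self.planted_pairs)
        if total > min(self.n1, self.n2):
            raise ValueError("planted pair count exceeds cohort size")
        for rate in (self.missing_rate1, self.missing_rate2):
            if not 0.0 <= rate < 1.0:
                raise ValueError("missing rate must lie in [0, 1)")


@dataclass
class TruthTable:
    """Planted-pair ground truth: indices, degree, realized IBD sharing."""

    pairs: pd.DataFrame  # columns IDX1, IDX2, DEGREE, REALIZED

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def simulate_relative_pair(
    founder_dosages: np.ndarray,
    r: int,
    p: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-drop an r-th-degree relative of each founder row.

    Returns (relative dosages, realized IBD-sharing fraction per row).
    r = 0 copies the founder.  Each meiosis step keeps an allele-level
    IBD indicator so the realized kinship (expected 2^-r) is reported
    exactly, not re-estimated.
    """
    if r < 0:
        raise ValueError("degree r must be >= 0")
    founders = np.atleast_2d(np.asarray(founder_dosages))
    n, m = founders.shape
    if r == 0:
        return founders.astype(np.int8).copy(), np.ones(n)
    # allele-level state of the current generation: (kept allele, fresh allele)
    # plus an IBD flag for each, relative to the founder.
    hets = founders == 1
    # split founder dosage into two alleles (order random for hets)
    first = np.where(founders == 2, 1, np.where(hets, rng.integers(0, 2, (n, m)), 0))
    second = founders - first
    alleles = np.stack([first, second])  # (2, n, m)
    ibd = np.ones((2, n, m), dtype=bool)
    for _ in range(r):
        choice = rng.integers(0, 2, (n, m))
        transmitted = np.where(choice == 0, alleles[0], alleles[1])
        transmitted_ibd = np.where(choice == 0, ibd[0], ibd[1])
        fresh = rng.binomial(1, p, (n, m))
        alleles = np.stack([transmitted, fresh])
        ibd = np.stack([transmitted_ibd, np.zeros((n, m), dtype=bool)])
    dosages = (alleles[0] + alleles[1]).astype(np.int8)
    # per-locus kinship contribution: half an allele pair shared IBD
    realized = 0.5 * (ibd[0] | ibd[1]).mean(axis=1)
    return dosages, realized


def _apply_missing(
    dosages: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate > 0.0:
        mask = rng.random(dosages.shape) < rate
        dosages = dosages.copy()
        dosages[mask] = MISSING
    return dosages


def _panel(p: np.ndarray) -> list[SnpMeta]:
    return [
        SnpMeta(snp_id=f"snp{j}", a1="A", a2="C", freq_a1=float(p[j]))
        for j in range(p.size)
    ]


def simulate_cohort_pair(
    spec: ScenarioSpec,
) -> tuple[GenotypeMatrix, GenotypeMatrix, TruthTable]:
    """Two cohorts with planted relatives, fully reproducible from the seed.

    Planted pairs occupy the leading indices of both cohorts, in the
    order the (degree, count) blocks are listed; all other individuals
    are independent founders.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.maf_law.draw(spec.m, rng)
    x1 = rng.binomial(2, p, (spec.n1, spec.m)).astype(np.int8)
    x2 = rng.binomial(2, p, (spec.n2, spec.m)).astype(np.int8)
    rows = []
    offset = 0
    for r, count in spec.planted_pairs:
        rel, realized = simulate_relative_pair(
            x1[offset : offset + count], r, p, rng
        )
        x2[offset : offset + count] = rel
        for t in range(count):
            rows.append(
                {
                    "IDX1": offset + t,
                    "IDX2": offset + t,
                    "DEGREE": r,
                    "REALIZED": realized[t],
                }
            )
        offset += count
    truth = TruthTable(
        pd.DataFrame(rows, columns=["IDX1", "IDX2", "DEGREE", "REALIZED"])
    )
    x1 = _apply_missing(x1, spec.missing_rate1, rng)
    x2 = _apply_missing(x2, spec.missing_rate2, rng)

    def build(prefix: str, x: np.ndarray) -> GenotypeMatrix:
        snps = []
        for j, meta in enumerate(_panel(p)):
            col = x[:, j]
            obs = col[col != MISSING]
            freq = float(obs.sum() / (2 * obs.size)) if obs.size else float("nan")
            callrate = float((col != MISSING).mean())
            snps.append(
                SnpMeta(meta.snp_id, meta.a1, meta.a2, freq, max(callrate, 1e-9))
            )
        ids = [f"{prefix}_{i}" for i in range(x.shape[0])]
        return GenotypeMatrix(ids, snps, x)

    return build("c1", x1), build("c2", x2), truth


# ---------------------------------------------------------------------------
# validation harnesses


def variance_validation(
    degrees: tuple[int, ...] = (0, 1, 2, 3),
    ms: tuple[int, ...] = (1000, 2000),
    ks: tuple[int, ...] = (4000, 8000),
    n_pairs: int = 1000,
    maf_law: MafLaw | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical vs theoretical sampling variance over the (estimator, r, m, k) grid.

    For each cell, ``n_pairs`` relative pairs are simulated, split across
    two cohorts, encrypted with a fresh shared S, and scored by all three
    estimators; the empirical variance of the per-pair scores is tabled
    against the Table-1 theory with m_e = m (independent markers).
    """
    maf_law = maf_law or MafLaw()
    rng = np.random.default_rng(seed)
    records = []
    for m in ms:
        p = maf_law.draw(m, rng)
        scale = np.sqrt(2.0 * p * (1.0 - p))
        for k in ks:
            s = rng.normal(0.0, np.sqrt(1.0 / m), (m, k))
            for r in degrees:
                theta = 0.5**r
                x1 = rng.binomial(2, p, (n_pairs, m))
                x2, _ = simulate_relative_pair(x1, r, p, rng)
                z1 = (x1 - 2 * p) / scale
                z2 = (x2 - 2 * p) / scale
                e1 = z1 @ s
                e2 = z2 @ s
                grm = np.einsum("ij,ij->i", z1, z2) / m
                encgrm = np.einsum("ij,ij->i", e1, e2) / k
                c1 = e1 - e1.mean(axis=1, keepdims=True)
                c2 = e2 - e2.mean(axis=1, keepdims=True)
                slope = np.einsum("ij,ij->i", c1, c2) / np.einsum("ij,ij->i", c1, c1)
                for name, scores in (
                    ("grm", grm),
                    ("encgrm", encgrm),
                    ("encg_reg", slope),
                ):
                    theo = core.theoretical_moments(name, theta, m, k).variance
                    records.append(
                        {
                            "estimator": name,
                            "r": r,
                            "m": m,
                            "k": k,
                            "mean": float(scores.mean()),
                            "empirical_var": float(scores.var(ddof=1)),
                            "theoretical_var": theo,
                        }
                    )
    return pd.DataFrame(records)


@dataclass
class PowerResult:
    """Outcome of the end-to-end operating-point experiment."""

    power: dict[int, float]  # degree -> fraction of planted pairs detected
    false_positives: int  # null pairs above threshold, totalled
    null_tests: int  # number of null pairs examined
    replicates: int
    design_table: pd.DataFrame


def power_experiment(
    alpha_exp: float = 0.05 / 40_000,
    beta: float = 0.1,
    degrees: tuple[int, ...] = (0, 1, 2),
    n1: int = 200,
    n2: int = 200,
    planted_per_degree: int = 10,
    replicates: int = 100,
    convention: design_mod.ThetaConvention | None = None,
    threshold_override: float | None = None,
    seed: int = 0,
) -> PowerResult:
    """Run the full design -> simulate -> encrypt -> encG-reg -> threshold loop.

    ``alpha_exp`` is the per-test (already Bonferroni-corrected) error
    rate, e.g. 0.05/40,000 for two cohorts of 200.  Each degree is
    designed separately: m = twice the m_e bound, k from the k bound at
    m_e = m.  Power is the fraction of planted pairs exceeding the
    threshold; false positives are tallied over all unrelated pairs.
    """
    convention = convention or design_mod.ThetaConvention()
    rng = np.random.default_rng(seed)
    n_comp = n1 * n2
    detected = {r: 0 for r in degrees}
    planted_total = {r: 0 for r in degrees}
    fp = 0
    nulls = 0
    design_rows = []
    for r in degrees:
        theta = convention.theta(r)
        me_bound = design_mod.min_me(alpha_exp, beta, theta)
        m = 2 * me_bound
        k = design_mod.min_k(alpha_exp, beta, theta, m)
        threshold = design_mod.z_quantile(1.0 - alpha_exp) * np.sqrt(1.0 / m + 1.0 / k)
        if threshold_override is not None:
            threshold = threshold_override
        design_rows.append(
            {"DEGREE": r, "THETA_EFF": theta, "MIN_ME": me_bound, "M": m, "K": k,
             "THRESHOLD": threshold}
        )
        for _ in range(replicates):
            sub_seed = int(rng.integers(0, 2**31))
            g1, g2, truth = simulate_cohort_pair(
                ScenarioSpec(
                    n1=n1,
                    n2=n2,
                    m=m,
                    planted_pairs=((r, planted_per_degree),),
                    seed=sub_seed,
                )
            )
            spec = encryption.ProjectionSpec(m=m, k=k, seed=sub_seed)
            s = encryption.generate_projection(spec)
            e1 = encryption.encrypt(
                core.standardize(g1), s, spec, "c1", g1.sample_ids, g1.snps
            )
            e2 = encryption.encrypt(
                core.standardize(g2), s, spec, "c2", g2.sample_ids, g2.snps
            )
            scores = core.encg_reg_cross(e1, e2).scores
            hits = scores > threshold
            planted = np.zeros((n1, n2), dtype=bool)
            planted[truth.pairs["IDX1"], truth.pairs["IDX2"]] = True
            detected[r] += int(hits[planted].sum())
            planted_total[r] += planted_per_degree
            fp += int(hits[~planted].sum())
            nulls += n_comp - planted_per_degree
    return PowerResult(
        power={
            r: (detected[r] / planted_total[r]) if planted_total[r] else 0.0
            for r in degrees
        },
        false_positives=fp,
        null_tests=nulls,
        replicates=replicates,
        design_table=pd.DataFrame(design_rows),
    )
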