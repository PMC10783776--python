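"""The four-step, two-interaction encG-reg protocol.

Cohort side (steps 1 and 3): intra-cohort QC + summary report; then
standardization on the centrally-issued SNP list, regeneration of S from
the shared seed, and encryption.  Central side (steps 2 and 4): panel
intersection and cohort-level QC; design of m_e, k and thresholds; the
pairwise encG-reg run; and the relatedness report with positive-control
verification.  No cohort-side artifact ever contains raw dosages or the
raw seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, design as design_mod, encryption, qc
from .io import (
    CohortSummary,
    EncryptedMatrix,
    GenotypeMatrix,
    MISSING,
    SnpMeta,
    write_summary,
)

logger = logging.getLogger("encgreg")

EXIT_QC_FAILURE = 3
EXIT_PROTOCOL_MISMATCH = 4
EXIT_CONTROL_FAILURE = 5

#: Intra-cohort QC gates (standard biobank defaults).
QC_GATES = {"maf_min": 0.01, "hwe_min": 1e-7, "miss_max": 0.05}


class QCFailure(RuntimeError):
    exit_code = EXIT_QC_FAILURE


class ControlFailure(RuntimeError):
    exit_code = EXIT_CONTROL_FAILURE


@dataclass
class RunConfig:
    """Flat key=value run configuration shared by the CLI subcommands."""

    role: str = "cohort"
    design: str = "parsimony"
    alpha: float = 0.05
    beta: float = 0.1
    degrees: tuple[int, ...] = (0, 1)
    deflation: float = 0.9
    seed: int | None = None
    paths: dict[str, str] = field(default_factory=dict)
    report_all_scores: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("cohort", "central"):
            raise ValueError("role must be 'cohort' or 'central'")
        if self.design not in ("parsimony", "exhaustive"):
            raise ValueError("design must be 'parsimony' or 'exhaustive'")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        kwargs: dict = {}
        if "role" in kv:
            kwargs["role"] = kv.pop("role")
        if "design" in kv:
            kwargs["design"] = kv.pop("design")
        if "alpha" in kv:
            kwargs["alpha"] = float(kv.pop("alpha"))
        if "beta" in kv:
            kwargs["beta"] = float(kv.pop("beta"))
        if "degrees" in kv:
            kwargs["degrees"] = tuple(int(x) for x in kv.pop("degrees").split(","))
        if "deflation" in kv:
            kwargs["deflation"] = float(kv.pop("deflation"))
        if "seed" in kv:
            kwargs["seed"] = int(kv.pop("seed"))
        if "report_all_scores" in kv:
            kwargs["report_all_scores"] = kv.pop("report_all_scores") in ("1", "true")
        return cls(paths=kv, **kwargs)


# ---------------------------------------------------------------------------
# cohort side


def hwe_pvalue(dosages: np.ndarray) -> float:
    """1-df chi-square Hardy-Weinberg test from one SNP's genotype counts."""
    from scipy.stats import chi2

    obs = dosages[dosages != MISSING]
    n = obs.size
    if n == 0:
        return 1.0
    counts = np.array([(obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()], float)
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    stat = float(((counts - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def intra_cohort_qc(
    g: GenotypeMatrix,
    maf_min: float = QC_GATES["maf_min"],
    hwe_min: float = QC_GATES["hwe_min"],
    miss_max: float = QC_GATES["miss_max"],
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the MAF / HWE / missingness gates; log every exclusion with a reason."""
    keep: list[str] = []
    excluded: list[dict] = []
    for j, s in enumerate(g.snps):
        col = g.dosages[:, j]
        obs = col[col != MISSING]
        reason = None
        if obs.size == 0:
            reason = "ALL_MISSING"
        else:
            freq = obs.sum() / (2 * obs.size)
            maf = min(freq, 1 - freq)
            missingness = 1.0 - obs.size / col.size
            if maf <= maf_min:
                reason = "MAF"
            elif missingness >= miss_max:
                reason = "MISSINGNESS"
            elif hwe_pvalue(col) <= hwe_min:
                reason = "HWE"
        if reason is None:
            keep.append(s.snp_id)
        else:
            excluded.append({"SNP": s.snp_id, "REASON": reason})
            logger.info("QC exclude %s: %s", s.snp_id, reason)
    if not keep:
        raise QCFailure("no SNPs survived intra-cohort QC")
    return g.subset_snps(keep), pd.DataFrame(excluded, columns=["SNP", "REASON"])


def cohort_summarize(
    g: GenotypeMatrix, cohort_id: str, gates: dict | None = None
) -> tuple[CohortSummary, pd.DataFrame]:
    """Step 1: intra-cohort QC, then the summary report to send central."""
    qced, exclusions = intra_cohort_qc(g, **(gates or {}))
    return write_summary(qced, cohort_id), exclusions


@dataclass
class Directive:
    """What the central analyst issues to each cohort before encryption."""

    snps: list[SnpMeta]  # ordered panel, central orientation
    k: int
    seed: int

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


def cohort_encrypt(
    g: GenotypeMatrix,
    directive: Directive,
    cohort_id: str,
    controls: GenotypeMatrix | None = None,
) -> EncryptedMatrix:
    """Step 3: standardize on the central SNP list and project with the shared S.

    Positive-control samples (``controls``) are appended after the
    summary stage, so they never inflate the cohort's frequency report;
    they are standardized and encrypted together with the cohort.
    Missing data is mean-imputed (zero after standardization) and each
    individual's call rate over the panel rides along for the
    missing-data score adjustment.
    """
    have = set(g.snp_ids)
    absent = [sid for sid in directive.snp_ids if sid not in have]
    if absent:
        raise QCFailure(
            f"cohort {cohort_id} lacks {len(absent)} directive SNPs "
            f"(e.g. {absent[:3]})"
        )
    sub = g.subset_snps(directive.snp_ids)
    sample_ids = list(sub.sample_ids)
    dosages = sub.dosages
    if controls is not None:
        ctrl = controls.subset_snps(directive.snp_ids)
        sample_ids = sample_ids + list(ctrl.sample_ids)
        dosages = np.vstack([dosages, ctrl.dosages])
    # orient dosages to the central allele convention
    flips = []
    for mine, central in zip(sub.snps, directive.snps):
        if (mine.a1, mine.a2) == (central.a1, central.a2):
            flips.append(False)
        elif (mine.a1, mine.a2) == (central.a2, central.a1):
            flips.append(True)
        else:
            raise QCFailure(f"allele mismatch at {mine.snp_id} in {cohort_id}")
    flips = np.array(flips)
    if flips.any():
        flipped = dosages.copy()
        cols = np.flatnonzero(flips)
        block = flipped[:, cols]
        block[block != MISSING] = 2 - block[block != MISSING]
        flipped[:, cols] = block
        dosages = flipped
    merged = GenotypeMatrix(sample_ids, directive.snps, dosages)
    # standardization basis: the cohort's OWN frequencies (only summaries
    # cross sites), oriented to the central allele convention
    freqs = np.array(
        [
            1.0 - mine.freq_a1 if flip else mine.freq_a1
            for mine, flip in zip(sub.snps, flips)
        ]
    )
    z = core.standardize(merged, freqs)
    spec = encryption.ProjectionSpec(m=len(directive.snps), k=directive.k,
                                     seed=directive.seed)
    s = encryption.generate_projection(spec)
    return encryption.encrypt(
        z, s, spec, cohort_id, sample_ids, directive.snps,
        callrates=merged.callrates(),
    )


# ---------------------------------------------------------------------------
# central side


def central_intersect(
    summaries: list[CohortSummary], design: str = "parsimony"
):
    """Step 2 (first half): aligned panel(s) plus fPCA of the frequency matrix."""
    panel = qc.align_snps(summaries, design=design)
    if design == "parsimony":
        f = qc.freq_matrix(summaries, panel)
        scores, explained = qc.fpca(f)
        fpca_report = pd.DataFrame(
            {
                "COHORT": f.cohort_ids,
                "PC1": scores[:, 0],
                "PC2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
            }
        )
        return panel, fpca_report, explained
    return panel, None, None


def central_design(
    panel: qc.AlignedPanel,
    sizes: list[int],
    degrees: tuple[int, ...],
    alpha: float = 0.05,
    beta: float = 0.1,
    empirical_me: dict[int, float] | None = None,
    deflation: float = 0.9,
    seed: int = 0,
    m_budget: int | None = None,
) -> tuple[design_mod.DesignParams, Directive]:
    """Step 2 (second half): per-degree design and the SNP-list + seed directive.

    The directive carries ``m_budget`` panel SNPs (default: the practical
    budget of the deepest degree, capped by the panel size) and the k of
    the shallowest-theta degree requirement (the largest k designed).
    """
    convention = design_mod.ThetaConvention(deflation)
    if empirical_me is None:
        empirical_me = {}
    params = design_mod.build_design(
        alpha, beta, sizes, list(degrees), empirical_me or None, convention
    )
    need = m_budget or max(d.me_practical for d in params.degrees)
    if len(panel.snps) < need:
        raise QCFailure(
            f"panel has {len(panel.snps)} SNPs but the design needs {need}"
        )
    k = max(d.k_min for d in params.degrees)
    return params, Directive(snps=panel.snps[:need], k=k, seed=seed)


def central_run(
    encrypted: list[EncryptedMatrix],
) -> dict[tuple[str, str], core.ScoreMatrix]:
    """Step 4 (first half): pairwise encG-reg over every cohort pair."""
    results = {}
    for a in range(len(encrypted)):
        for b in range(a + 1, len(encrypted)):
            e1, e2 = encrypted[a], encrypted[b]
            results[(e1.cohort_id, e2.cohort_id)] = core.encg_reg_cross(e1, e2)
    return results


def central_report(
    encrypted: list[EncryptedMatrix],
    scores: dict[tuple[str, str], core.ScoreMatrix],
    params: design_mod.DesignParams,
    control_ids: list[str] | None = None,
    report_all: bool = False,
) -> pd.DataFrame:
    """Step 4 (second half): thresholded relatedness report + control checks.

    By default only pairs above the deepest-degree threshold appear
    (privacy-preserving mode); ``report_all`` emits every score.  When
    ``control_ids`` is given, every cross-cohort pairing of the shared
    positive controls must be called identical, else the run fails.
    """
    by_id = {e.cohort_id: e for e in encrypted}
    deepest = max(params.degrees, key=lambda d: d.r)
    frames = []
    for (ca, cb), sm in scores.items():
        e1, e2 = by_id[ca], by_id[cb]
        if e1.callrates is not None and e2.callrates is not None:
            joint = core.joint_nonmissing_fraction(e1.callrates, e2.callrates)
        else:
            joint = np.ones(sm.scores.shape)
        adj = sm.scores / joint
        if report_all:
            pairs = [(i, j) for i in range(e1.n) for j in range(e2.n)]
        else:
            pairs = [tuple(x) for x in np.argwhere(adj > deepest.threshold)]
        labels = np.empty(sm.scores.shape, dtype=object)
        for i, j in pairs:
            labels[i, j] = design_mod.classify_degree(float(adj[i, j]), params)
        frames.append(
            core.relatedness_report(
                sm, ca, e1.sample_ids, cb, e2.sample_ids,
                joint_fraction=joint, degree_labels=labels, pairs=pairs,
            )
        )
    frames = [f for f in frames if not f.empty]
    report = (
        pd.concat(frames, ignore_index=True)
        if frames
        else core.relatedness_report(None, "", [], "", [], pairs=[])
    )
    if control_ids:
        failed = _verify_controls(report, encrypted, control_ids)
        if failed:
            raise ControlFailure(
                f"positive controls not recovered as identical: {failed[:5]}"
            )
    return report


def _verify_controls(
    report: pd.DataFrame, encrypted: list[EncryptedMatrix], control_ids: list[str]
) -> list[str]:
    failed = []
    present = {
        e.cohort_id: set(e.sample_ids) & set(control_ids) for e in encrypted
    }
    for a in range(len(encrypted)):
        for b in range(a + 1, len(encrypted)):
            ca, cb = encrypted[a].cohort_id, encrypted[b].cohort_id
            for cid in present[ca] & present[cb]:
                hit = report[
                    (report.COHORT1 == ca)
                    & (report.COHORT2 == cb)
                    & (report.ID1 == cid)
                    & (report.ID2 == cid)
                    & (report.DEGREE == "identical")
                ]
                if hit.empty:
                    failed.append(f"{cid} ({ca} vs {cb})")
    return failed
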