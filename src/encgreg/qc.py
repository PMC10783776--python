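"""Summary-statistics-only inter-cohort QC.

Nothing in this module touches individual-level data from other sites:
SNP panels are intersected and aligned from per-cohort summary reports,
population structure is screened with frequency-PCA (fPCA) and
Fst-derived composition bars (fStructure), and frequency concordance
flags orientation mistakes.  Ethnicity-insensitive SNP selection is the
one step that uses reference-panel genotypes, which are public.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import CohortSummary, GenotypeMatrix, MISSING, SnpMeta

#: Strand-ambiguous allele pairs (indistinguishable under strand flips).
AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))


@dataclass
class AlignedPanel:
    """A shared SNP panel with per-cohort allele orientation resolved.

    ``orientation[cohort_id][snp_id]`` is ``+1`` (keep) or ``-1`` (swap:
    the cohort's A1 is the panel's A2, so its frequency becomes 1 - p).
    """

    snps: list[SnpMeta]  # panel orientation: A1/A2 of the first cohort
    cohort_ids: list[str]
    orientation: dict[str, dict[str, int]]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (snp, reason)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def oriented_freq(self, summary: CohortSummary) -> np.ndarray:
        """Panel-oriented A1 frequencies of one cohort, in panel SNP order."""
        by_id = {r.snp_id: r for r in summary.records}
        flips = self.orientation[summary.cohort_id]
        out = np.empty(len(self.snps))
        for j, s in enumerate(self.snps):
            rec = by_id[s.snp_id]
            out[j] = rec.freq_a1 if flips[s.snp_id] == +1 else 1.0 - rec.freq_a1
        return out


@dataclass
class FreqMatrix:
    """Cohorts x SNPs allele-frequency matrix on an aligned panel."""

    cohort_ids: list[str]
    snp_ids: list[str]
    p: np.ndarray  # (C, M)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (len(self.cohort_ids), len(self.snp_ids)):
            raise ValueError("frequency matrix shape mismatch")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("frequencies outside [0, 1]")


def _is_ambiguous(a1: str, a2: str) -> bool:
    return frozenset({a1.upper(), a2.upper()}) in AMBIGUOUS_PAIRS


def align_snps(
    summaries: list[CohortSummary],
    design: str = "parsimony",
    drop_ambiguous: bool = True,
):
    """Intersect and allele-align SNP panels across cohort summaries.

    ``parsimony`` returns one :class:`AlignedPanel` shared by all cohorts;
    ``exhaustive`` returns a dict keyed by cohort-id pairs, one panel per
    pair.  Matching is by SNP ID; orientation is resolved by comparing
    allele pairs (swapped pair means p := 1 - p on the cohort side);
    strand-ambiguous (A/T, C/G) SNPs and allele-pair mismatches are
    dropped with a reason.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two cohort summaries")
    if design == "parsimony":
        return _align_group(summaries, drop_ambiguous)
    if design == "exhaustive":
        return {
            (a.cohort_id, b.cohort_id): _align_group([a, b], drop_ambiguous)
            for a, b in itertools.combinations(summaries, 2)
        }
    raise ValueError(f"unknown design {design!r}")


def _align_group(summaries: list[CohortSummary], drop_ambiguous: bool) -> AlignedPanel:
    maps = [{r.snp_id: r for r in s.records} for s in summaries]
    shared = set(maps[0])
    for m in maps[1:]:
        shared &= set(m)
    if not shared:
        raise ValueError("empty SNP intersection across cohorts")
    ref = summaries[0]
    order = [r.snp_id for r in ref.records if r.snp_id in shared]
    panel: list[SnpMeta] = []
    dropped: list[tuple[str, str]] = []
    orientation: dict[str, dict[str, int]] = {s.cohort_id: {} for s in summaries}
    for sid in order:
        base = maps[0][sid]
        if drop_ambiguous and _is_ambiguous(base.a1, base.a2):
            dropped.append((sid, "strand-ambiguous"))
            continue
        flips = {}
        ok = True
        for summary, m in zip(summaries, maps):
            rec = m[sid]
            if (rec.a1, rec.a2) == (base.a1, base.a2):
                flips[summary.cohort_id] = +1
            elif (rec.a1, rec.a2) == (base.a2, base.a1):
                flips[summary.cohort_id] = -1
            else:
                dropped.append((sid, f"allele mismatch in {summary.cohort_id}"))
                ok = False
                break
        if not ok:
            continue
        panel.append(base)
        for cid, f in flips.items():
            orientation[cid][sid] = f
    if not panel:
        raise ValueError("no SNPs survived alignment")
    return AlignedPanel(
        snps=panel,
        cohort_ids=[s.cohort_id for s in summaries],
        orientation=orientation,
        dropped=dropped,
    )


def freq_matrix(summaries: list[CohortSummary], panel: AlignedPanel) -> FreqMatrix:
    p = np.vstack([panel.oriented_freq(s) for s in summaries])
    return FreqMatrix(
        cohort_ids=[s.cohort_id for s in summaries],
        snp_ids=panel.snp_ids,
        p=p,
    )


def fpca(f: FreqMatrix, n_components: int = 2):
    """Frequency-PCA: SVD of the column-centered cohorts x SNPs matrix.

    Frequencies are commensurate across SNPs, so columns are mean-centered
    but not rescaled.  Returns (scores C x n_components, explained-variance
    fractions).  A rank-0 matrix (all cohorts identical) yields all-zero
    scores.
    """
    c, m = f.p.shape
    if c < 2 or m < 2:
        raise ValueError("fPCA needs >= 2 cohorts and >= 2 SNPs")
    centered = f.p - f.p.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    n_components = min(n_components, len(s))
    total = float((s**2).sum())
    if total == 0.0:
        return np.zeros((c, n_components)), np.zeros(n_components)
    scores = u[:, :n_components] * s[:n_components]
    explained = (s[:n_components] ** 2) / total
    return scores, explained


def fst(
    p_a: np.ndarray,
    p_b: np.ndarray,
    n_a: float,
    n_b: float,
    corrected: bool = True,
) -> float:
    """Multi-SNP Hudson Fst between two populations (ratio of averages).

    Per SNP the numerator is (p_a - p_b)^2 minus the within-population
    sampling corrections p(1-p)/(n-1), and the denominator is
    p_a(1-p_b) + p_b(1-p_a); the multi-SNP estimate is the ratio of the
    summed numerators to the summed denominators, truncated at 0.
    Setting ``corrected=False`` drops the sample-size terms (Nei-style,
    for cross-checks).
    """
    p_a = np.atleast_1d(np.asarray(p_a, dtype=np.float64))
    p_b = np.atleast_1d(np.asarray(p_b, dtype=np.float64))
    if p_a.shape != p_b.shape:
        raise ValueError("frequency vectors differ in length")
    if np.any((p_a < 0) | (p_a > 1) | (p_b < 0) | (p_b > 1)):
        raise ValueError("frequencies outside [0, 1]")
    num = (p_a - p_b) ** 2
    if corrected:
        if n_a <= 1 or n_b <= 1:
            raise ValueError("sample sizes must exceed 1 with correction enabled")
        num = num - p_a * (1 - p_a) / (n_a - 1) - p_b * (1 - p_b) / (n_b - 1)
    den = p_a * (1 - p_b) + p_b * (1 - p_a)
    total_den = float(den.sum())
    if total_den == 0.0:
        return 0.0
    return max(float(num.sum()) / total_den, 0.0)


def fstructure(
    f: FreqMatrix,
    refs: list[CohortSummary],
    ref_freqs: np.ndarray | None = None,
    ref_sizes: list[float] | None = None,
    cohort_sizes: list[float] | None = None,
    eps: float = 1e-4,
) -> pd.DataFrame:
    """Per-cohort composition proportions over reference populations.

    For each cohort the mean Hudson Fst to each reference is computed on
    the shared panel, floored at ``eps``, inverted, and normalized to sum
    to one.  ``ref_freqs`` (R x M, panel-oriented) may be supplied
    directly; otherwise reference frequencies are matched by SNP ID from
    the reference summaries (assumed panel-oriented).
    """
    if len(refs) < 2:
        raise ValueError("need at least two reference populations")
    r_names = [r.cohort_id for r in refs]
    if ref_freqs is None:
        cols = {sid: j for j, sid in enumerate(f.snp_ids)}
        ref_freqs = np.empty((len(refs), len(f.snp_ids)))
        for i, ref in enumerate(refs):
            by_id = {rec.snp_id: rec.freq_a1 for rec in ref.records}
            absent = [sid for sid in f.snp_ids if sid not in by_id]
            if len(absent) == len(f.snp_ids):
                raise ValueError(f"cohorts share no SNPs with reference {ref.cohort_id}")
            for sid, j in cols.items():
                ref_freqs[i, j] = by_id.get(sid, np.nan)
    ref_sizes = ref_sizes or [r.n for r in refs]
    rows = []
    for c, cid in enumerate(f.cohort_ids):
        n_c = cohort_sizes[c] if cohort_sizes is not None else 10**9
        inv = np.empty(len(refs))
        for i in range(len(refs)):
            keep = ~np.isnan(ref_freqs[i])
            if not keep.any():
                raise ValueError(f"cohort {cid} shares no SNPs with {r_names[i]}")
            d = fst(f.p[c, keep], ref_freqs[i, keep], n_c, ref_sizes[i])
            inv[i] = 1.0 / max(d, eps)
        rows.append(dict(zip(r_names, inv / inv.sum()), COHORT=cid))
    return pd.DataFrame(rows, columns=["COHORT", *r_names])


def allele_count_test(
    dosages_a: np.ndarray, dosages_b: np.ndarray
) -> float:
    """Chi-square p-value comparing allele counts of one SNP in two panels.

    The 2 x 2 table is (A1 count, A2 count) per panel over non-missing
    calls; the statistic is the uncorrected 1-df Pearson chi-square.
    Identical frequencies give statistic 0, p = 1.
    """
    counts = []
    for d in (dosages_a, dosages_b):
        obs = d[d != MISSING]
        a1 = int(obs.sum())
        counts.append((a1, int(2 * obs.size - a1)))
    table = np.array(counts, dtype=np.float64)
    total = table.sum()
    if total == 0 or np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def ethnicity_insensitive_snps(
    ref_panels: list[GenotypeMatrix], p_threshold: float = 0.05
) -> list[str]:
    """SNPs whose allele frequencies are indistinguishable across ancestries.

    For every pair of reference panels each shared SNP is tested with an
    allele-count chi-square; only SNPs insignificant (p > threshold) in
    every pair are kept.  Panels are expected to be QCed beforehand
    (MAF > 0.01, HWE p > 1e-7, missingness < 0.05).  An empty result is
    returned as-is (flagged by the caller, not fatal).
    """
    if len(ref_panels) < 2:
        raise ValueError("need at least two reference panels")
    shared = set(ref_panels[0].snp_ids)
    for g in ref_panels[1:]:
        shared &= set(g.snp_ids)
    order = [sid for sid in ref_panels[0].snp_ids if sid in shared]
    col_index = [{sid: j for j, sid in enumerate(g.snp_ids)} for g in ref_panels]
    keep: list[str] = []
    for sid in order:
        ok = True
        for (ia, ga), (ib, gb) in itertools.combinations(enumerate(ref_panels), 2):
            p = allele_count_test(
                ga.dosages[:, col_index[ia][sid]], gb.dosages[:, col_index[ib][sid]]
            )
            if p <= p_threshold:
                ok = False
                break
        if ok:
            keep.append(sid)
    return keep


def freq_concordance(
    summary_a: CohortSummary,
    summary_b: CohortSummary,
    panel: AlignedPanel | None = None,
    flag_cut: float = 0.2,
) -> pd.DataFrame:
    """Aligned per-SNP frequency deltas between two cohorts, outliers flagged.

    A frequency reported in the wrong orientation shows up as a large
    |delta| (p vs 1-p); the default cut of 0.2 flags those while passing
    binomial sampling noise at realistic sample sizes.
    """
    if panel is None:
        panel = align_snps([summary_a, summary_b], design="parsimony")
    pa = panel.oriented_freq(summary_a)
    pb = panel.oriented_freq(summary_b)
    delta = pb - pa
    return pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "FREQ_A": pa,
            "FREQ_B": pb,
            "DELTA": delta,
            "FLAGGED": np.abs(delta) > flag_cut,
        }
    )
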