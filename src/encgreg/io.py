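"""Reading and writing the artifacts exchanged in the encG-reg protocol.

Four kinds of files cross site boundaries: per-cohort genotype matrices
(VCF or a plain dosage TSV), per-cohort SNP summary reports, encrypted
n-by-k matrices, and relatedness reports.  Dosages are counts of the A1
allele; for VCF input A1 is the ALT allele by default.  Missing genotypes
use a single internal sentinel regardless of source format.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("encgreg")

#: Internal missing-genotype sentinel (int8-compatible).
MISSING: int = -1

SUMMARY_COLUMNS = ["SNP", "A1", "A2", "FREQ_A1", "CALLRATE", "N"]


class FormatError(ValueError):
    """A file does not parse under the named standard."""


@dataclass(frozen=True)
class SnpMeta:
    """Per-SNP summary record: identity, allele pair, A1 frequency, call rate."""

    snp_id: str
    a1: str
    a2: str
    freq_a1: float
    callrate: float = 1.0

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: A1 and A2 must differ")
        if not 0.0 <= self.freq_a1 <= 1.0:
            raise ValueError(f"{self.snp_id}: freq_a1 {self.freq_a1} outside [0,1]")
        if not 0.0 < self.callrate <= 1.0:
            raise ValueError(f"{self.snp_id}: callrate {self.callrate} outside (0,1]")


@dataclass
class GenotypeMatrix:
    """n individuals by m biallelic SNPs, dosages in {0,1,2} with MISSING."""

    sample_ids: list[str]
    snps: list[SnpMeta]
    dosages: np.ndarray  # int8, shape (n, m)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.snps) != m:
            raise ValueError("snps length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("duplicate SNP IDs")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,missing}")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def callrates(self) -> np.ndarray:
        """Per-individual non-missing fraction over this matrix's SNP list."""
        return 1.0 - self.missing_mask().mean(axis=1)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        index = {s.snp_id: j for j, s in enumerate(self.snps)}
        cols = [index[i] for i in snp_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[j] for j in cols],
            dosages=self.dosages[:, cols],
        )


@dataclass
class CohortSummary:
    """Per-cohort SNP report exchanged in the first protocol interaction."""

    cohort_id: str
    n: int
    records: list[SnpMeta]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort sample count must be >= 1")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP IDs in summary")

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": [r.snp_id for r in self.records],
                "A1": [r.a1 for r in self.records],
                "A2": [r.a2 for r in self.records],
                "FREQ_A1": [r.freq_a1 for r in self.records],
                "CALLRATE": [r.callrate for r in self.records],
                "N": self.n,
            },
            columns=SUMMARY_COLUMNS,
        )


@dataclass
class EncryptedMatrix:
    """n-by-k projected genotype matrix plus the provenance needed to pair it.

    ``seed_fingerprint`` is a hash of the shared seed, never the seed itself;
    ``snp_list_hash`` pins the ordered SNP list (with alleles) used before
    projection so the central side can refuse mismatched encryptions.
    ``callrates`` carries each individual's non-missing fraction over the
    shared SNP list, used for the missing-data score adjustment.
    """

    cohort_id: str
    sample_ids: list[str]
    values: np.ndarray  # float64, shape (n, k)
    m_used: int
    k: int
    seed_fingerprint: str
    snp_list_hash: str
    callrates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.k:
            raise ValueError("value column count does not match k")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match row count")
        if self.m_used < 1:
            raise ValueError("m_used must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("encrypted values must be finite")
        if self.callrates is not None:
            self.callrates = np.asarray(self.callrates, dtype=np.float64)
            if self.callrates.shape != (self.values.shape[0],):
                raise ValueError("callrates length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def snp_list_hash(snps: list[SnpMeta]) -> str:
    """SHA-256 over the ordered (id, A1, A2) triples of a SNP panel."""
    h = hashlib.sha256()
    for s in snps:
        h.update(f"{s.snp_id}\t{s.a1}\t{s.a2}\n".encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# genotype input


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage-TSV file.

    Only biallelic SNP records are accepted; multiallelic or malformed
    records raise :class:`FormatError` naming the offending record.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise FormatError(f"unknown genotype format {format!r}")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    for idx, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise FormatError(
                f"record {idx} ({variant.ID or variant.POS}): not biallelic"
            )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(3 in cyvcf2), 2=unknown
        gts = variant.gt_types
        dos = np.full(len(sample_ids), MISSING, dtype=np.int8)
        dos[gts == 0] = 0
        dos[gts == 1] = 1
        dos[gts == 3] = 2
        columns.append(dos)
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # A1 = ALT: dosage counts the alternate allele
        snps.append(
            SnpMeta(
                snp_id=snp_id,
                a1=variant.ALT[0],
                a2=variant.REF,
                freq_a1=_freq(dos),
                callrate=float((dos != MISSING).mean()),
            )
        )
    if not snps:
        raise FormatError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(sample_ids, snps, np.column_stack(columns))


def _read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty dosage table")
    values = df.to_numpy()
    dosages = np.full(values.shape, MISSING, dtype=np.int8)
    for code in ("0", "1", "2"):
        dosages[values == code] = int(code)
    known = np.isin(values, ("0", "1", "2", "NA")) | pd.isna(values)
    if not known.all():
        i, j = np.argwhere(~known)[0]
        raise FormatError(
            f"{path}: line {i + 2}: cell {values[i, j]!r} not in {{0,1,2,NA}}"
        )
    snps = [
        SnpMeta(
            snp_id=str(c).split("_")[0],
            a1=str(c).split("_")[1] if "_" in str(c) else "A",
            a2=str(c).split("_")[2] if str(c).count("_") >= 2 else "B",
            freq_a1=_freq(dosages[:, j]),
            callrate=float((dosages[:, j] != MISSING).mean()),
        )
        for j, c in enumerate(df.columns)
    ]
    return GenotypeMatrix([str(s) for s in df.index], snps, dosages)


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage-TSV dialect: SNP-ID header, one row per sample, NA missing.

    Column names encode the allele pair as ``id_A1_A2`` so a round trip
    preserves SNP identity.
    """
    cols = [f"{s.snp_id}_{s.a1}_{s.a2}" for s in g.snps]
    values = g.dosages.astype(object)
    values[g.dosages == MISSING] = "NA"
    pd.DataFrame(values, index=g.sample_ids, columns=cols).to_csv(path, sep="\t")


def _freq(column: np.ndarray) -> float:
    obs = column[column != MISSING]
    if obs.size == 0:
        return float("nan")
    return float(obs.sum() / (2 * obs.size))


# ---------------------------------------------------------------------------
# summary reports


def write_summary(
    g: GenotypeMatrix, cohort_id: str, path: str | Path | None = None
) -> CohortSummary:
    """Build (and optionally serialize) the per-SNP summary report of a cohort.

    Frequencies are computed over non-missing calls only; a column whose
    calls are all missing is excluded from the report and logged.
    """
    if g.n == 0 or g.m == 0:
        raise ValueError("genotype matrix is empty")
    records: list[SnpMeta] = []
    for j, s in enumerate(g.snps):
        col = g.dosages[:, j]
        callrate = float((col != MISSING).mean())
        if callrate == 0.0:
            logger.warning("summary %s: SNP %s all-missing, excluded", cohort_id, s.snp_id)
            continue
        records.append(SnpMeta(s.snp_id, s.a1, s.a2, _freq(col), callrate))
    summary = CohortSummary(cohort_id=cohort_id, n=g.n, records=records)
    if path is not None:
        summary.to_frame().to_csv(path, sep="\t", index=False)
    return summary


def read_summary(path: str | Path, cohort_id: str | None = None) -> CohortSummary:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    missing_cols = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing summary columns {missing_cols}")
    records = [
        SnpMeta(r.SNP, r.A1, r.A2, float(r.FREQ_A1), float(r.CALLRATE))
        for r in df.itertuples()
    ]
    n = int(df["N"].iloc[0])
    return CohortSummary(cohort_id or str(Path(path).stem), n, records)


# ---------------------------------------------------------------------------
# encrypted matrices

_HEADER_KEYS = ("cohort_id", "n", "k", "m_used", "seed_fingerprint", "snp_list_hash")


def write_encrypted(e: EncryptedMatrix, path: str | Path) -> None:
    """Serialize an encrypted matrix as TSV with a '#' key=value header block.

    Values are written with 17 significant digits so the round trip is
    bit-faithful at double precision.
    """
    with open(path, "w") as fh:
        fh.write(f"#cohort_id={e.cohort_id}\n")
        fh.write(f"#n={e.n}\n")
        fh.write(f"#k={e.k}\n")
        fh.write(f"#m_used={e.m_used}\n")
        fh.write(f"#seed_fingerprint={e.seed_fingerprint}\n")
        fh.write(f"#snp_list_hash={e.snp_list_hash}\n")
        cols = "\t".join(f"V{j + 1}" for j in range(e.k))
        has_cr = e.callrates is not None
        fh.write("ID\t" + ("CALLRATE\t" if has_cr else "") + cols + "\n")
        for i, sid in enumerate(e.sample_ids):
            row = "\t".join(f"{v:.17g}" for v in e.values[i])
            cr = f"{e.callrates[i]:.17g}\t" if has_cr else ""
            fh.write(f"{sid}\t{cr}{row}\n")


def read_encrypted(path: str | Path) -> EncryptedMatrix:
    header: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            header[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        body = pd.read_csv(
            fh, sep="\t", dtype={"ID": str}, float_precision="round_trip"
        )
    absent = [kk for kk in _HEADER_KEYS if kk not in header]
    if absent:
        raise FormatError(f"{path}: missing header keys {absent}")
    k = int(header["k"])
    has_cr = "CALLRATE" in body.columns
    value_cols = [c for c in body.columns if c not in ("ID", "CALLRATE")]
    if len(value_cols) != k:
        raise FormatError(
            f"{path}: header k={k} but {len(value_cols)} value columns"
        )
    if len(body) != int(header["n"]):
        raise FormatError(f"{path}: header n={header['n']} but {len(body)} rows")
    return EncryptedMatrix(
        cohort_id=header["cohort_id"],
        sample_ids=body["ID"].tolist(),
        values=body[value_cols].to_numpy(dtype=np.float64),
        m_used=int(header["m_used"]),
        k=k,
        seed_fingerprint=header["seed_fingerprint"],
        snp_list_hash=header["snp_list_hash"],
        callrates=body["CALLRATE"].to_numpy(dtype=np.float64) if has_cr else None,
    )
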