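import numpy as np
import pytest

from encgreg.io import GenotypeMatrix, SnpMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20240111)


@pytest.fixture
def tiny_vcf(tmp_path):
    """Two samples, three biallelic SNPs plus one missing call."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n"
        "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t1/1\n"
        "1\t300\trs3\tG\tC\t.\t.\t.\tGT\t1/1\t./.\n"
    )
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


def make_genotypes(dosages, prefix="s", freqs=None):
    """GenotypeMatrix from a dosage array, with plausible metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    snps = []
    for j in range(m):
        col = dosages[:, j]
        obs = col[col != -1]
        if freqs is not None:
            f = freqs[j]
        else:
            f = float(obs.sum() / (2 * obs.size)) if obs.size else 0.5
        snps.append(
            SnpMeta(f"snp{j}", "A", "C", f, float((col != -1).mean()) or 1.0)
        )
    return GenotypeMatrix([f"{prefix}{i}" for i in range(n)], snps, dosages)


@pytest.fixture
def make_g():
    return make_genotypes
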