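"""Deterministic generation of the shared random projection S and encryption.

Each cohort regenerates the identical m-by-k Gaussian matrix S from a
shared seed, multiplies its standardized genotype matrix by S, and ships
only the n-by-k product.  The raw seed never appears in any artifact:
files carry a cryptographic fingerprint of it instead.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .core import StandardizedMatrix
from .io import EncryptedMatrix, SnpMeta, snp_list_hash

#: The single pinned generator; independently-run cohorts must agree on it.
GENERATOR_ID = "pcg64-rowmajor"


@dataclass(frozen=True)
class ProjectionSpec:
    """Everything needed to regenerate S: dimensions, seed, entry variance.

    ``sigma2`` defaults to 1/m (the convention under which encGRM carries
    a 1/k prefactor); the regression slope is invariant to this choice.
    """

    m: int
    k: int
    seed: int
    sigma2: float | None = None
    generator_id: str = GENERATOR_ID

    def __post_init__(self) -> None:
        if self.m < 1 or self.k < 1:
            raise ValueError("m and k must be >= 1")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0 <= self.seed < 2**64:
            raise ValueError("seed must be a 64-bit unsigned integer")

    @property
    def entry_variance(self) -> float:
        return self.sigma2 if self.sigma2 is not None else 1.0 / self.m


def seed_fingerprint(seed: int) -> str:
    """SHA-256 fingerprint of a shared seed; safe to publish in artifacts."""
    return hashlib.sha256(f"encgreg-seed:{seed}".encode()).hexdigest()


def generate_projection(spec: ProjectionSpec) -> np.ndarray:
    """Regenerate the m-by-k matrix S, bit-identical for identical specs.

    The PCG64 stream is filled in row-major order; entries are iid
    N(0, sigma2).
    """
    if spec.generator_id != GENERATOR_ID:
        raise ValueError(f"unsupported generator_id {spec.generator_id!r}")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    s = rng.standard_normal((spec.m, spec.k))  # C-order fill
    s *= np.sqrt(spec.entry_variance)
    return s


def encrypt(
    z: StandardizedMatrix,
    s: np.ndarray,
    spec: ProjectionSpec,
    cohort_id: str,
    sample_ids: list[str],
    snps: list[SnpMeta],
    callrates: np.ndarray | None = None,
) -> EncryptedMatrix:
    """Project standardized genotypes: values = Z S, with provenance metadata."""
    if z.values.shape[1] != s.shape[0]:
        raise ValueError(
            f"marker count {z.values.shape[1]} does not match S rows {s.shape[0]}"
        )
    if len(snps) != z.m:
        raise ValueError("snps length does not match standardized marker count")
    return EncryptedMatrix(
        cohort_id=cohort_id,
        sample_ids=list(sample_ids),
        values=z.values @ s,
        m_used=z.m,
        k=s.shape[1],
        seed_fingerprint=seed_fingerprint(spec.seed),
        snp_list_hash=snp_list_hash(snps),
        callrates=callrates,
    )


def pairwise_specs(
    cohort_ids: list[str], m_by_pair: dict[tuple[str, str], int], k: int, base_seed: int
) -> dict[tuple[str, str], ProjectionSpec]:
    """Exhaustive design: one ProjectionSpec per cohort pair (C(C-1)/2 of them).

    Pair seeds are derived from the base seed by hashing the ordered pair
    label, so no two pairs share a projection.
    """
    specs: dict[tuple[str, str], ProjectionSpec] = {}
    for a in range(len(cohort_ids)):
        for b in range(a + 1, len(cohort_ids)):
            pair = (cohort_ids[a], cohort_ids[b])
            digest = hashlib.sha256(
                f"{base_seed}:{pair[0]}|{pair[1]}".encode()
            ).digest()
            pair_seed = int.from_bytes(digest[:8], "big")
            specs[pair] = ProjectionSpec(m=m_by_pair[pair], k=k, seed=pair_seed)
    return specs
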