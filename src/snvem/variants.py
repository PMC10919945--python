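"""Candidate SNVs: loci whose decided genotype differs from homozygous reference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from snvem.genotypes import (
    BASE_INDEX,
    GENOTYPE_ALLELES,
    HOM_REF_CLASS,
    IS_HET,
    genotype_label,
)


@dataclass
class CandidateVariant:
    """One SNV candidate with the four filter features attached.

    ``decided`` is the canonical genotype-class index; by construction it is
    never the homozygous-reference class of ``ref_base``. ``alt_fraction``
    is the fraction of retained observations whose base differs from the
    reference (0 when depth is 0).
    """

    contig: str
    pos: int  # 0-based
    ref_base: str
    decided: int
    depth: int
    alt_fraction: float
    entropy_bits: float
    posterior: np.ndarray  # 10-vector

    def __post_init__(self) -> None:
        if self.decided == HOM_REF_CLASS[BASE_INDEX[self.ref_base]]:
            raise ValueError("candidate genotype equals homozygous reference")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError(f"alt_fraction out of range: {self.alt_fraction}")

    @property
    def is_het(self) -> bool:
        return IS_HET[self.decided]

    @property
    def genotype(self) -> str:
        return genotype_label(self.decided)

    def alt_bases(self) -> list[str]:
        """Non-reference alleles of the decided genotype, in canonical
        allele order (deduplicated for homozygous alternates)."""
        ref_idx = BASE_INDEX[self.ref_base]
        alts: list[str] = []
        for a in GENOTYPE_ALLELES[self.decided]:
            if a != ref_idx and "ACGT"[a] not in alts:
                alts.append("ACGT"[a])
        return alts
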