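"""Diploid genotype classes over {A,C,G,T} and nucleotide encodings.

The ten unordered diploid genotypes are kept in a fixed canonical order
(homozygotes first, then heterozygotes lexicographically); every array in
the package indexed "by class" uses this order.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

GENOTYPES = ("AA", "CC", "GG", "TT", "AC", "AG", "AT", "CG", "CT", "GT")
N_CLASSES = len(GENOTYPES)

GENOTYPE_INDEX = {g: k for k, g in enumerate(GENOTYPES)}

#: allele pair of each class as base indices, e.g. class "AC" -> (0, 1)
GENOTYPE_ALLELES = tuple((BASE_INDEX[g[0]], BASE_INDEX[g[1]]) for g in GENOTYPES)

#: class index of the homozygous-reference genotype for ref base r (A,C,G,T)
HOM_REF_CLASS = (
    GENOTYPE_INDEX["AA"],
    GENOTYPE_INDEX["CC"],
    GENOTYPE_INDEX["GG"],
    GENOTYPE_INDEX["TT"],
)

IS_HET = tuple(a != b for a, b in GENOTYPE_ALLELES)

# ALLELE_FRACTION[k, b]: fraction of the two alleles of class k equal to base b
# (1.0 / 0.5 / 0.0); the error-free emission profile of a learner.
ALLELE_FRACTION = np.zeros((N_CLASSES, 4))
for _k, (_a, _b) in enumerate(GENOTYPE_ALLELES):
    ALLELE_FRACTION[_k, _a] += 0.5
    ALLELE_FRACTION[_k, _b] += 0.5

_SORTED_INDEX = {"".join(sorted(g)): k for k, g in enumerate(GENOTYPES)}


def genotype_of(allele_a: str, allele_b: str) -> int:
    """Canonical class index of an unordered allele pair, e.g. ('C','A') -> AC."""
    try:
        return _SORTED_INDEX["".join(sorted((allele_a.upper(), allele_b.upper())))]
    except KeyError as exc:
        raise ValueError(f"not a diploid ACGT genotype: {allele_a}/{allele_b}") from exc


def genotype_label(k: int) -> str:
    return GENOTYPES[k]


def genotype_bases(k: int) -> tuple[str, str]:
    a, b = GENOTYPE_ALLELES[k]
    return BASES[a], BASES[b]
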