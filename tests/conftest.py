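"""Shared fixtures: small simulated datasets and a brute-force Bayes oracle."""

from __future__ import annotations

import math

import numpy as np
import pysam
import pytest

from snvem.caller import CallerConfig, call_variants
from snvem.genotypes import BASES, GENOTYPES, N_CLASSES
from snvem.simulate import SimConfig, simulate


def brute_force_posterior(counts, ref_idx, theta, pi):
    """Independent oracle: plain-Python Bayes over the ten genotype classes.

    counts: nested list [learner][base]; theta: [learner][class][base];
    pi: [ref_base][class]. Deliberately loop-based and library-free so it
    shares nothing with the vectorized implementation it checks.
    """
    weights = []
    for k in range(N_CLASSES):
        w = pi[ref_idx][k]
        for j in range(len(counts)):
            for b in range(4):
                w *= theta[j][k][b] ** counts[j][b]
        weights.append(w)
    total = sum(weights)
    return [w / total for w in weights]


def brute_force_entropy(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """10 kb, 30x default-condition dataset shared across read-only tests."""
    out = tmp_path_factory.mktemp("small_sim")
    return simulate(SimConfig(seed=11, genome_length=10_000), out)


@pytest.fixture(scope="session")
def small_call_unfiltered(small_sim):
    """Unfiltered caller result on the 10 kb dataset."""
    return call_variants(
        small_sim.reads_sam,
        small_sim.reference_fasta,
        config=CallerConfig(apply_tree_filter=False),
    )


def write_sam(path, reads, contig="ctg", length=1000):
    """Write a tiny coordinate-sorted SAM from (name, flag, pos, mapq, seq, quals)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for name, flag, pos, mapq, seq, quals in sorted(reads, key=lambda r: r[2]):
            a = pysam.AlignedSegment(af.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(33 + q) for q in quals)
            )
            af.write(a)
    return path


def write_fasta(path, seq, contig="ctg"):
    with open(path, "w") as fh:
        fh.write(f">{contig}\n{seq}\n")
    pysam.faidx(str(path))
    return path
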