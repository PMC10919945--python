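"""Seeded synthetic test bed: reference, planted diploid SNVs, aligned reads.

The generator emulates a small whole-genome sequencing experiment in which
the true variants are known: an i.i.d. uniform reference, SNVs planted at a
configurable per-base rate (heterozygous with a configurable fraction),
and reads drawn uniformly from the two haplotypes. Each read belongs to one
learner stratum with its own substitution-error rate; the base-quality
string encodes the stratum, which is how the pileup engine's quality bins
recover it. Reads are emitted pre-aligned (perfect mapping, all-match
CIGAR) in coordinate-sorted SAM — alignment is upstream of the caller.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from snvem.genotypes import BASES, genotype_of
from snvem.vcfio import SnvRecord, write_truth_vcf

#: default learner strata: (base quality, substitution error rate, weight).
#: Qualities sit one per usable default quality bin ([10-19], [20-29], [30+]);
#: error rates follow the at-most-1%-per-base study condition at 30x.
DEFAULT_LEARNERS = (
    (15, 0.010, 1 / 3),
    (25, 0.004, 1 / 3),
    (35, 0.001, 1 / 3),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic experiment.

    Defaults model a 100 kb diploid genome at 30x coverage with one SNV per
    kilobase, two-thirds of them heterozygous — the canonical small-scale
    regime used throughout the test suite.
    """

    seed: int = 0
    genome_length: int = 100_000
    contig_name: str = "sim1"
    snv_rate: float = 1e-3
    het_fraction: float = 2 / 3
    coverage: float = 30.0
    read_length: int = 100
    error_rates: tuple[float, ...] = tuple(e for _, e, _ in DEFAULT_LEARNERS)
    learner_baseq: tuple[int, ...] = tuple(q for q, _, _ in DEFAULT_LEARNERS)
    learner_weights: tuple[float, ...] = tuple(w for _, _, w in DEFAULT_LEARNERS)
    mapq: int = 60
    #: fraction of reads drawn from a diverged contaminant genome instead of
    #: the sample haplotypes; contaminant variants are NOT in the truth set,
    #: so they seed low-allele-fraction false candidates (off by default)
    contamination_rate: float = 0.0
    #: per-base divergence of the contaminant genome from the reference
    contamination_divergence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.snv_rate < 1.0:
            raise ValueError("snv_rate must lie in [0, 1)")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if any(not 0.0 <= e < 0.5 for e in self.error_rates):
            raise ValueError("error rates must lie in [0, 0.5)")
        if len({len(self.error_rates), len(self.learner_baseq), len(self.learner_weights)}) != 1:
            raise ValueError("per-learner tuples must have equal length")
        if abs(sum(self.learner_weights) - 1.0) > 1e-9:
            raise ValueError("learner weights must sum to 1")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must lie in [0, 1)")
        if not 0.0 <= self.contamination_divergence < 1.0:
            raise ValueError("contamination_divergence must lie in [0, 1)")


@dataclass
class TruthVariant:
    pos: int  # 0-based
    ref_base: str
    genotype: int  # canonical class index, never homozygous reference


@dataclass
class SimOutput:
    """Paths of the written files plus the in-memory truth."""

    reference_fasta: Path
    reads_sam: Path
    truth_vcf: Path
    truth: list[TruthVariant]
    haplotypes: tuple[str, str]
    read_learners: np.ndarray  # learner index per read, in SAM order
    config: SimConfig


def _plant_variants(
    rng: np.random.Generator, ref: np.ndarray, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray, list[TruthVariant]]:
    """Plant SNVs; returns the two haplotypes (base-index arrays) and truth."""
    hap1 = ref.copy()
    hap2 = ref.copy()
    positions = np.nonzero(rng.random(cfg.genome_length) < cfg.snv_rate)[0]
    truth: list[TruthVariant] = []
    for pos in positions:
        r = int(ref[pos])
        alt = int(rng.choice([b for b in range(4) if b != r]))
        if rng.random() < cfg.het_fraction:
            # alt on a random haplotype
            if rng.random() < 0.5:
                hap1[pos] = alt
            else:
                hap2[pos] = alt
            gt = genotype_of(BASES[r], BASES[alt])
        else:
            hap1[pos] = alt
            hap2[pos] = alt
            gt = genotype_of(BASES[alt], BASES[alt])
        truth.append(TruthVariant(pos=int(pos), ref_base=BASES[r], genotype=gt))
    return hap1, hap2, truth


def simulate(
    config: SimConfig,
    out_dir: str | Path,
    prefix: str = "sim",
    write_fastq: bool = False,
) -> SimOutput:
    """Generate reference FASTA (+ .fai), coordinate-sorted SAM and truth VCF."""
    cfg = config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    ref = rng.integers(0, 4, cfg.genome_length, dtype=np.int8)
    hap1, hap2, truth = _plant_variants(rng, ref, cfg)

    contaminant = None
    if cfg.contamination_rate > 0.0:
        contaminant = ref.copy()
        div = np.nonzero(rng.random(cfg.genome_length) < cfg.contamination_divergence)[0]
        contaminant[div] = (contaminant[div] + rng.integers(1, 4, len(div))) % 4

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    ref_seq = base_arr[ref].tobytes().decode()

    fasta = out_dir / f"{prefix}.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{cfg.contig_name}\n")
        for i in range(0, len(ref_seq), 70):
            fh.write(ref_seq[i : i + 70] + "\n")
    pysam.faidx(str(fasta))

    n_reads = int(round(cfg.coverage * cfg.genome_length / cfg.read_length))
    starts = np.sort(
        rng.integers(0, cfg.genome_length - cfg.read_length + 1, n_reads)
    )
    hap_choice = rng.integers(0, 2, n_reads)
    learners = rng.choice(len(cfg.error_rates), size=n_reads, p=cfg.learner_weights)
    err = np.asarray(cfg.error_rates)
    if contaminant is not None:
        is_contam = rng.random(n_reads) < cfg.contamination_rate
    else:
        is_contam = np.zeros(n_reads, dtype=bool)

    haps = (hap1, hap2)
    sam = out_dir / f"{prefix}.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.contig_name, "LN": cfg.genome_length}],
    }
    rl = cfg.read_length
    qual_strings = {
        j: pysam.qualitystring_to_array(chr(33 + q) * rl)
        for j, q in enumerate(cfg.learner_baseq)
    }
    fastq_lines: list[str] = []
    with pysam.AlignmentFile(str(sam), "w", header=header) as af:
        for i in range(n_reads):
            s = int(starts[i])
            j = int(learners[i])
            source = contaminant if is_contam[i] else haps[hap_choice[i]]
            bases = source[s : s + rl].copy()
            err_mask = rng.random(rl) < err[j]
            if err_mask.any():
                idx = np.nonzero(err_mask)[0]
                # uniform among the three wrong bases
                bases[idx] = (bases[idx] + rng.integers(1, 4, len(idx))) % 4
            seq = base_arr[bases].tobytes().decode()
            a = pysam.AlignedSegment(af.header)
            a.query_name = f"r{i:08d}"
            a.flag = 0
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = cfg.mapq
            a.cigarstring = f"{rl}M"
            a.query_sequence = seq
            a.query_qualities = qual_strings[j]
            af.write(a)
            if write_fastq:
                fastq_lines.append(
                    f"@r{i:08d}\n{seq}\n+\n{chr(33 + cfg.learner_baseq[j]) * rl}\n"
                )
    if write_fastq:
        (out_dir / f"{prefix}.fq").write_text("".join(fastq_lines))

    truth_vcf = out_dir / f"{prefix}.truth.vcf"
    write_truth_vcf(
        [
            SnvRecord(
                contig=cfg.contig_name, pos=t.pos, ref_base=t.ref_base, genotype=t.genotype
            )
            for t in truth
        ],
        truth_vcf,
        contigs={cfg.contig_name: cfg.genome_length},
    )

    hap_seqs = (base_arr[hap1].tobytes().decode(), base_arr[hap2].tobytes().decode())
    return SimOutput(
        reference_fasta=fasta,
        reads_sam=sam,
        truth_vcf=truth_vcf,
        truth=truth,
        haplotypes=hap_seqs,
        read_learners=learners,
        config=cfg,
    )
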