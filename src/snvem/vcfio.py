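"""VCF 4.2 output for called SNVs and genotype-aware benchmarking.

Writing and parsing go through pysam/htslib. Evaluation compares a call
set against a truth set with genotype-aware matching at identical
(chrom, pos): a call is a true positive only when its genotype is
identical to the truth genotype; a call at a truth locus with the wrong
genotype counts as both a false positive and a false negative. For
isolated SNVs this is equivalent to haplotype-comparison benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from intervaltree import IntervalTree

from snvem.genotypes import BASE_INDEX, genotype_bases, genotype_of
from snvem.variants import CandidateVariant

QUAL_CAP = 99.0


@dataclass
class SnvRecord:
    """A minimal SNV record: 0-based position, reference base, genotype."""

    contig: str
    pos: int  # 0-based
    ref_base: str
    genotype: int  # canonical class index
    qual: float | None = None
    depth: int | None = None
    alt_fraction: float | None = None
    entropy_bits: float | None = None


@dataclass
class EvalReport:
    """TP/FP/FN counts with precision, recall and f1.

    When no calls are evaluated, precision is reported as 1.0 with
    ``zero_calls`` set so the value cannot be misread as an earned score.
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    zero_calls: bool = False
    skipped_calls: int = 0
    skipped_truth: int = 0

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, skipped_calls: int = 0, skipped_truth: int = 0
    ) -> "EvalReport":
        zero_calls = (tp + fp) == 0
        precision = 1.0 if zero_calls else tp / (tp + fp)
        recall = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        return cls(
            tp=tp,
            fp=fp,
            fn=fn,
            precision=precision,
            recall=recall,
            f1=f1,
            zero_calls=zero_calls,
            skipped_calls=skipped_calls,
            skipped_truth=skipped_truth,
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "zero_calls": self.zero_calls,
            "skipped_calls": self.skipped_calls,
            "skipped_truth": self.skipped_truth,
        }


def _make_header(contigs: dict[str, int], sample_name: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Total retained read depth at the locus")
    header.info.add("AF", "A", "Float", "Fraction of retained reads with a non-reference base")
    header.info.add("ENT", 1, "Float", "Shannon entropy (bits) of the 10-class genotype posterior")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_name)
    return header


def _gt_and_alts(ref_base: str, genotype: int) -> tuple[list[str], tuple[int, int]]:
    """ALT list and GT allele indices for a decided genotype on ref_base."""
    a, b = genotype_bases(genotype)
    alts: list[str] = []
    idx = []
    for allele in (a, b):
        if allele == ref_base:
            idx.append(0)
        else:
            if allele not in alts:
                alts.append(allele)
            idx.append(alts.index(allele) + 1)
    return alts, (min(idx), max(idx))


def write_vcf(
    candidates: Sequence[CandidateVariant],
    path: str | Path,
    contigs: dict[str, int],
    sample_name: str = "sample",
) -> None:
    """Write kept candidates as a VCF 4.2 file (sorted input required).

    QUAL is the Phred-scaled confidence -10*log10(1 - posterior of the
    decided class), capped at 99.
    """
    order = [(c.contig, c.pos) for c in candidates]
    if order != sorted(order):
        raise ValueError("candidates must be sorted by (contig, pos)")
    header = _make_header(contigs, sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for c in candidates:
            alts, gt = _gt_and_alts(c.ref_base, c.decided)
            p = float(c.posterior[c.decided])
            qual = QUAL_CAP if p >= 1.0 else min(QUAL_CAP, -10.0 * math.log10(1.0 - p))
            rec = vf.new_record(
                contig=c.contig,
                start=c.pos,
                stop=c.pos + 1,
                alleles=[c.ref_base] + alts,
                qual=round(qual, 2),
                filter="PASS",
            )
            rec.info["DP"] = c.depth
            rec.info["AF"] = tuple([c.alt_fraction] * len(alts))
            rec.info["ENT"] = c.entropy_bits
            rec.samples[sample_name]["GT"] = gt
            rec.samples[sample_name].phased = False
            vf.write(rec)


def write_truth_vcf(
    records: Sequence[SnvRecord], path: str | Path, contigs: dict[str, int],
    sample_name: str = "truth",
) -> None:
    """Write plain SNV records (e.g. a simulated truth set) as VCF 4.2."""
    header = _make_header(contigs, sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            alts, gt = _gt_and_alts(r.ref_base, r.genotype)
            rec = vf.new_record(
                contig=r.contig,
                start=r.pos,
                stop=r.pos + 1,
                alleles=[r.ref_base] + alts,
                qual=r.qual,
                filter="PASS",
            )
            if r.depth is not None:
                rec.info["DP"] = r.depth
            rec.samples[sample_name]["GT"] = gt
            rec.samples[sample_name].phased = False
            vf.write(rec)


def read_snvs(path: str | Path) -> tuple[list[SnvRecord], int]:
    """Read biallelic/multiallelic SNV records with genotypes from a VCF.

    Returns (records, skipped): records whose alleles are not all single
    ACGT bases, that lack a called genotype, or that duplicate an earlier
    (chrom, pos) are skipped and counted.
    """
    records: list[SnvRecord] = []
    seen: set[tuple[str, int]] = set()
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            try:
                alleles = [a.upper() for a in rec.alleles]
            except (TypeError, AttributeError):
                skipped += 1
                continue
            if any(len(a) != 1 or a not in BASE_INDEX for a in alleles):
                skipped += 1
                continue
            if not samples:
                skipped += 1
                continue
            gt = rec.samples[samples[0]].get("GT")
            if gt is None or len(gt) != 2 or any(i is None for i in gt):
                skipped += 1
                continue
            key = (rec.chrom, rec.start)
            if key in seen:
                skipped += 1
                continue
            seen.add(key)
            info = dict(rec.info)
            af = info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            records.append(
                SnvRecord(
                    contig=rec.chrom,
                    pos=rec.start,
                    ref_base=alleles[0],
                    genotype=genotype_of(alleles[gt[0]], alleles[gt[1]]),
                    qual=rec.qual,
                    depth=info.get("DP"),
                    alt_fraction=af,
                    entropy_bits=info.get("ENT"),
                )
            )
    return records, skipped


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-contig interval trees."""
    trees: dict[str, IntervalTree] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _in_regions(regions: dict[str, IntervalTree] | None, contig: str, pos: int) -> bool:
    if regions is None:
        return True
    tree = regions.get(contig)
    return bool(tree is not None and tree.overlaps(pos))


def evaluate(
    calls: str | Path,
    truth: str | Path,
    regions: str | Path | dict[str, IntervalTree] | None = None,
) -> EvalReport:
    """Precision/recall/f1 of a call VCF against a truth VCF.

    Precision is the fraction of calls that are true; recall the fraction
    of truths that are called; f1 their harmonic mean. Matching is
    genotype-aware at identical positions; optional confident regions
    (BED, 0-based half-open) restrict both sets.
    """
    if regions is not None and not isinstance(regions, dict):
        regions = read_bed(regions)
    call_recs, skipped_calls = read_snvs(calls)
    truth_recs, skipped_truth = read_snvs(truth)

    truth_map = {
        (r.contig, r.pos): r.genotype
        for r in truth_recs
        if _in_regions(regions, r.contig, r.pos)
    }
    tp = fp = 0
    matched: set[tuple[str, int]] = set()
    for r in call_recs:
        if not _in_regions(regions, r.contig, r.pos):
            continue
        key = (r.contig, r.pos)
        if truth_map.get(key) == r.genotype:
            tp += 1
            matched.add(key)
        else:
            fp += 1
    fn = len(truth_map) - len(matched)
    return EvalReport.from_counts(
        tp, fp, fn, skipped_calls=skipped_calls, skipped_truth=skipped_truth
    )
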