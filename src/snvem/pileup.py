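"""Pileup engine: per-locus, per-learner nucleotide observation counts.

Converts a reference FASTA plus coordinate-sorted alignments into the EM's
sufficient statistics: for every covered reference position, an L x 4
integer matrix of nucleotide counts, stratified by "learner" — here a
base-quality bin. Alignment parsing (flags, CIGAR) is delegated to pysam;
this module only filters and counts.

Coordinates are 0-based half-open internally; the samtools-style region
string accepted by :func:`parse_region` is 1-based inclusive.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from snvem.genotypes import BASE_INDEX

MAX_PHRED = 93  # highest base quality encodable in SAM ('~')


@dataclass(frozen=True)
class LearnerSpec:
    """Partition of the base-quality range into learner bins.

    ``lower_bounds`` are the inclusive lower edges of the bins; the default
    (0, 10, 20, 30) gives four learners covering [0-9], [10-19], [20-29]
    and [30+]. Bins are exhaustive and non-overlapping by construction, so
    every non-negative quality maps to exactly one learner.
    """

    lower_bounds: tuple[int, ...] = (0, 10, 20, 30)

    def __post_init__(self) -> None:
        if len(self.lower_bounds) < 1 or self.lower_bounds[0] != 0:
            raise ValueError("learner bins must start at quality 0")
        if list(self.lower_bounds) != sorted(set(self.lower_bounds)):
            raise ValueError("learner bin bounds must be strictly increasing")

    @property
    def n_learners(self) -> int:
        return len(self.lower_bounds)

    def assign(self, base_quality: int) -> int:
        """Index of the unique bin containing ``base_quality``."""
        if base_quality < 0:
            raise ValueError(f"negative base quality: {base_quality}")
        return bisect.bisect_right(self.lower_bounds, base_quality) - 1

    def quality_lut(self) -> np.ndarray:
        """Vectorized quality -> learner lookup table over 0..MAX_PHRED."""
        return np.array([self.assign(q) for q in range(MAX_PHRED + 1)], dtype=np.int64)


def assign_learner(base_quality: int, mapping_quality: int, learner_spec: LearnerSpec) -> int:
    """Learner id for one read observation.

    Learners are defined purely by base-quality strata; ``mapping_quality``
    is part of the observation record but does not influence the bin (reads
    below the mapping-quality floor are excluded upstream instead).
    """
    if mapping_quality < 0:
        raise ValueError(f"negative mapping quality: {mapping_quality}")
    return learner_spec.assign(base_quality)


@dataclass(frozen=True)
class ReadFilterConfig:
    """Which alignments and base observations enter the pileup."""

    min_mapq: int = 20
    min_baseq: int = 13
    exclude_duplicates: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_qcfail: bool = True


@dataclass
class LocusPileup:
    """Per-locus sufficient statistics: counts[learner, base] over A,C,G,T."""

    contig: str
    pos: int  # 0-based
    ref_base: str
    counts: np.ndarray  # shape (L, 4), integer
    depth: int

    def alt_fraction(self) -> float:
        if self.depth == 0:
            return 0.0
        ref_count = int(self.counts[:, BASE_INDEX[self.ref_base]].sum())
        return (self.depth - ref_count) / self.depth


@dataclass
class PileupStats:
    """Counters accumulated while building pileups."""

    reads_seen: int = 0
    reads_filtered: int = 0
    observations: int = 0
    dropped_baseq: int = 0
    dropped_n_base: int = 0
    dropped_negative_quality: int = 0
    skipped_n_reference: int = 0

    def merge(self, other: "PileupStats") -> None:
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))


_REGION_RE = re.compile(r"^([^:]+)(?::([\d,]+)-([\d,]+))?$")


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    """Parse a samtools-style region ``ctg`` or ``ctg:start-end`` (1-based
    inclusive) into (contig, 0-based start, 0-based exclusive end)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region: {region!r}")
    contig, s, e = m.groups()
    if s is None:
        return contig, None, None
    start = int(s.replace(",", "")) - 1
    end = int(e.replace(",", ""))
    if start < 0 or end <= start:
        raise ValueError(f"empty or negative region: {region!r}")
    return contig, start, end


def _read_passes(read: pysam.AlignedSegment, filters: ReadFilterConfig) -> bool:
    if read.is_unmapped:
        return False
    if filters.exclude_secondary and read.is_secondary:
        return False
    if filters.exclude_supplementary and read.is_supplementary:
        return False
    if filters.exclude_duplicates and read.is_duplicate:
        return False
    if filters.exclude_qcfail and read.is_qcfail:
        return False
    if read.mapping_quality < filters.min_mapq:
        return False
    return True


# base byte -> index, -1 for anything outside ACGT (N, ambiguity codes)
_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def _iter_reads(
    af: pysam.AlignmentFile, contig: str | None, start: int | None, end: int | None
) -> Iterator[pysam.AlignedSegment]:
    if contig is None:
        yield from af
        return
    if af.has_index():
        yield from af.fetch(contig, start, end)
        return
    # no index: stream the (coordinate-sorted) file and keep overlapping reads
    for read in af:
        if read.reference_name != contig or read.is_unmapped:
            continue
        if end is not None and read.reference_start >= end:
            break  # sorted input: nothing further can overlap
        if start is not None and (read.reference_end or 0) <= start:
            continue
        yield read


def build_pileups(
    alignments: str | Path,
    reference: str | Path,
    contig: str | None = None,
    start: int | None = None,
    end: int | None = None,
    filters: ReadFilterConfig | None = None,
    learner_spec: LearnerSpec | None = None,
    stats: PileupStats | None = None,
) -> list[LocusPileup]:
    """Build per-locus observation counts for one reference window.

    Only read-to-reference match columns contribute (insertions are skipped
    and deletion columns add no observation). Reads failing the alignment
    filters contribute nothing; individual observations below the
    base-quality floor or with a non-ACGT base are dropped. Positions whose
    reference base is N are skipped entirely.

    Returns one :class:`LocusPileup` per position with at least one retained
    observation, in coordinate order.
    """
    filters = filters or ReadFilterConfig()
    learner_spec = learner_spec or LearnerSpec()
    stats = stats if stats is not None else PileupStats()

    with pysam.FastaFile(str(reference)) as fa:
        if contig is None:
            if fa.nreferences != 1:
                raise ValueError("contig must be given for a multi-contig reference")
            contig = fa.references[0]
        if contig not in fa.references:
            raise ValueError(f"contig {contig!r} absent from reference")
        contig_len = fa.get_reference_length(contig)
        w_start = 0 if start is None else max(0, start)
        w_end = contig_len if end is None else min(end, contig_len)
        if w_end <= w_start:
            return []
        ref_bases = fa.fetch(contig, w_start, w_end).upper()

    L = learner_spec.n_learners
    qual_lut = learner_spec.quality_lut()
    counts = np.zeros((w_end - w_start, L, 4), dtype=np.int32)

    with pysam.AlignmentFile(str(alignments)) as af:
        for read in _iter_reads(af, contig, start, end):
            stats.reads_seen += 1
            if not _read_passes(read, filters):
                stats.reads_filtered += 1
                continue
            quals = read.query_qualities
            seq = read.query_sequence
            if quals is None or seq is None:
                stats.reads_filtered += 1
                continue
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qidx = np.fromiter((p[0] for p in pairs), np.int64, len(pairs))
            ridx = np.fromiter((p[1] for p in pairs), np.int64, len(pairs))
            in_window = (ridx >= w_start) & (ridx < w_end)
            if not in_window.any():
                continue
            qidx, ridx = qidx[in_window], ridx[in_window]
            bases = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][qidx]
            bq = np.asarray(quals, dtype=np.int64)[qidx]

            neg = bq < 0
            if neg.any():  # defensive: SAM cannot encode these, but contract says count
                stats.dropped_negative_quality += int(neg.sum())
            n_base = bases < 0
            stats.dropped_n_base += int(n_base.sum())
            low_q = (~n_base) & (~neg) & (bq < filters.min_baseq)
            stats.dropped_baseq += int(low_q.sum())

            keep = (~neg) & (~n_base) & (bq >= filters.min_baseq)
            if not keep.any():
                continue
            np.add.at(
                counts,
                (ridx[keep] - w_start, qual_lut[np.minimum(bq[keep], MAX_PHRED)], bases[keep]),
                1,
            )

    depths = counts.sum(axis=(1, 2))
    pileups: list[LocusPileup] = []
    for off in np.nonzero(depths)[0]:
        ref_b = ref_bases[off]
        if ref_b not in BASE_INDEX:
            stats.skipped_n_reference += 1
            continue
        d = int(depths[off])
        stats.observations += d
        pileups.append(
            LocusPileup(
                contig=contig,
                pos=w_start + int(off),
                ref_base=ref_b,
                counts=counts[off].copy(),
                depth=d,
            )
        )
    return pileups


def dump_pileups(pileups: Iterable[LocusPileup]) -> str:
    """Deterministic text dump of pileups (one line per locus), used for
    byte-identity checks and debugging."""
    lines = []
    for p in pileups:
        flat = ",".join(str(int(x)) for x in p.counts.ravel())
        lines.append(f"{p.contig}\t{p.pos}\t{p.ref_base}\t{p.depth}\t{flat}")
    return "\n".join(lines) + ("\n" if lines else "")
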