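"""The two-step calling pipeline: pileup -> EM genotyping -> candidates
(-> decision-tree filter), fitted per window with deterministic merging."""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from snvem.em import EMConfig, EMResult, call_candidates, run_em
from snvem.filtering import FilterModel, apply_filter, default_filter_model
from snvem.pileup import (
    LearnerSpec,
    PileupStats,
    ReadFilterConfig,
    build_pileups,
    parse_region,
)
from snvem.variants import CandidateVariant


@dataclass(frozen=True)
class CallerConfig:
    filters: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    learner_spec: LearnerSpec = field(default_factory=LearnerSpec)
    em: EMConfig = field(default_factory=EMConfig)
    window_size: int = 1_000_000
    apply_tree_filter: bool = True
    threads: int = 1


@dataclass
class WindowLog:
    contig: str
    start: int
    end: int
    n_loci: int
    n_iters: int
    converged: bool
    loglik_trace: list[float]
    objective_trace: list[float]


@dataclass
class CallResult:
    candidates: list[CandidateVariant]  # after the tree filter, if applied
    raw_candidates: list[CandidateVariant]  # EM candidates before filtering
    windows: list[WindowLog]
    stats: PileupStats
    contigs: dict[str, int]
    filter_model: FilterModel | None


def _windows(
    ref_path: str | Path, region: str | None, window_size: int
) -> tuple[list[tuple[str, int, int]], dict[str, int]]:
    with pysam.FastaFile(str(ref_path)) as fa:
        lengths = dict(zip(fa.references, fa.lengths))
    if region is not None:
        contig, start, end = parse_region(region)
        if contig not in lengths:
            raise ValueError(f"contig {contig!r} absent from reference")
        start = start or 0
        end = lengths[contig] if end is None else min(end, lengths[contig])
        spans = [(contig, start, end)]
    else:
        spans = [(c, 0, ln) for c, ln in lengths.items()]
    wins = []
    for contig, start, end in spans:
        for s in range(start, end, window_size):
            wins.append((contig, s, min(s + window_size, end)))
    return wins, lengths


def call_variants(
    alignments: str | Path,
    reference: str | Path,
    region: str | None = None,
    config: CallerConfig | None = None,
    filter_model: FilterModel | None = None,
) -> CallResult:
    """Run the pipeline over a reference (or one region) and return candidates.

    The EM is fitted independently per window (default 1 Mb); windows are
    processed by a thread pool when ``config.threads > 1`` and merged in
    coordinate order, so the output is identical regardless of thread count.
    """
    config = config or CallerConfig()
    wins, lengths = _windows(reference, region, config.window_size)
    stats = PileupStats()

    def run_window(win: tuple[str, int, int]):
        contig, start, end = win
        local_stats = PileupStats()
        pileups = build_pileups(
            alignments,
            reference,
            contig=contig,
            start=start,
            end=end,
            filters=config.filters,
            learner_spec=config.learner_spec,
            stats=local_stats,
        )
        if not pileups:
            return None, local_stats
        em = run_em(pileups, config.learner_spec, config.em)
        cands = call_candidates(em.posteriors, pileups)
        log = WindowLog(
            contig=contig,
            start=start,
            end=end,
            n_loci=len(pileups),
            n_iters=em.n_iters,
            converged=em.converged,
            loglik_trace=em.loglik_trace,
            objective_trace=em.objective_trace,
        )
        return (cands, log), local_stats

    results = []
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            for out, local_stats in pool.map(run_window, wins):
                results.append(out)
                stats.merge(local_stats)
    else:
        for win in wins:
            out, local_stats = run_window(win)
            results.append(out)
            stats.merge(local_stats)

    raw: list[CandidateVariant] = []
    windows: list[WindowLog] = []
    for out in results:
        if out is None:
            continue
        cands, log = out
        raw.extend(cands)
        windows.append(log)

    model = None
    kept = raw
    if config.apply_tree_filter:
        model = filter_model if filter_model is not None else default_filter_model()
        kept = apply_filter(raw, model)

    return CallResult(
        candidates=kept,
        raw_candidates=raw,
        windows=windows,
        stats=stats,
        contigs=lengths,
        filter_model=model,
    )
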