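"""Truth matching and the end-to-end detection pipeline.

A call matches a truth junction when chromosome and strand agree and
both junction ends are within the matching tolerance (default 5 bp);
matching is one-to-one and greedy in coordinate-sorted order.  The
report carries the hit number N_h (calls matching truth), the total
call count N and the accuracy N_h / N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genome_annotation import AnnotationCatalog, read_fasta, read_gtf
from .junction_caller import (
    CircCandidate,
    SELF,
    call_candidate,
    refine,
    self_circle_detectable,
    write_calls,
)
from .kmer_index import Config, KmerTable, build_table
from .read_scanner import ReadRecord, best_hit_for_read, read_fastq
from .synthetic_data import TruthJunction

log = logging.getLogger(__name__)

__all__ = [
    "MatchReport",
    "PipelineResult",
    "match_calls",
    "eligible_truth",
    "detect_reads",
    "run_pipeline",
]


@dataclass
class MatchReport:
    """Comparison of called junctions against a truth set."""

    n_called: int
    n_hit: int
    n_truth: int
    misses: list[TruthJunction] = field(default_factory=list)

    @property
    def accuracy(self) -> float | None:
        """N_h / N; None (reported as null) when nothing was called."""
        if self.n_called == 0:
            return None
        return self.n_hit / self.n_called

    @property
    def recall(self) -> float | None:
        if self.n_truth == 0:
            return None
        return (self.n_truth - len(self.misses)) / self.n_truth

    def as_dict(self) -> dict[str, object]:
        return {
            "n_called": self.n_called,
            "n_hit": self.n_hit,
            "n_truth": self.n_truth,
            "accuracy": self.accuracy,
            "recall": self.recall,
            "misses": [
                {"chrom": m.chrom, "start": m.start, "end": m.end,
                 "strand": m.strand, "case_type": m.case_type}
                for m in self.misses
            ],
        }


def match_calls(
    calls: Sequence[CircCandidate],
    truth: Sequence[TruthJunction],
    tolerance: int = 5,
) -> MatchReport:
    """Greedy one-to-one matching of calls to truth junctions.

    Both ends must lie within ``tolerance`` bp and chromosome and
    strand must agree.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.start, c.end))
    truth_sorted = sorted(truth, key=lambda t: (t.chrom, t.start, t.end))
    unmatched = list(truth_sorted)
    n_hit = 0
    for call in calls:
        for i, tj in enumerate(unmatched):
            if (
                call.chrom == tj.chrom
                and call.strand == tj.strand
                and abs(call.start - tj.start) <= tolerance
                and abs(call.end - tj.end) <= tolerance
            ):
                n_hit += 1
                del unmatched[i]
                break
    return MatchReport(
        n_called=len(calls), n_hit=n_hit, n_truth=len(truth), misses=unmatched
    )


def eligible_truth(
    truth: Sequence[TruthJunction], config: Config | None = None
) -> list[TruthJunction]:
    """Truth junctions detectable in principle under the calling rules.

    Self-circular exons near the read length can never reach the
    minimum hitting number (every wrapping read forfeits the k-mers
    spanning the junction), so such junctions are excluded; everything
    else planted by the simulator carries the required signals by
    construction.
    """
    config = config or Config()
    out = []
    for tj in truth:
        if tj.case_type == SELF and not self_circle_detectable(
            tj.end - tj.start, config
        ):
            continue
        out.append(tj)
    return out


@dataclass
class PipelineResult:
    candidates: list[CircCandidate]
    counters: dict[str, int]
    report: MatchReport | None = None


def detect_reads(
    reads: Iterable[ReadRecord],
    table: KmerTable,
    catalog: AnnotationCatalog,
    config: Config,
) -> tuple[list[CircCandidate], dict[str, int]]:
    """Per-read detection loop: quick check, scan, best case, both
    filtering procedures, calling; then support-count refinement."""
    counters = {
        "reads_seen": 0,
        "reads_too_short": 0,
        "quick_check_failed": 0,
        "no_best_case": 0,
        "below_min_hits": 0,
        "rejected_case": 0,
        "supporting_reads": 0,
    }
    per_read: list[CircCandidate] = []
    from .genome_annotation import reverse_complement
    from .junction_caller import passes_min_hits
    from .read_scanner import BestHitCase, orient_and_scan, quick_check, select_best

    for read in reads:
        counters["reads_seen"] += 1
        if len(read.sequence) < config.k:
            counters["reads_too_short"] += 1
            continue
        if not (
            quick_check(read.sequence, table, config)
            or quick_check(reverse_complement(read.sequence), table, config)
        ):
            counters["quick_check_failed"] += 1
            continue
        statuses, orientation = orient_and_scan(read, table, config, catalog)
        status = select_best(statuses, config)
        if status is None:
            counters["no_best_case"] += 1
            continue
        if not passes_min_hits(status, config):
            counters["below_min_hits"] += 1
            continue
        best = BestHitCase(status=status, orientation=orientation)
        cand = call_candidate(best, config, catalog)
        if cand is None:
            counters["rejected_case"] += 1
            continue
        counters["supporting_reads"] += 1
        per_read.append(cand)
    candidates = refine(per_read, config)
    counters["candidates"] = len(candidates)
    for name, value in counters.items():
        log.info("counter %s = %d", name, value)
    return candidates, counters


def run_pipeline(
    genome: dict[str, str],
    catalog: AnnotationCatalog,
    reads: Iterable[ReadRecord],
    config: Config | None = None,
    truth: Sequence[TruthJunction] | None = None,
    out_bed: str | Path | None = None,
) -> PipelineResult:
    """Build the k-mer table, detect over all reads, refine, optionally
    write BED and score against a truth set."""
    config = config or Config()
    table = build_table(catalog, genome, config)
    log.info("k-mer table: %d keys over %d chromosomes",
             table.n_kmers, len(table.per_chrom))
    candidates, counters = detect_reads(reads, table, catalog, config)
    if out_bed is not None:
        write_calls(candidates, out_bed)
    report = None
    if truth is not None:
        report = match_calls(candidates, truth, tolerance=config.tolerance)
    return PipelineResult(candidates=candidates, counters=counters, report=report)


def run_files(
    fasta: str | Path,
    gtf: str | Path,
    fastq: str | Path,
    fastq2: str | Path | None = None,
    config: Config | None = None,
    out_bed: str | Path | None = None,
    truth: Sequence[TruthJunction] | None = None,
) -> PipelineResult:
    """File-based wrapper around :func:`run_pipeline`."""
    genome = read_fasta(fasta)
    catalog = read_gtf(gtf, genome)

    def reads() -> Iterable[ReadRecord]:
        yield from read_fastq(fastq, mate=1 if fastq2 else None)
        if fastq2 is not None:
            yield from read_fastq(fastq2, mate=2)

    return run_pipeline(genome, catalog, reads(), config=config,
                        truth=truth, out_bed=out_bed)
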