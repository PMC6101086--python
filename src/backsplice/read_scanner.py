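"""Streaming read scanner.

Each read first passes a cheap sampling check (eight k-mers spread
from the 10% to the 80% position must yield at least two table hits),
then every k-mer from start to end is looked up and its hits are
grouped per transcript into "hitting statuses" kept in read order.
The best hitting status is selected by preferring clearly larger
support (N_h exceeding the incumbent by more than the margin), and
otherwise the shorter total hit-exon length; a best case with fewer
than ``min_best_hits`` supporting k-mers is discarded.

Only the genome-forward strand is indexed, so each read is scanned in
both orientations and the orientation whose best status wins under the
same ordering is kept (ties go to forward).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome_annotation import AnnotationCatalog, reverse_complement
from .kmer_index import Config, KmerTable, encode_all

log = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "TagEvent",
    "HittingStatus",
    "BestHitCase",
    "read_fastq",
    "quick_check",
    "scan_read",
    "orient_and_scan",
    "select_best",
    "best_hit_for_read",
    "QUICK_CHECK_FRACTIONS",
    "QUICK_CHECK_MIN_HITS",
]

#: sampling positions of the quick check, as fractions of (|read| - k)
QUICK_CHECK_FRACTIONS = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80)
#: minimum number of sampled k-mers that must hit the table
QUICK_CHECK_MIN_HITS = 2

FORWARD = "forward"
REVERSE = "reverse-complement"


class ReadRecord(NamedTuple):
    id: str
    sequence: str
    mate: int | None = None


class TagEvent(NamedTuple):
    """One k-mer hit: which exon (within its transcript), which exon
    part, and where in the read."""

    exon_index: int
    part_tag: str
    read_offset: int


@dataclass
class HittingStatus:
    """All hits of one read against one transcript, in read order."""

    transcript_key: tuple[int, int, int]  # (chrom, gene, transcript) indices
    events: list[TagEvent] = field(default_factory=list)
    hit_exon_lengths: dict[int, int] = field(default_factory=dict)

    @property
    def n_h(self) -> int:
        return len(self.events)

    @property
    def exon_hit_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for ev in self.events:
            counts[ev.exon_index] = counts.get(ev.exon_index, 0) + 1
        return counts

    @property
    def total_hit_exon_len(self) -> int:
        return sum(self.hit_exon_lengths.values())


@dataclass
class BestHitCase:
    status: HittingStatus
    orientation: str = FORWARD


def read_fastq(path: str | Path, mate: int | None = None) -> Iterator[ReadRecord]:
    """Stream a (possibly gzipped) FASTQ file as ReadRecords."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield ReadRecord(id=title.split()[0], sequence=seq.upper(), mate=mate)


def quick_check(sequence: str, table: KmerTable, config: Config) -> bool:
    """Sampling pre-filter: True iff at least two of the eight sampled
    k-mers (offsets at 10%..80% of |read|-k) hit the table."""
    span = len(sequence) - config.k
    if span < 0:
        return False
    offsets = sorted({int(frac * span) for frac in QUICK_CHECK_FRACTIONS})
    hits = 0
    for off in offsets:
        kmer = sequence[off : off + config.k]
        codes = encode_all(kmer, config.k)
        if codes and codes[0] >= 0 and table.lookup(codes[0]):
            hits += 1
            if hits >= QUICK_CHECK_MIN_HITS:
                return True
    return False


def scan_read(
    sequence: str,
    table: KmerTable,
    config: Config,
    catalog: AnnotationCatalog,
) -> list[HittingStatus]:
    """Collect hitting statuses for every k-mer of the read, start to
    end, grouped per transcript in first-encounter order."""
    statuses: dict[tuple[int, int, int], HittingStatus] = {}
    for offset, code in enumerate(encode_all(sequence, config.k)):
        if code < 0:
            continue
        for pos in table.lookup(code):
            key = (pos.chrom_index, pos.gene_index, pos.transcript_index)
            status = statuses.get(key)
            if status is None:
                status = HittingStatus(transcript_key=key)
                statuses[key] = status
            status.events.append(
                TagEvent(exon_index=pos.exon_index, part_tag=pos.part_tag,
                         read_offset=offset)
            )
            if pos.exon_index not in status.hit_exon_lengths:
                exon = catalog.exon(*key, pos.exon_index)
                status.hit_exon_lengths[pos.exon_index] = exon.length
    return list(statuses.values())


def _beats(challenger: HittingStatus, best_n: int, best_len: int, margin: int) -> bool:
    """The best-hitting-case replacement rule: clearly more supporting
    k-mers wins; within the margin, the shorter total hit-exon length
    wins."""
    if challenger.n_h - best_n > margin:
        return True
    return (
        abs(challenger.n_h - best_n) <= margin
        and challenger.total_hit_exon_len < best_len
    )


def select_best(
    statuses: list[HittingStatus], config: Config
) -> HittingStatus | None:
    """Pick the best hitting status, or None.

    Iterates in encounter order, keeping (PreBestHitNum, PreBestHitLen)
    for the incumbent; the final incumbent is returned only if its N_h
    reaches ``min_best_hits``.
    """
    if not statuses:
        return None
    best = statuses[0]
    best_n, best_len = best.n_h, best.total_hit_exon_len
    for status in statuses[1:]:
        if _beats(status, best_n, best_len, config.best_hit_margin):
            best = status
            best_n, best_len = status.n_h, status.total_hit_exon_len
    if best.n_h < config.min_best_hits:
        return None
    return best


def orient_and_scan(
    read: ReadRecord,
    table: KmerTable,
    config: Config,
    catalog: AnnotationCatalog,
) -> tuple[list[HittingStatus], str]:
    """Scan the read and its reverse complement; keep the orientation
    whose best status wins under the select_best ordering (ties ->
    forward)."""
    fwd = scan_read(read.sequence, table, config, catalog)
    rev = scan_read(reverse_complement(read.sequence), table, config, catalog)
    best_f = select_best(fwd, config)
    best_r = select_best(rev, config)
    if best_r is None:
        return fwd, FORWARD
    if best_f is None:
        return rev, REVERSE
    if _beats(best_r, best_f.n_h, best_f.total_hit_exon_len, config.best_hit_margin):
        return rev, REVERSE
    return fwd, FORWARD


def best_hit_for_read(
    read: ReadRecord,
    table: KmerTable,
    config: Config,
    catalog: AnnotationCatalog,
) -> BestHitCase | None:
    """Quick check (either orientation), scan, select: the per-read
    front half of the pipeline."""
    if len(read.sequence) < config.k:
        return None
    if not (
        quick_check(read.sequence, table, config)
        or quick_check(reverse_complement(read.sequence), table, config)
    ):
        return None
    statuses, orientation = orient_and_scan(read, table, config, catalog)
    best = select_best(statuses, config)
    if best is None:
        return None
    return BestHitCase(status=best, orientation=orientation)
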