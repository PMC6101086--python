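"""Filtering and back-spliced junction calling.

A best hitting case survives filtering procedure one only if its
support N_h reaches the minimum hitting number

    N_hm = sum(L_he) - K + 5   if sum(L_he) <= L_em   (short exons must
                                be covered more than once by the read)
    N_hm = floor(1.2 * L_B)    otherwise               (the read must sit
                                within both exon boundaries)

Procedure two splits cases by the number of hit exons: one exon is a
self-circular candidate, exactly two exons (after skipping exons with
at most three hits) a regular-circular candidate.  Part tags are
condensed per exon and a valid back-splice must read "E" then "S" —
k-mers out of order relative to the reference.  Hit events are
canonicalised to transcript order first (for "−" genes this reverses
the read order and swaps S/E), so the strand-specific breakpoint rules
apply exactly as stated: on "+" the exon index must decrease at the
junction (head exon = larger index), on "−" it must increase (head
exon = smaller index).  The called junction is the genomic interval
from the tail-side exon start to the head-side exon end, which for
both strands is (leftmost exon start, rightmost exon end).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

from .genome_annotation import AnnotationCatalog, ExonRecord
from .kmer_index import Config, TAG_END, TAG_START
from .read_scanner import BestHitCase, HittingStatus, TagEvent

log = logging.getLogger(__name__)

__all__ = [
    "SELF", "REGULAR",
    "CondensedTag",
    "CircCandidate",
    "min_hit_threshold",
    "passes_min_hits",
    "max_wrap_hits",
    "self_circle_detectable",
    "classify_case",
    "events_transcript_order",
    "condense_tags",
    "call_self",
    "call_regular",
    "call_candidate",
    "refine",
    "write_calls",
    "read_calls",
]

SELF = "self"
REGULAR = "regular"


def max_wrap_hits(circle_length: int, read_length: int, k: int) -> int:
    """Largest possible N_h of a read wrapping a circle of annotated
    sequence: k-mer windows spanning the back-splice junction are not
    in the table, so each junction crossing costs up to k-1 windows."""
    n_windows = read_length - k + 1
    last_linear = circle_length - k  # largest in-table window offset
    best = 0
    for s in range(circle_length):
        hits = sum(1 for o in range(n_windows) if (s + o) % circle_length <= last_linear)
        best = max(best, hits)
    return best


def self_circle_detectable(exon_length: int, config: Config) -> bool:
    """Whether a self-circular exon of this length can ever pass the
    filtering rules.

    Exons at least read-length long are called through the condensed
    E-then-S tag path.  Shorter exons must be short-case (<= L_em) and
    a wrapping read must be able to reach the minimum hitting number
    L_e - K + 5; near the read length this is impossible because every
    read crosses the junction and forfeits k-1 windows per crossing.
    """
    if exon_length >= config.read_length:
        return True
    if exon_length > config.max_short_exon:
        return False
    if exon_length < config.k:
        return False
    needed = exon_length - config.k + 5
    return max_wrap_hits(exon_length, config.read_length, config.k) >= needed


class CondensedTag(NamedTuple):
    exon_index: int
    tag: str
    count: int


@dataclass(frozen=True)
class CircCandidate:
    """A called back-spliced junction (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    case_type: str
    support: int = 1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"junction start {self.start} must be < end {self.end}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


def min_hit_threshold(best: HittingStatus, config: Config) -> int:
    """Minimum hitting number N_hm for filtering procedure one."""
    total = best.total_hit_exon_len
    if total <= config.max_short_exon:
        return total - config.k + 5
    return math.floor(config.boundary_len * 1.2)


def passes_min_hits(best: HittingStatus, config: Config) -> bool:
    """Filtering procedure one: a best hitting case is discarded only
    when its N_h is strictly smaller than N_hm."""
    return best.n_h >= min_hit_threshold(best, config)


def classify_case(best: HittingStatus, config: Config) -> tuple[str, list[int]] | None:
    """Split into self (one hit exon) vs regular (exactly two after
    skipping exons hit at most ``min_exon_hits`` times); anything else
    is rejected."""
    counts = best.exon_hit_counts
    if len(counts) == 1:
        return SELF, list(counts)
    kept = [e for e, c in counts.items() if c > config.min_exon_hits]
    if len(kept) == 2:
        return REGULAR, kept
    return None


_FLIP = {TAG_START: TAG_END, TAG_END: TAG_START}


def events_transcript_order(events: list[TagEvent], strand: str) -> list[TagEvent]:
    """Events in transcript (5'->3') scanning order.

    The table indexes the genome-forward sequence with genomic part
    tags, so a read from a "−" transcript matches in its reverse
    complement; reversing the event list and swapping S/E restores the
    transcript's own reading direction.
    """
    if strand == "+":
        return events
    return [
        TagEvent(ev.exon_index, _FLIP[ev.part_tag], ev.read_offset)
        for ev in reversed(events)
    ]


def condense_tags(
    events: list[TagEvent], case_type: str, config: Config | None = None
) -> list[CondensedTag]:
    """Condense the ordered tag stream into per-exon tag runs.

    Consecutive same-tag hits in one exon become a single run S(n) or
    E(n).  Runs supported by at most ``min_exon_hits`` k-mers inside an
    exon that also carries the other tag are dropped as random hits
    (e.g. S(1),E(10) condenses to E(10)); adjacent same-tag runs then
    merge.  In the regular case an exon still carrying S then E is
    condensed to E if it is the first exon and S if the second — the
    pattern left by a read that covers that exon completely.
    """
    config = config or Config()
    runs: list[CondensedTag] = []
    for ev in events:
        if runs and runs[-1].exon_index == ev.exon_index and runs[-1].tag == ev.part_tag:
            runs[-1] = runs[-1]._replace(count=runs[-1].count + 1)
        else:
            runs.append(CondensedTag(ev.exon_index, ev.part_tag, 1))

    def _merge_adjacent(seq: list[CondensedTag]) -> list[CondensedTag]:
        out: list[CondensedTag] = []
        for run in seq:
            if out and out[-1].exon_index == run.exon_index and out[-1].tag == run.tag:
                out[-1] = out[-1]._replace(count=out[-1].count + run.count)
            else:
                out.append(run)
        return out

    # drop small noise runs, but only in exons where both tags occur
    mixed = {
        e for e in {r.exon_index for r in runs}
        if len({r.tag for r in runs if r.exon_index == e}) > 1
    }
    kept = [
        r for r in runs
        if r.exon_index not in mixed or r.count > config.min_exon_hits
    ]
    kept = _merge_adjacent(kept)

    if case_type == REGULAR:
        exon_order: list[int] = []
        for run in kept:
            if run.exon_index not in exon_order:
                exon_order.append(run.exon_index)
        condensed: list[CondensedTag] = []
        for run in kept:
            condensed.append(run)
            # collapse an S,E pair within one exon: first exon keeps E,
            # second exon keeps S
            if (
                len(condensed) >= 2
                and condensed[-2].exon_index == run.exon_index
                and condensed[-2].tag == TAG_START
                and run.tag == TAG_END
            ):
                rank = exon_order.index(run.exon_index)
                winner = TAG_END if rank == 0 else TAG_START
                keep = run if winner == TAG_END else condensed[-2]
                condensed[-2:] = [keep]
        kept = _merge_adjacent(condensed)
    return kept


def _transcript_sense_signals(head: ExonRecord, tail: ExonRecord) -> bool:
    """Donor at the head exon's transcript 3' end and acceptor at the
    tail exon's transcript 5' start, expressed via the genome-coordinate
    flags."""
    if head.strand == "+":
        return head.tail_signal and tail.head_signal
    return head.head_signal and tail.tail_signal


def call_self(
    best: BestHitCase,
    exon: ExonRecord,
    config: Config,
    catalog: AnnotationCatalog,
) -> CircCandidate | None:
    """Call a self-circular RNA (one exon circularised onto itself).

    Requires splice signals on both sides of the exon.  An exon shorter
    than the read must be covered at least L_e - K + 1 times.  Exons no
    longer than L_em are direct candidates (the read wraps the whole
    exon); longer exons must show condensed tags E then S — the
    junction read runs off the exon end and re-enters at its start.
    """
    if not (exon.head_signal and exon.tail_signal):
        return None
    if exon.length < config.read_length and best.status.n_h < exon.length - config.k + 1:
        return None
    if exon.length > config.max_short_exon:
        events = events_transcript_order(best.status.events, exon.strand)
        condensed = condense_tags(events, SELF, config)
        if len(condensed) != 2 or [c.tag for c in condensed] != [TAG_END, TAG_START]:
            return None
    chrom = catalog.chromosomes[exon.chrom_index]
    return CircCandidate(
        chrom=chrom, start=exon.start, end=exon.end,
        strand=exon.strand, case_type=SELF,
    )


def call_regular(
    best: BestHitCase,
    kept_exons: list[int],
    config: Config,
    catalog: AnnotationCatalog,
) -> CircCandidate | None:
    """Call a regular-circular RNA joining two exons of one transcript.

    In transcript scanning order the condensed tags must be exactly one
    per exon, arranged E then S, with the exon index decreasing at the
    breakpoint on "+" (head exon = larger index) and increasing on "−"
    (head exon = smaller index); a monotone index sequence is a linear
    read and is dropped.  The head exon needs the donor signal at its
    transcript end and the tail exon the acceptor at its transcript
    start.  The junction spans from the genomically left exon's start
    to the right exon's end.
    """
    ci, gi, ti = best.status.transcript_key
    strand = catalog.gene(ci, gi).strand
    events = [
        ev for ev in events_transcript_order(best.status.events, strand)
        if ev.exon_index in kept_exons
    ]
    condensed = condense_tags(events, REGULAR, config)
    if len(condensed) != 2:
        return None
    first, second = condensed
    if first.exon_index == second.exon_index:
        return None
    if (first.tag, second.tag) != (TAG_END, TAG_START):
        return None
    if strand == "+":
        if not first.exon_index > second.exon_index:  # must decrease
            return None
        head_idx, tail_idx = first.exon_index, second.exon_index
    else:
        if not first.exon_index < second.exon_index:  # must increase
            return None
        head_idx, tail_idx = first.exon_index, second.exon_index
    head = catalog.exon(ci, gi, ti, head_idx)
    tail = catalog.exon(ci, gi, ti, tail_idx)
    if not _transcript_sense_signals(head, tail):
        return None
    left, right = (tail, head) if strand == "+" else (head, tail)
    return CircCandidate(
        chrom=catalog.chromosomes[ci],
        start=left.start,
        end=right.end,
        strand=strand,
        case_type=REGULAR,
    )


def call_candidate(
    best: BestHitCase, config: Config, catalog: AnnotationCatalog
) -> CircCandidate | None:
    """Run both filtering procedures and the calling rules on one best
    hitting case; the per-read back half of the pipeline."""
    if best.status.n_h < min_hit_threshold(best.status, config):
        return None
    classified = classify_case(best.status, config)
    if classified is None:
        return None
    case_type, exons = classified
    ci, gi, ti = best.status.transcript_key
    if case_type == SELF:
        exon = catalog.exon(ci, gi, ti, exons[0])
        return call_self(best, exon, config, catalog)
    return call_regular(best, exons, config, catalog)


def refine(
    candidates: Iterable[CircCandidate], config: Config | None = None
) -> list[CircCandidate]:
    """Group identical junctions, count supporting reads, and keep
    those with support below ``max_support`` (the default sentinel
    keeps everything).  Self and regular calls at identical coordinates
    merge; the merged case type is "self" if any contributing read was.
    """
    config = config or Config()
    grouped: dict[tuple[str, int, int, str], list[CircCandidate]] = {}
    for cand in candidates:
        grouped.setdefault(cand.key, []).append(cand)
    out: list[CircCandidate] = []
    for (chrom, start, end, strand), group in grouped.items():
        support = len(group)
        if support >= config.max_support:
            continue
        case_type = SELF if any(c.case_type == SELF for c in group) else REGULAR
        out.append(
            CircCandidate(chrom=chrom, start=start, end=end, strand=strand,
                          case_type=case_type, support=support)
        )
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    return out


def write_calls(candidates: Iterable[CircCandidate], path: str | Path) -> None:
    """Write candidates as BED6 (name = case type, score = support)."""
    with open(path, "wt") as out:
        for cand in candidates:
            out.write(
                f"{cand.chrom}\t{cand.start}\t{cand.end}\t"
                f"{cand.case_type}\t{cand.support}\t{cand.strand}\n"
            )


def read_calls(path: str | Path) -> list[CircCandidate]:
    out: list[CircCandidate] = []
    with open(path, "rt") as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                CircCandidate(chrom=chrom, start=int(start), end=int(end),
                              strand=strand, case_type=name, support=int(score))
            )
    return out
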