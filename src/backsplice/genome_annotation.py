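"""Reference genome and transcript annotation handling.

Reads a FASTA genome and a GTF annotation into an indexed catalog
(chromosome -> gene -> transcript -> exon) and computes per-exon
back-splice signal eligibility from the intron-flanking dinucleotides.

Coordinates are 0-based half-open internally; GTF input/output is
1-based inclusive.  Splice-signal placement is on the intron side:
for a "+" exon the acceptor dinucleotide "AG" sits immediately left
of the exon start and the donor "GT" immediately right of the exon
end; on "−" the genome-forward dinucleotides are "AC" (left) and
"CT" (right), the reverse complement of the canonical GT–AG intron
(a "−" intron reads CT...AC in genome-forward coordinates).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExonRecord",
    "Transcript",
    "Gene",
    "AnnotationCatalog",
    "read_fasta",
    "read_gtf",
    "write_gtf",
    "splice_signal_flags",
    "compute_signals",
    "eligible_exons",
    "reverse_complement",
]


class FormatError(ValueError):
    """Raised for malformed FASTA/GTF input."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# every non-ACGT letter (IUPAC ambiguity codes, lowercase handled before) -> N
_CLEAN = str.maketrans(
    {c: "N" for c in "BDEFHIJKLMOPQRSUVWXYZ"}
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA file into ``{name: sequence}``.

    Sequences are uppercased and any letter outside A/C/G/T becomes N.
    Record order is preserved (plain dicts keep insertion order).
    """
    with _open_text(path) as handle:
        # SeqIO silently skips leading junk; validate the header ourselves.
        lineno = 0
        for line in handle:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header '>'"
                    )
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
        handle.seek(0)
        genome: dict[str, str] = {}
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in genome:
                raise FormatError(f"{path}: duplicate sequence name {record.id!r}")
            seq = str(record.seq).upper().translate(_CLEAN)
            if not seq:
                raise FormatError(f"{path}: empty sequence for {record.id!r}")
            genome[record.id] = seq
    return genome


@dataclass(frozen=True)
class ExonRecord:
    """One exon of one transcript, addressable by four small indices.

    ``exon_index`` is the rank within the transcript in ascending
    genomic-coordinate order (0-based), for both strands.
    """

    chrom_index: int
    gene_index: int
    transcript_index: int
    exon_index: int
    start: int  # 0-based
    end: int    # half-open
    strand: str
    head_signal: bool = False
    tail_signal: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon start {self.start} must be < end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.chrom_index, self.gene_index, self.transcript_index, self.exon_index)


@dataclass
class Transcript:
    transcript_id: str
    exons: list[ExonRecord] = field(default_factory=list)


@dataclass
class Gene:
    gene_id: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class AnnotationCatalog:
    """Indexed hierarchy chromosomes -> genes -> transcripts -> exons."""

    chromosomes: list[str] = field(default_factory=list)
    genes_by_chrom: list[list[Gene]] = field(default_factory=list)

    def add_chromosome(self, name: str) -> int:
        self.chromosomes.append(name)
        self.genes_by_chrom.append([])
        return len(self.chromosomes) - 1

    def chrom_index(self, name: str) -> int:
        return self.chromosomes.index(name)

    def gene(self, chrom_index: int, gene_index: int) -> Gene:
        return self.genes_by_chrom[chrom_index][gene_index]

    def transcript(self, chrom_index: int, gene_index: int, transcript_index: int) -> Transcript:
        return self.genes_by_chrom[chrom_index][gene_index].transcripts[transcript_index]

    def exon(self, chrom_index: int, gene_index: int,
             transcript_index: int, exon_index: int) -> ExonRecord:
        return (
            self.genes_by_chrom[chrom_index][gene_index]
            .transcripts[transcript_index]
            .exons[exon_index]
        )

    def iter_exons(self) -> Iterator[ExonRecord]:
        for genes in self.genes_by_chrom:
            for gene in genes:
                for tx in gene.transcripts:
                    yield from tx.exons

    @property
    def n_exons(self) -> int:
        return sum(1 for _ in self.iter_exons())


def _match_chrom(name: str, genome: dict[str, str]) -> str | None:
    """Exact match, then the common chr-prefix dialect fix-up."""
    if name in genome:
        return name
    if name.startswith("chr") and name[3:] in genome:
        return name[3:]
    if not name.startswith("chr") and "chr" + name in genome:
        return "chr" + name
    return None


def read_gtf(path: str | Path, genome: dict[str, str]) -> AnnotationCatalog:
    """Parse GTF exon lines into an :class:`AnnotationCatalog`.

    Gene/transcript feature lines are optional; the hierarchy is built
    from exon-line ``gene_id``/``transcript_id`` attributes.  Exons are
    grouped per transcript, sorted ascending by start and re-indexed.
    Chromosomes absent from the genome are dropped with a warning.
    """
    # raw[(chrom, gene_id)][transcript_id] -> list of (start, end, strand)
    raw: dict[str, dict[str, dict[str, list[tuple[int, int, str]]]]] = {}
    dropped: set[str] = set()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # pragma: no cover - gffutils detail
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            chrom = _match_chrom(feat.seqid, genome)
            if chrom is None:
                dropped.add(feat.seqid)
                continue
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: exon lacks {exc} attribute"
                ) from exc
            if feat.end < feat.start:
                raise FormatError(
                    f"{path}: line {lineno}: end {feat.end} < start {feat.start}"
                )
            start, end = feat.start - 1, feat.end  # GTF 1-based inclusive
            if end > len(genome[chrom]):
                raise FormatError(
                    f"{path}: line {lineno}: exon end {end} beyond "
                    f"{chrom} length {len(genome[chrom])}"
                )
            raw.setdefault(chrom, {}).setdefault(gene_id, {}).setdefault(
                transcript_id, []
            ).append((start, end, feat.strand))
    for name in sorted(dropped):
        log.warning("GTF chromosome %r absent from genome; records dropped", name)

    catalog = AnnotationCatalog()
    for chrom in genome:  # chromosome order follows the genome
        if chrom not in raw:
            catalog.add_chromosome(chrom)
            continue
        ci = catalog.add_chromosome(chrom)
        for gi, (gene_id, txs) in enumerate(raw[chrom].items()):
            strands = {s for tx in txs.values() for _, _, s in tx}
            strand = sorted(strands)[0]
            gene = Gene(gene_id=gene_id, strand=strand)
            for ti, (transcript_id, exon_spans) in enumerate(txs.items()):
                tx = Transcript(transcript_id=transcript_id)
                for ei, (start, end, estrand) in enumerate(
                    sorted(exon_spans, key=lambda t: (t[0], t[1]))
                ):
                    tx.exons.append(
                        ExonRecord(
                            chrom_index=ci,
                            gene_index=gi,
                            transcript_index=ti,
                            exon_index=ei,
                            start=start,
                            end=end,
                            strand=estrand,
                        )
                    )
                gene.transcripts.append(tx)
            catalog.genes_by_chrom[ci].append(gene)
    return catalog


def write_gtf(catalog: AnnotationCatalog, path: str | Path) -> None:
    """Emit exon lines (GTF2.2, 1-based inclusive), deterministic order."""
    with open(path, "wt") as out:
        for ci, chrom in enumerate(catalog.chromosomes):
            for gene in catalog.genes_by_chrom[ci]:
                for tx in gene.transcripts:
                    for exon in tx.exons:
                        attrs = (
                            f'gene_id "{gene.gene_id}"; '
                            f'transcript_id "{tx.transcript_id}";'
                        )
                        out.write(
                            f"{chrom}\tbacksplice\texon\t{exon.start + 1}\t"
                            f"{exon.end}\t.\t{exon.strand}\t.\t{attrs}\n"
                        )


def splice_signal_flags(exon: ExonRecord, sequence: str) -> tuple[bool, bool]:
    """Back-splice signal eligibility of one exon.

    Returns ``(head_signal, tail_signal)``: whether the intron-side
    dinucleotide flanking the exon start (head) / end (tail) matches the
    canonical splice signal for the exon's strand.  Chromosome-edge
    flanks are False.
    """
    if exon.strand == "+":
        left_want, right_want = "AG", "GT"
    else:
        left_want, right_want = "AC", "CT"
    head = exon.start >= 2 and sequence[exon.start - 2 : exon.start] == left_want
    tail = exon.end + 2 <= len(sequence) and sequence[exon.end : exon.end + 2] == right_want
    return head, tail


def compute_signals(catalog: AnnotationCatalog, genome: dict[str, str]) -> None:
    """Fill ``head_signal``/``tail_signal`` on every exon in place."""
    for ci, chrom in enumerate(catalog.chromosomes):
        seq = genome[chrom]
        for gene in catalog.genes_by_chrom[ci]:
            for tx in gene.transcripts:
                for i, exon in enumerate(tx.exons):
                    head, tail = splice_signal_flags(exon, seq)
                    if (head, tail) != (exon.head_signal, exon.tail_signal):
                        tx.exons[i] = ExonRecord(
                            chrom_index=exon.chrom_index,
                            gene_index=exon.gene_index,
                            transcript_index=exon.transcript_index,
                            exon_index=exon.exon_index,
                            start=exon.start,
                            end=exon.end,
                            strand=exon.strand,
                            head_signal=head,
                            tail_signal=tail,
                        )


def eligible_exons(catalog: AnnotationCatalog) -> list[ExonRecord]:
    """Exons carrying a back-splice signal in head or tail; only these
    are k-mer indexed."""
    return [e for e in catalog.iter_exons() if e.head_signal or e.tail_signal]
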