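"""Hand-rolled toy genome construction for controlled unit tests."""

from __future__ import annotations

import numpy as np

from backsplice.genome_annotation import (
    AnnotationCatalog,
    ExonRecord,
    Gene,
    Transcript,
    compute_signals,
)
from backsplice.read_scanner import HittingStatus, TagEvent


def build_toy(
    genes: list[tuple[str, list[int | str], list[int]]],
    pad: int = 60,
    seed: int = 11,
    chrom: str = "chrT",
) -> tuple[dict[str, str], AnnotationCatalog]:
    """Assemble one chromosome holding the given gene models.

    ``genes`` entries are (strand, exons, intron_lengths); an exon given
    as an int gets a random sequence of that length, a str is used
    verbatim.  Introns carry the canonical splice dinucleotides for the
    gene's strand; gene outer flanks are "CC" (no signal either strand).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def rand(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    seq_parts: list[str] = []
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        seq_parts.append(s)
        pos += len(s)

    catalog = AnnotationCatalog()
    ci = catalog.add_chromosome(chrom)
    for gi, (strand, exon_specs, intron_lens) in enumerate(genes):
        assert len(intron_lens) == len(exon_specs) - 1
        emit(rand(pad - 2) + "CC")
        gene = Gene(gene_id=f"TG{gi}", strand=strand)
        tx = Transcript(transcript_id=f"TT{gi}")
        left, right = ("GT", "AG") if strand == "+" else ("CT", "AC")
        for ei, spec in enumerate(exon_specs):
            exon_seq = spec if isinstance(spec, str) else rand(spec)
            start = pos
            emit(exon_seq)
            tx.exons.append(
                ExonRecord(chrom_index=ci, gene_index=gi, transcript_index=0,
                           exon_index=ei, start=start, end=pos, strand=strand)
            )
            if ei < len(exon_specs) - 1:
                ilen = intron_lens[ei]
                assert ilen >= 4
                emit(left + rand(ilen - 4) + right)
        emit("CC")
        gene.transcripts.append(tx)
        catalog.genes_by_chrom[ci].append(gene)
    emit(rand(pad))
    genome = {chrom: "".join(seq_parts)}
    compute_signals(catalog, genome)
    return genome, catalog


def make_status(
    n_h: int,
    total_len: int,
    exon_index: int = 0,
    key: tuple[int, int, int] = (0, 0, 0),
) -> HittingStatus:
    """A hitting status with a prescribed support and hit-exon length."""
    status = HittingStatus(transcript_key=key)
    status.events = [TagEvent(exon_index, "S", i) for i in range(n_h)]
    status.hit_exon_lengths = {exon_index: total_len}
    return status


def events_from(spec: list[tuple[int, str, int]]) -> list[TagEvent]:
    """Expand [(exon_index, tag, run_length), ...] into a read-ordered
    event list."""
    out: list[TagEvent] = []
    offset = 0
    for exon_index, tag, run in spec:
        for _ in range(run):
            out.append(TagEvent(exon_index, tag, offset))
            offset += 1
    return out
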