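"""Synthetic genomes, annotations and back-splice reads with known truth.

The generator emulates a small multi-gene genome: uniform-random
A/C/G/T background, non-overlapping genes on either strand, each a
single transcript of several exons separated by introns that carry the
canonical splice signal on the gene's strand (genome-forward GT...AG
for "+", AC...CT for "−"), so every internal exon is back-splice
eligible on both sides.  The two bases flanking a gene's outer exons
are fixed to "CC" so terminal exons carry no spurious signal.

A fraction of genes is circularised: either one internal exon joined
onto itself (self case) or an exon span whose last exon's end joins
back to the first exon's start (regular case).  Reads are sampled
uniformly from spliced linear transcripts and from the circularised
sequences (with wrap-around, so junction-spanning reads are
guaranteed), from either strand, with per-base substitution errors.

All randomness derives from ``SimParams.seed``; fixed seed gives
byte-identical FASTA/GTF/FASTQ/BED outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import yaml

from .genome_annotation import (
    AnnotationCatalog,
    ExonRecord,
    Gene,
    Transcript,
    compute_signals,
    reverse_complement,
    write_gtf,
)
from .junction_caller import REGULAR, SELF, self_circle_detectable
from .kmer_index import Config
from .read_scanner import ReadRecord

log = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "SizingError",
    "TruthJunction",
    "SimulatedDataset",
    "simulate_genome",
    "plant_circrnas",
    "simulate_reads",
    "simulate_dataset",
    "write_truth",
    "read_truth",
    "write_fasta",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


class SizingError(ValueError):
    """Genes do not fit in the requested genome length."""


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulator.

    Defaults describe the package's standard smoke dataset: a ~100 kb
    genome over two chromosomes holding 30 four-to-six-exon genes,
    two thirds of them carrying one planted circle, sequenced at 20X
    circular and 50X linear coverage with 101 bp error-free reads.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 2
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (60, 180)
    intron_length: tuple[int, int] = (60, 300)
    fraction_circular: float = 2 / 3
    circ_coverage: float = 20.0
    linear_coverage: float = 50.0
    read_length: int = 101
    error_rate: float = 0.0
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0 or self.n_genes < 0:
            raise ValueError("sizes must be positive")
        if not 0 <= self.fraction_circular <= 1:
            raise ValueError("fraction_circular must be in [0, 1]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if self.circ_coverage < 0 or self.linear_coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.exon_length[0] < 16:
            raise ValueError("exons must be at least k-mer sized")
        if self.intron_length[0] < 4:
            raise ValueError("introns must hold both splice dinucleotides")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "SimParams":
        known = set(cls.__dataclass_fields__)
        bad = set(mapping) - known
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
        data = dict(mapping)
        for key in ("exons_per_gene", "exon_length", "intron_length"):
            if key in data and isinstance(data[key], (list, tuple)):
                data[key] = tuple(data[key])  # type: ignore[assignment]
        return cls(**data)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path) as handle:
            return cls.from_mapping(yaml.safe_load(handle) or {})


class TruthJunction(NamedTuple):
    """A planted back-splice junction (BED-style half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    case_type: str  # self | regular
    coverage: float
    chrom_index: int = 0
    gene_index: int = 0
    exon_span: tuple[int, int] = (0, 0)  # (first, last) exon index, inclusive


@dataclass
class SimulatedDataset:
    params: SimParams
    genome: dict[str, str]
    catalog: AnnotationCatalog
    truth: list[TruthJunction]
    reads: list[ReadRecord]


def _rng(params: SimParams, stage: int) -> np.random.Generator:
    # distinct, order-independent stream per stage so the standalone ops
    # reproduce the pipeline exactly
    return np.random.default_rng([params.seed, stage])


def simulate_genome(params: SimParams) -> tuple[dict[str, str], AnnotationCatalog]:
    """Random background genome with planted gene models; returns the
    genome and a catalog with splice-signal flags computed."""
    rng = _rng(params, 0)
    chrom_len = params.genome_length // params.n_chromosomes
    names = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    seqs = {
        name: rng.choice(_BASES, size=chrom_len) for name in names
    }
    catalog = AnnotationCatalog()
    for name in names:
        catalog.add_chromosome(name)

    # round-robin genes over chromosomes, laid out left to right
    cursors = {name: 0 for name in names}
    for g in range(params.n_genes):
        ci = g % params.n_chromosomes
        name = names[ci]
        seq = seqs[name]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        exon_lens = rng.integers(params.exon_length[0], params.exon_length[1] + 1, n_exons)
        intron_lens = rng.integers(
            params.intron_length[0], params.intron_length[1] + 1, n_exons - 1
        )
        gap = int(rng.integers(50, 200))
        start = cursors[name] + gap
        span = int(exon_lens.sum() + intron_lens.sum())
        if start + span + 2 > chrom_len:
            raise SizingError(
                f"gene {g} does not fit on {name}: need {start + span + 2} bp, "
                f"chromosome holds {chrom_len}"
            )
        gi = len(catalog.genes_by_chrom[ci])
        gene = Gene(gene_id=f"G{g:03d}", strand=strand)
        tx = Transcript(transcript_id=f"T{g:03d}")
        pos = start
        exons: list[tuple[int, int]] = []
        for e in range(n_exons):
            exons.append((pos, pos + int(exon_lens[e])))
            pos += int(exon_lens[e])
            if e < n_exons - 1:
                left, right = ("GT", "AG") if strand == "+" else ("CT", "AC")
                seq[pos] = left[0]
                seq[pos + 1] = left[1]
                seq[pos + int(intron_lens[e]) - 2] = right[0]
                seq[pos + int(intron_lens[e]) - 1] = right[1]
                pos += int(intron_lens[e])
        # neutral outer flanks: no signal on either strand
        seq[start - 2 : start] = ["C", "C"]
        seq[pos : pos + 2] = ["C", "C"]
        for ei, (es, ee) in enumerate(exons):
            tx.exons.append(
                ExonRecord(chrom_index=ci, gene_index=gi, transcript_index=0,
                           exon_index=ei, start=es, end=ee, strand=strand)
            )
        gene.transcripts.append(tx)
        catalog.genes_by_chrom[ci].append(gene)
        cursors[name] = pos + 2

    genome = {name: "".join(seqs[name]) for name in names}
    compute_signals(catalog, genome)
    return genome, catalog


def plant_circrnas(catalog: AnnotationCatalog, params: SimParams) -> list[TruthJunction]:
    """Choose circularised genes and record the ground-truth junctions.

    Self case: one internal exon, junction (exon.start, exon.end);
    only exons whose length can pass the self-circular support rules
    are used, so every planted junction is detectable in principle.
    Regular case: an exon span a..b with 1 <= a < b <= n-2, junction
    (exon_a.start, exon_b.end) — exon boundaries that carry the donor
    and acceptor signals by construction on both strands.
    """
    rng = _rng(params, 1)
    detector = Config(read_length=params.read_length)
    genes = [
        (ci, gi, gene)
        for ci, chrom_genes in enumerate(catalog.genes_by_chrom)
        for gi, gene in enumerate(chrom_genes)
    ]
    n_circ = int(round(params.fraction_circular * len(genes)))
    if n_circ == 0:
        return []
    chosen = rng.choice(len(genes), size=n_circ, replace=False)
    truth: list[TruthJunction] = []
    for idx in sorted(chosen):
        ci, gi, gene = genes[idx]
        exons = gene.transcripts[0].exons
        n = len(exons)
        internal = [
            e for e in exons[1:-1] if self_circle_detectable(e.length, detector)
        ]
        can_regular = n >= 4
        if not internal and not can_regular:
            log.warning("gene %s has no circularisable exon; skipped", gene.gene_id)
            continue
        if internal and can_regular:
            case = SELF if rng.random() < 0.5 else REGULAR
        else:
            case = SELF if internal else REGULAR
        if case == SELF:
            exon = internal[int(rng.integers(len(internal)))]
            span = (exon.exon_index, exon.exon_index)
            start, end = exon.start, exon.end
        else:
            a = int(rng.integers(1, n - 2))
            b = int(rng.integers(a + 1, n - 1))
            span = (a, b)
            start, end = exons[a].start, exons[b].end
        truth.append(
            TruthJunction(
                chrom=catalog.chromosomes[ci], start=start, end=end,
                strand=gene.strand, case_type=case, coverage=params.circ_coverage,
                chrom_index=ci, gene_index=gi, exon_span=span,
            )
        )
    return truth


def _spliced(catalog: AnnotationCatalog, genome: dict[str, str],
             ci: int, gi: int, exon_span: tuple[int, int] | None = None) -> str:
    gene = catalog.gene(ci, gi)
    exons = gene.transcripts[0].exons
    if exon_span is not None:
        exons = exons[exon_span[0] : exon_span[1] + 1]
    seq = "".join(genome[catalog.chromosomes[ci]][e.start : e.end] for e in exons)
    return reverse_complement(seq) if gene.strand == "-" else seq


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        others = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([others[int(rng.integers(3))]])
    return arr.tobytes().decode()


def simulate_reads(
    genome: dict[str, str],
    catalog: AnnotationCatalog,
    truth: list[TruthJunction],
    params: SimParams,
) -> list[ReadRecord]:
    """Sample reads from linear transcripts and circularised sequences.

    Per transcript the read count is round(coverage * length / L_R).
    Circular fragments wrap around the back-splice junction; linear
    fragments stay inside the transcript.  Each fragment is emitted
    from either strand with equal probability, then substitution errors
    are applied.
    """
    rng = _rng(params, 2)
    lr = params.read_length
    reads: list[ReadRecord] = []

    def emit(tag: str, seq: str, i: int) -> None:
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        seq = _mutate(seq, rng, params.error_rate)
        if params.paired:
            reads.append(ReadRecord(id=f"{tag}|{i}/1", sequence=seq, mate=1))
            reads.append(
                ReadRecord(id=f"{tag}|{i}/2", sequence=reverse_complement(seq), mate=2)
            )
        else:
            reads.append(ReadRecord(id=f"{tag}|{i}", sequence=seq))

    for ci, chrom_genes in enumerate(catalog.genes_by_chrom):
        for gi, gene in enumerate(chrom_genes):
            tseq = _spliced(catalog, genome, ci, gi)
            if len(tseq) < lr or params.linear_coverage == 0:
                continue
            n = int(round(params.linear_coverage * len(tseq) / lr))
            for i in range(n):
                start = int(rng.integers(0, len(tseq) - lr + 1))
                emit(f"lin|{gene.gene_id}", tseq[start : start + lr], i)

    for tj in truth:
        circ = _spliced(catalog, genome, tj.chrom_index, tj.gene_index, tj.exon_span)
        if not circ or params.circ_coverage == 0:
            continue
        n = max(1, int(round(params.circ_coverage * len(circ) / lr)))
        tiled = circ * (lr // len(circ) + 2)
        gene_id = catalog.gene(tj.chrom_index, tj.gene_index).gene_id
        for i in range(n):
            start = int(rng.integers(0, len(circ)))
            emit(f"circ|{gene_id}|{tj.case_type}", tiled[start : start + lr], i)
    return reads


def simulate_dataset(params: SimParams, out_dir: str | Path | None = None) -> SimulatedDataset:
    """Run the full generator; optionally write FASTA/GTF/FASTQ/BED."""
    genome, catalog = simulate_genome(params)
    truth = plant_circrnas(catalog, params)
    reads = simulate_reads(genome, catalog, truth, params)
    dataset = SimulatedDataset(
        params=params, genome=genome, catalog=catalog, truth=truth, reads=reads
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        write_gtf(catalog, out / "annotation.gtf")
        write_fastq(reads, out / "reads.fastq")
        write_truth(truth, out / "truth.bed")
    return dataset


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "wt") as out:
        for read in reads:
            out.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_truth(truth: list[TruthJunction], path: str | Path) -> None:
    """BED6 with the case type in the name column and planted coverage
    as the score."""
    with open(path, "wt") as out:
        for tj in truth:
            out.write(
                f"{tj.chrom}\t{tj.start}\t{tj.end}\t{tj.case_type}\t"
                f"{int(tj.coverage)}\t{tj.strand}\n"
            )


def read_truth(path: str | Path) -> list[TruthJunction]:
    out: list[TruthJunction] = []
    with open(path, "rt") as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(
                TruthJunction(chrom=chrom, start=int(start), end=int(end),
                              strand=strand, case_type=name, coverage=float(score))
            )
    return out
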