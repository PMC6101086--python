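"""Exon-boundary k-mer table.

K-mers are packed 2 bits per base (A=0, C=1, G=2, T=3) into a 32-bit
word, which caps k at 15.  For each eligible exon, only the k-mers near
the exon boundaries are indexed: the boundary region length is

    L_B = floor(L_R * R_c)

where L_R is the read length and R_c the per-boundary coverage fraction
(default 0.30, so the two boundaries cover 60% of a read, more than
half).  Exons not longer than

    L_em = 2 * L_B + 2 * K - 1

are short enough that the two boundary windows meet, and the whole exon
is indexed, k-mers in the first half tagged "S" and in the second half
"E".  Longer exons contribute exactly L_B windows per side, head
windows tagged "S" and tail windows "E".  Each indexed k-mer maps to a
list of compact 8-byte annotation-position records.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml

from .genome_annotation import AnnotationCatalog, ExonRecord, compute_signals, eligible_exons

__all__ = [
    "Config",
    "ConfigError",
    "AnnotationPosition",
    "KmerTable",
    "encode_kmer",
    "decode_kmer",
    "encode_all",
    "boundary_length",
    "max_short_exon_length",
    "extract_exon_kmers",
    "build_table",
    "DEFAULT_MAX_SUPPORT",
    "TAG_START",
    "TAG_END",
]

TAG_START = "S"
TAG_END = "E"

#: sentinel meaning "keep every candidate however deep the support"
DEFAULT_MAX_SUPPORT = 2**31

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


class ConfigError(ValueError):
    """Invalid detector configuration."""


@dataclass(frozen=True)
class Config:
    """Detector parameters.

    k               k-mer length in bp (2 bits/base in a 32-bit word => k <= 15)
    read_length     expected read length L_R in bp
    r_c             boundary coverage fraction of read length per side
    min_best_hits   minimum supporting k-mers N_h for a retained best hit case
    best_hit_margin the "clearly more support" margin in the best-case rule
    min_exon_hits   per-exon hit count must exceed this in regular-case filtering
    max_support     refinement keeps candidates with support < max_support
    tolerance       junction-matching tolerance in bp for evaluation
    """

    k: int = 15
    read_length: int = 101
    r_c: float = 0.30
    min_best_hits: int = 5
    best_hit_margin: int = 5
    min_exon_hits: int = 3
    max_support: int = DEFAULT_MAX_SUPPORT
    tolerance: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 15:
            raise ConfigError(f"k must be in [1, 15], got {self.k}")
        if not 0 < self.r_c < 0.5:
            raise ConfigError(f"r_c must be in (0, 0.5), got {self.r_c}")
        if self.read_length < self.k:
            raise ConfigError("read_length must be >= k")

    @property
    def boundary_len(self) -> int:
        return boundary_length(self)

    @property
    def max_short_exon(self) -> int:
        return max_short_exon_length(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "Config":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(mapping) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**mapping)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_mapping(data)


def boundary_length(config: Config) -> int:
    """L_B = floor(L_R * R_c) in bp."""
    return math.floor(config.read_length * config.r_c)


def max_short_exon_length(config: Config) -> int:
    """L_em = 2*L_B + 2*K - 1: the longest exon indexed in full."""
    return 2 * boundary_length(config) + 2 * config.k - 1


def encode_kmer(s: str, k: int | None = None) -> int | None:
    """Pack a k-mer into an integer, or None if it contains a non-ACGT
    letter (such k-mers are discarded).  If ``k`` is given, a k-mer of
    any other length is an argument error."""
    if k is not None and len(s) != k:
        raise ValueError(f"expected a {k}-mer, got {len(s)} letters")
    code = 0
    for ch in s:
        b = _BASE_CODE.get(ch)
        if b is None:
            return None
        code = (code << 2) | b
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_CODE_BASE[(code >> shift) & 3])
    return "".join(out)


def encode_all(seq: str, k: int) -> list[int]:
    """Rolling 2-bit codes for every k-mer window of ``seq``.

    Returns one entry per window offset; windows containing an invalid
    letter are -1.
    """
    n = len(seq)
    if n < k:
        return []
    mask = (1 << (2 * k)) - 1
    out: list[int] = []
    code = 0
    valid_run = 0
    for i, ch in enumerate(seq):
        b = _BASE_CODE.get(ch)
        if b is None:
            code = 0
            valid_run = 0
        else:
            code = ((code << 2) | b) & mask
            valid_run += 1
        if i >= k - 1:
            out.append(code if valid_run >= k else -1)
    return out


class AnnotationPosition(NamedTuple):
    """Compact record of where an indexed k-mer comes from.

    Serializes to exactly 8 bytes: chromosome index (1 byte), gene
    index (3 bytes), transcript index (2 bytes), exon index (15 bits)
    and the part tag (1 bit).
    """

    chrom_index: int
    gene_index: int
    transcript_index: int
    exon_index: int
    part_tag: str  # TAG_START | TAG_END

    RECORD_SIZE = 8

    def pack(self) -> bytes:
        if not 0 <= self.chrom_index < 1 << 8:
            raise ValueError("chrom_index out of range for 1 byte")
        if not 0 <= self.gene_index < 1 << 24:
            raise ValueError("gene_index out of range for 3 bytes")
        if not 0 <= self.transcript_index < 1 << 16:
            raise ValueError("transcript_index out of range for 2 bytes")
        if not 0 <= self.exon_index < 1 << 15:
            raise ValueError("exon_index out of range for 15 bits")
        tag_bit = 1 if self.part_tag == TAG_END else 0
        word = (
            (self.chrom_index << 56)
            | (self.gene_index << 32)
            | (self.transcript_index << 16)
            | (self.exon_index << 1)
            | tag_bit
        )
        return struct.pack(">Q", word)

    @classmethod
    def unpack(cls, data: bytes) -> "AnnotationPosition":
        (word,) = struct.unpack(">Q", data)
        return cls(
            chrom_index=(word >> 56) & 0xFF,
            gene_index=(word >> 32) & 0xFFFFFF,
            transcript_index=(word >> 16) & 0xFFFF,
            exon_index=(word >> 1) & 0x7FFF,
            part_tag=TAG_END if word & 1 else TAG_START,
        )


_TABLE_MAGIC = b"BSKT"
_TABLE_VERSION = 1


@dataclass
class KmerTable:
    """Per-chromosome map from encoded k-mer to annotation positions."""

    k: int
    per_chrom: dict[str, dict[int, list[AnnotationPosition]]] = field(default_factory=dict)
    _merged: dict[int, list[AnnotationPosition]] | None = field(
        default=None, repr=False, compare=False
    )

    def add(self, chrom: str, code: int, pos: AnnotationPosition) -> None:
        bucket = self.per_chrom.setdefault(chrom, {}).setdefault(code, [])
        if pos not in bucket:
            bucket.append(pos)
        self._merged = None

    def chrom_lookup(self, chrom: str, code: int) -> list[AnnotationPosition]:
        return self.per_chrom.get(chrom, {}).get(code, [])

    def lookup(self, code: int) -> list[AnnotationPosition]:
        """Positions of ``code`` across all chromosomes (absent -> [])."""
        if self._merged is None:
            merged: dict[int, list[AnnotationPosition]] = {}
            for chrom in self.per_chrom:
                for key, positions in self.per_chrom[chrom].items():
                    merged.setdefault(key, []).extend(positions)
            self._merged = merged
        return self._merged.get(code, [])

    def __contains__(self, code: int) -> bool:
        return bool(self.lookup(code))

    @property
    def n_kmers(self) -> int:
        return sum(len(t) for t in self.per_chrom.values())

    @classmethod
    def merge(cls, tables: Iterable["KmerTable"]) -> "KmerTable":
        """Combine per-chromosome tables built independently (the
        work-partitioning contract: per-chromosome build + merge equals
        a global build)."""
        tables = list(tables)
        if not tables:
            raise ValueError("no tables to merge")
        ks = {t.k for t in tables}
        if len(ks) != 1:
            raise ValueError(f"cannot merge tables with different k: {ks}")
        out = cls(k=ks.pop())
        for table in tables:
            for chrom, mapping in table.per_chrom.items():
                for code, positions in mapping.items():
                    for pos in positions:
                        out.add(chrom, code, pos)
        return out

    def dump(self, path: str | Path) -> None:
        """Versioned binary dump: header, then per-chromosome blocks."""
        with open(path, "wb") as out:
            out.write(_TABLE_MAGIC)
            out.write(struct.pack(">HBI", _TABLE_VERSION, self.k, len(self.per_chrom)))
            for chrom, mapping in self.per_chrom.items():
                name = chrom.encode()
                out.write(struct.pack(">H", len(name)))
                out.write(name)
                out.write(struct.pack(">I", len(mapping)))
                for code, positions in mapping.items():
                    out.write(struct.pack(">II", code, len(positions)))
                    for pos in positions:
                        out.write(pos.pack())

    @classmethod
    def load(cls, path: str | Path) -> "KmerTable":
        with open(path, "rb") as handle:
            if handle.read(4) != _TABLE_MAGIC:
                raise ValueError(f"{path}: not a k-mer table file")
            version, k, n_chroms = struct.unpack(">HBI", handle.read(7))
            if version != _TABLE_VERSION:
                raise ValueError(f"{path}: unsupported table version {version}")
            table = cls(k=k)
            for _ in range(n_chroms):
                (name_len,) = struct.unpack(">H", handle.read(2))
                chrom = handle.read(name_len).decode()
                (n_keys,) = struct.unpack(">I", handle.read(4))
                mapping: dict[int, list[AnnotationPosition]] = {}
                for _ in range(n_keys):
                    code, count = struct.unpack(">II", handle.read(8))
                    size = AnnotationPosition.RECORD_SIZE
                    mapping[code] = [
                        AnnotationPosition.unpack(handle.read(size))
                        for _ in range(count)
                    ]
                table.per_chrom[chrom] = mapping
        return table


def extract_exon_kmers(
    exon: ExonRecord, sequence: str, config: Config
) -> list[tuple[int, AnnotationPosition]]:
    """Indexed (code, position) pairs for one eligible exon.

    Short exons (L_e <= L_em) contribute every window, split S/E at the
    window-count midpoint (the odd middle window goes to "S").  Long
    exons contribute the L_B head windows as "S" and the L_B tail
    windows as "E"; windows never extend past the exon.  Windows with
    an N are skipped.
    """
    k = config.k
    length = exon.length
    if length < k:
        return []
    region = sequence[exon.start : exon.end]
    codes = encode_all(region, k)
    n_windows = length - k + 1

    offsets_tags: list[tuple[int, str]]
    if length <= config.max_short_exon:
        half = math.ceil(n_windows / 2)
        offsets_tags = [
            (o, TAG_START if o < half else TAG_END) for o in range(n_windows)
        ]
    else:
        lb = config.boundary_len
        head = [(o, TAG_START) for o in range(lb)]
        tail = [(o, TAG_END) for o in range(n_windows - lb, n_windows)]
        offsets_tags = head + tail

    out: list[tuple[int, AnnotationPosition]] = []
    for offset, tag in offsets_tags:
        code = codes[offset]
        if code < 0:
            continue
        out.append(
            (
                code,
                AnnotationPosition(
                    chrom_index=exon.chrom_index,
                    gene_index=exon.gene_index,
                    transcript_index=exon.transcript_index,
                    exon_index=exon.exon_index,
                    part_tag=tag,
                ),
            )
        )
    return out


def build_table(
    catalog: AnnotationCatalog,
    genome: dict[str, str],
    config: Config | None = None,
    chromosomes: Iterable[str] | None = None,
) -> KmerTable:
    """Build the exon-boundary k-mer table over all eligible exons.

    ``chromosomes`` restricts the build to a subset (per-chromosome
    work partitioning); tables built per chromosome and merged equal
    the global build.
    """
    config = config or Config()
    compute_signals(catalog, genome)
    wanted = set(chromosomes) if chromosomes is not None else None
    table = KmerTable(k=config.k)
    for exon in eligible_exons(catalog):
        chrom = catalog.chromosomes[exon.chrom_index]
        if wanted is not None and chrom not in wanted:
            continue
        for code, pos in extract_exon_kmers(exon, genome[chrom], config):
            table.add(chrom, code, pos)
    return table
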