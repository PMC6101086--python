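"""Brute-force string-matching oracles, independent of the package's
encoded k-mer table and rolling scanner.

The oracle enumerates every k-length window of every eligible exon by
string slicing and records its source and part tag; scanning a read is
then a plain dictionary lookup per window string.
"""

from __future__ import annotations

from backsplice.genome_annotation import AnnotationCatalog, eligible_exons
from backsplice.kmer_index import Config


def oracle_windows(
    catalog: AnnotationCatalog, genome: dict[str, str], config: Config
) -> dict[str, list[tuple[tuple[int, int, int, int], str]]]:
    """Map k-mer string -> [(exon key, part tag)] over all eligible exons."""
    k = config.k
    lb = config.boundary_len
    table: dict[str, list[tuple[tuple[int, int, int, int], str]]] = {}
    for exon in eligible_exons(catalog):
        seq = genome[catalog.chromosomes[exon.chrom_index]][exon.start : exon.end]
        n_windows = len(seq) - k + 1
        if n_windows <= 0:
            continue
        if len(seq) <= config.max_short_exon:
            first_half = (n_windows + 1) // 2  # ceil: odd middle window -> "S"
            windows = [(o, "S" if o < first_half else "E") for o in range(n_windows)]
        else:
            windows = [(o, "S") for o in range(lb)]
            windows += [(o, "E") for o in range(n_windows - lb, n_windows)]
        for offset, tag in windows:
            kmer = seq[offset : offset + k]
            if set(kmer) - set("ACGT"):
                continue
            entry = (exon.key, tag)
            bucket = table.setdefault(kmer, [])
            if entry not in bucket:
                bucket.append(entry)
    return table


def oracle_scan(
    sequence: str,
    windows: dict[str, list[tuple[tuple[int, int, int, int], str]]],
    k: int,
) -> dict[tuple[int, int, int], list[tuple[int, str, int]]]:
    """Read-order (exon_index, tag, offset) events grouped by transcript."""
    statuses: dict[tuple[int, int, int], list[tuple[int, str, int]]] = {}
    for offset in range(len(sequence) - k + 1):
        kmer = sequence[offset : offset + k]
        for (ci, gi, ti, ei), tag in windows.get(kmer, []):
            statuses.setdefault((ci, gi, ti), []).append((ei, tag, offset))
    return statuses
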