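"""Build and inspect the exon-boundary k-mer table.

Loads a small synthetic genome + annotation, shows the derived length
constants (boundary region L_B, short-exon cutoff L_em), builds the
table over the splice-signal-eligible exons, and looks one k-mer up.

Printed numbers: the length constants in bp, how many exons were
eligible for indexing, the table size, and the annotation positions
(chromosome/gene/transcript/exon indices plus the S/E part tag) stored
for one example k-mer.
"""

from backsplice import Config, SimParams, build_table, eligible_exons
from backsplice.kmer_index import decode_kmer
from backsplice.synthetic_data import simulate_dataset

config = Config()  # k=15, 101 bp reads, 30% boundary coverage
print(f"k = {config.k}, read length = {config.read_length} bp")
print(f"boundary region L_B = {config.boundary_len} bp per exon side")
print(f"short-exon cutoff L_em = {config.max_short_exon} bp "
      "(shorter exons are indexed in full)")

dataset = simulate_dataset(SimParams(genome_length=30_000, n_genes=8, seed=3))
table = build_table(dataset.catalog, dataset.genome, config)
n_eligible = len(eligible_exons(dataset.catalog))
print(f"\n{n_eligible} of {dataset.catalog.n_exons} exons carry a splice "
      f"signal and were indexed; table holds {table.n_kmers} k-mer keys")

code = next(iter(table.per_chrom["chr1"]))
print(f"\nexample k-mer {decode_kmer(code, config.k)} maps to:")
for pos in table.lookup(code):
    print(f"  chrom {pos.chrom_index} gene {pos.gene_index} "
          f"transcript {pos.transcript_index} exon {pos.exon_index} "
          f"part '{pos.part_tag}' ({len(pos.pack())} bytes packed)")
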