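"""Generate a synthetic circRNA benchmark dataset.

Builds a small multi-gene genome with GT-AG introns, plants back-splice
junctions (self- and regular-circular), samples 101 bp reads from the
linear and circularised transcripts, and writes FASTA/GTF/FASTQ plus a
truth BED.  The printed counts describe the study conditions: how many
genes, how many planted junctions, and how many reads at the chosen
coverages.
"""

from backsplice import SimParams, simulate_dataset

params = SimParams(genome_length=40_000, n_genes=12, seed=7)
dataset = simulate_dataset(params, out_dir="sim_out")

n_genes = sum(len(g) for g in dataset.catalog.genes_by_chrom)
print(f"genome: {sum(map(len, dataset.genome.values()))} bp over "
      f"{len(dataset.genome)} chromosomes, {n_genes} genes")
print(f"planted junctions: {len(dataset.truth)} "
      f"({sum(t.case_type == 'self' for t in dataset.truth)} self, "
      f"{sum(t.case_type == 'regular' for t in dataset.truth)} regular)")
print(f"reads: {len(dataset.reads)} x {params.read_length} bp "
      f"(circular {params.circ_coverage:.0f}X, linear {params.linear_coverage:.0f}X)")
print("files written to sim_out/: genome.fa annotation.gtf reads.fastq truth.bed")
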