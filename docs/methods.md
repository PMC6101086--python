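# Methods

## Model and assumptions

`backsplice` detects circular RNA by classifying RNA-seq reads against
a k-mer index of annotated exon boundaries, without read mapping. The
underlying model is purely positional: a linear read produces k-mer
hits that walk *forward* through a transcript (beginning-of-exon tags
before end-of-exon tags, exon indices non-decreasing in transcript
order), whereas a read spanning a back-spliced junction produces hits
that go *backward* at exactly one point (an `E` region followed by an
`S` region, a later exon followed by an earlier one). Everything else
— thresholds, tag condensation, signal checks — exists to separate
these two signatures under read errors and k-mer collisions.

Assumptions inherited from the approach:

- every junction of interest lies on annotated exon boundaries (no de
  novo junctions, no intronic breakpoints);
- back-splicing joins exons of a single annotated transcript; the two
  junction exons therefore share one hitting status;
- candidate exons must carry canonical splice signals on the relevant
  sides: acceptor `AG` left / donor `GT` right of a `+` exon in genome
  coordinates, and `AC` left / `CT` right of a `−` exon (a `−` intron
  reads `CT…AC` genome-forward, the reverse complement of `GT…AG`).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 15 bp | k-mer length; 2 bits/base must fit a 32-bit word, so k ≤ 15 and 15 maximises specificity |
| `read_length` (L_R) | 101 bp | expected read length; enters L_B and the self-circular coverage check |
| `r_c` | 0.30 | boundary coverage fraction per exon side; the two boundaries then cover 60% of a read, more than half |
| `min_best_hits` | 5 | minimum supporting k-mers for a best hitting case |
| `best_hit_margin` | 5 | "clearly more support" margin in best-case selection |
| `min_exon_hits` | 3 | per-exon hits must exceed this to count in regular-case filtering; also the noise floor in tag condensation |
| `max_support` | 2³¹ (sentinel) | refinement drops junctions with at least this many supporting reads; the default keeps everything, finite values suit data where circRNA coverage is bounded and very deep junctions are suspect |
| `tolerance` | 5 bp | junction matching tolerance in evaluation |

Derived lengths: L_B = ⌊L_R·r_c⌋ = 30 bp, L_em = 2·L_B + 2·k − 1 =
89 bp. L_em is the largest exon length at which the two boundary
windows of length L_B + k − 1 still cover the whole exon, hence
"short" exons are indexed in full.

## Numerical and procedural choices

- **Rounding.** L_B uses floor (a length times a fraction); the
  long-case minimum hitting number ⌊1.2·L_B⌋ = 36 uses floor so hit
  counts stay integral. Both thresholds compare with "discard if
  strictly smaller".
- **Short-exon tag split.** With an odd number of windows the middle
  window is tagged `S` (ceil on the first half).
- **Boundary windows stay inside the exon**; k-mers containing `N` are
  skipped; duplicate (exon, tag) records under one k-mer are stored
  once.
- **Strand handling.** Only the genome-forward sequence is indexed;
  each read is scanned in both orientations and the orientation whose
  best status wins under the selection ordering is kept (ties →
  forward). The sampling quick-check passes if either orientation
  passes, since reads sequenced from the non-indexed strand would
  otherwise never be scanned. For `−` genes the matched orientation is
  the reverse complement of the transcript, so hit events are
  canonicalised to transcript order (list reversed, `S`/`E` swapped)
  before filtering procedure two; the `+` rule (index decreases at the
  junction, head exon = larger index) and the `−` mirror rule (index
  increases, head = smaller index) then apply literally, and on both
  strands the reported junction is (genomic-left exon start,
  genomic-right exon end).
- **Best-case selection** seeds the incumbent with the first status
  encountered and replaces it only by the printed rule; a challenger
  with clearly *less* support never wins, and equal metrics keep the
  earlier status, making selection deterministic in read order.
- **Tag condensation.** Runs of identical (exon, tag) events are
  counted; inside an exon showing both tags, runs supported by at most
  `min_exon_hits` k-mers are dropped as random hits (so S(1),E(10)
  condenses to E(10)) and adjacent same-tag runs merge. In the regular
  case an exon that still shows `S` then `E` — the footprint of a read
  covering that exon completely — keeps `E` if it is the first exon of
  the read and `S` if the second. A strictly larger-count-wins rule
  would always collapse an exon to a single tag, which both erases the
  `E`-then-`S` junction pattern needed for long self-circular exons and
  makes the first/second-exon rule unreachable; the noise-floor rule
  preserves both while filtering the same random hits.
- **Self-circular support.** An exon shorter than the read must be hit
  at least L_e − k + 1 times. For a circle of length L_e, a wrapping
  read forfeits the k − 1 windows spanning each junction crossing, so
  the maximum attainable N_h is below the minimum hitting number
  whenever L_e is close to L_R (at the defaults: 84 ≤ L_e ≤ 100 is
  undetectable, computed exactly by `self_circle_detectable`). The
  evaluator's `eligible_truth` applies the same predicate, and the
  simulator only plants self circles on exons that can pass it.
- **Refinement** groups candidates by (chrom, start, end, strand);
  self and regular calls at identical coordinates merge, recorded as
  "self" if any contributing read was. Output is coordinate-sorted,
  so repeated runs are byte-identical.

## Synthetic data

The generator emulates the essential structure of a eukaryotic
transcriptome at toy scale: a uniform-random genome (default 100 kb
over 2 chromosomes) holding 30 non-overlapping genes on either strand,
each one transcript of 4–6 exons (60–180 bp) separated by 60–300 bp
introns carrying the canonical splice dinucleotides, with neutral `CC`
flanks outside the terminal exons. Two thirds of the genes receive one
planted circle — a single internal exon (self case, restricted to
detectable lengths) or an exon span with valid donor/acceptor
boundaries (regular case) — and reads are drawn uniformly from the
spliced linear transcripts (50X) and from the circularised sequences
with junction wrap-around (20X), from either strand, 101 bp, with
independent per-base substitution errors. All randomness derives from
one seed via per-stage streams, so outputs are byte-reproducible and
the standalone generator operations match the bundled pipeline.

What the simulator deliberately does **not** model: indel or
quality-dependent errors (substitutions are the k-mer-relevant error
mode; indels only shorten hit runs), expression-level variation,
isoform mixtures, intron retention, GC bias, RNase R enrichment
chemistry, and genomic repeats. Passing tests on this data therefore
demonstrate the correctness of the indexing/scanning/calling logic and
its error tolerance, not performance on repeat-rich real genomes,
where shared exon sequence between paralogs would create multi-gene
hitting statuses and lower precision.

The dataset sizes used by the test suite and the acceptance script
(100 kb / 30 genes for end-to-end runs, ≤ 5 kb for brute-force oracle
comparisons) were chosen as the smallest instances that exercise every
code path — both strands, both case types, short and long exons,
multi-chromosome partitioning — with wide statistical margins.

## Limitations

- Junctions joining exons of *different* transcripts (or genes) are
  out of scope by construction, as is reconstruction of the full
  circular sequence.
- Self-circular exons with L_em < L_e < L_R are provably undetectable
  under the support rules (see above); they are excluded from the
  detectable-truth baseline rather than silently counted as misses.
- Paired-end mates are scanned independently; pairing information is
  never used.
- The annotation is trusted: a wrong exon boundary shifts the called
  junction coordinates accordingly.
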