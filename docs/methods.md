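# Methods

## Model and procedure

`mist` calls variants over targeted exonic regions by inverted mapping:
instead of placing every read on the genome, it retrieves the reads that
could belong to each target and aligns only those, to the target itself.
The stages, in order:

1. **Reference preparation.** Core exons (BED6 or a refFlat-style table)
   are extended by `extension` bp on both ends (default 70; the value is a
   function of the mean library insert — it exists so mates that reach
   into intron still align fully) and overlapping *or abutting* extended
   exons merge into super-exons. Abutting targets are merged although only
   overlap strictly requires it, because a read spanning a shared boundary
   would otherwise be counted under two targets. Coordinates are 0-based
   half-open internally; VCF and pileup output convert to 1-based.
2. **Read QC.** A pair is discarded if either mate contains a non-ACGT
   base or has any 16-nt sliding window (step 1, strict `<`) with mean
   Phred quality below 10. Qualities are not used past this point: at
   calling coverage, two independent Q30 errors coincide at a site with
   probability 10⁻⁶, so per-base qualities buy little and tie the caller
   to platform-specific calibration. Reads shorter than the window are
   judged as one whole-read window.
3. **Indexing.** Surviving pairs are concatenated `mate1 + '$' + mate2`
   and split round-robin into `subsets` groups (default 4), each indexed
   as an exact-match k-mer map (k = tile size, default 25). `'$'` is
   outside the DNA alphabet, so no window spans the mate junction. The
   genome gets the same index, queried on both strands. A hash of k-mers
   is contract-equivalent to a suffix array at fixed k; windows containing
   N are never keyed. The union of subset indexes equals the whole-set
   index, so results are invariant to the subset count (tested).
4. **Retrieval.** Each target sequence is tiled (k = 25, step 1, plus a
   final flush window); a pair is a candidate if any tile, on either
   strand, occurs exactly in its concatenated string. 25 nt balances
   sensitivity to variants (smaller tiles tolerate denser mismatches)
   against multi-mapping noise.
5. **Origin filter.** Per candidate: up to 4 non-overlapping tiles per
   mate, evenly spaced including both read ends (end tiles maximise
   intron reach); tiles with a mononucleotide run ≥ 10 or a dinucleotide
   tandem spanning ≥ 12 bases are dropped without replacement; tiles with
   more than `max_genome_mappings` (5) genome hits are dropped, and if
   none survive the pair is discarded. Hits are sorted and grouped
   greedily into windows of `origin_window` (500) bp anchored at each
   cluster's minimum hit coordinate; a window's match number is its count
   of distinct supporting tiles. The pair's origin is the unique
   maximum-match window — a tie discards the pair as paralogous — and the
   origin must reach the target core (closed containment, optionally
   widened by `insert_margin`). Anchoring at the minimum hit rather than
   centring windows on each hit keeps one read pair's support (which
   spans up to an insert length) inside a single window; centring would
   split it and manufacture ties at unique loci. If *all* selected tiles
   have zero genome hits anywhere (each straddles a variant or error),
   every k-mer window of both mates is queried before deciding: a pair
   retrieved by an exact target match always carries at least one
   mappable k-mer, and this keeps tie detection alive inside exact
   duplications without making retention depend on tile-grid phase.
6. **Alignment.** Each mate of a retained pair is aligned to the extended
   target with an optimal local affine-gap alignment (Smith–Waterman;
   match +1, mismatch −3, a length-L gap costs 5 + 2L), both orientations
   tried. Alignments scoring under 30 or covering under half the read are
   rejected. The dynamic program is Bio.Align.PairwiseAligner in local
   mode (its `open_gap_score` is set to −7 so the first gap base costs
   open+extend under our convention); the test suite checks it against an
   independent full-matrix DP oracle. Retrieval guarantees near-identity,
   so no heuristic seeding is needed. Ties between equal-scoring
   alignments resolve to the aligner's deterministic first traceback.
7. **Clonal collapse.** Pairs with both mates aligned form a 4-endpoint
   signature (outer target coordinates of each mate). Visiting pairs in
   sorted id order, a pair joins the first group in which any member
   shares ≥ 3 of 4 endpoints exactly (single linkage); the group's first
   pair is the representative, all others are flagged clonal. Exact
   integer equality defines coincidence — the 3-of-4 rule itself is the
   tolerance for trimming-shifted ends. Member linkage (not
   representative-only comparison) keeps a jittered duplicate attached to
   its template even when the template was absorbed earlier by a
   near-identical fragment.
8. **Pileup.** Statistics use pair-consistent coverage only: reads whose
   mate failed to align are excluded from counts (the clonal rule is
   undefined for half-pairs, and their uncollapsible duplicates would
   re-inflate coverage — the very artifact being removed) but remain in
   SAM output with the mate-unmapped flag. Per target offset the pileup
   tallies A/C/G/T, deleted-base and insertion events split by strand,
   twice: clonal-excluded (`counts`) and raw. Deletions count at every
   deleted offset; insertions are left-anchored to the preceding offset.
   Zero-coverage columns are emitted.
9. **Calling.** A non-reference allele is called when clonal-excluded
   coverage ≥ `min_coverage` (15) and its frequency ≥ `min_alt_freq`
   (0.3) — thresholds below which false positives dominate. Runs of
   adjacent qualifying deletion columns merge into one DEL; indel calls
   are normalised to the leftmost equivalent anchor, and the simulator's
   truth table uses the same normalisation, so representations in repeat
   context agree. Strand skew (n⁺ − n⁻)/(n⁺ + n⁻) is recorded per allele;
   |skew_alt − skew_ref| > `skew_delta` (0.5) sets the VCF FILTER to
   `skew` without suppressing the call — a variant whose reference allele
   is equally skewed is still credible. The 21-nt flank (10 per side,
   clamped at target edges) and its exact both-strand genome occurrence
   count annotate potential paralogy. Genotype is reported hom above
   frequency 0.75, het otherwise (reporting only). Coding effects come
   from codon comparison under the standard genetic code (synonymous /
   missense / nonsense / stop_loss; UTR, intronic, noncoding; frameshift
   vs inframe for CDS indels), on either transcript strand.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `extension` | 70 | bp | flank pad; function of mean insert size |
| `tile_size` | 25 | nt | exact-match tile; sensitivity/uniqueness balance |
| `read_tiles` | 4 | tiles/mate | origin evidence per mate |
| `max_genome_mappings` | 5 | hits | tile discard threshold for repeats |
| `origin_window` | 500 | bp | origin window span |
| `qc_window`, `qc_min_avg` | 16, 10 | nt, Phred | read-quality gate |
| `min_coverage` | 15 | reads | calling floor (clonal-excluded) |
| `min_alt_freq` | 0.3 | — | minor-allele frequency floor |
| `skew_delta` | 0.5 | — | ref/alt skew difference that flags a call |
| `subsets` | 4 | — | read-index parallelisation factor |

## Synthetic data: what it emulates, what it does not

The generator produces one random chromosome (default 50 kb) with exon
targets of 1.0–1.2 kb — the size of the large terminal exon used to
calibrate tile size — a single-exon CDS transcript per target, and
optionally a duplicated gene block: `exact_copy` (verbatim) or
`diverged_copy` (exon preserved, flanking intron mutated at 5% per base,
emulating a processed pseudogene's neutral intronic divergence). Variants
(default 20 het SNVs, 10 hom SNVs, one het 2-bp deletion, one hom 2-bp
insertion) are placed in equal slots across the core with ≥ 28 bp
separation: exact-match retrieval needs one clean 25-mer per read, so
packing variants denser than a tile length would deplete the variant
haplotype *by construction*; real exome variant spacing (~1 per kb) is far
sparser than a tile. Fragments are drawn per target at `depth` (60×) read
coverage with Normal(300, 30) insert lengths, a random haplotype each,
uniform substitution errors at 10⁻³, Q35 baseline qualities with a
low-quality 16-nt window injected in 2% of reads, and clonal duplicates at
probability 0.3 — a duplicate re-emits the template's base calls and
qualities, with one fragment end truncated by ≤ 2 bp in half of them
(modelling quality trimming; this is what the 3-of-4 rule must catch).
All randomness derives from one integer seed through per-fragment
streams, so outputs are byte-identical per configuration and base
fragments do not change when the clonal fraction changes.

Not modelled: capture-efficiency and GC bias, indel sequencing errors
(available as planted true indels instead), platform error profiles,
overlapping mates, optical duplicates. Passing the recovery suite
therefore demonstrates the pipeline's logic under idealised error and
capture models, not performance on real libraries.

## Numerical and degenerate-input choices

- Quality windows slide with step 1; strict `< 10`; whole-read window for
  short reads. Phred+33 by default (`--phred-offset`).
- The genome index answers both strands; the read index is forward-only
  and target tiles are queried in both orientations instead.
- `count_genome_mappings` truncates at cap+1 — anything past "too many"
  is never needed.
- Origin windows are clamped at chromosome ends; assign_origin sorts hits
  before grouping, so it is independent of tile evaluation order.
- Indel calls and simulator truth are both left-aligned with the same
  shift rule; a DEL run starting at target offset 0 cannot be anchored
  and is dropped (no reference base to the left).
- Empty FASTQ input yields a valid empty VCF and a zero-count report.
- Multi-allelic sites emit one VCF record per alternate allele.

## Known limitations

- **Terminal-mismatch clipping depresses het frequencies.** An optimal
  local alignment clips a mismatch within ~3 bp of a read end (the −3
  penalty outweighs the remaining match gain), so variant-carrying reads
  lose terminal evidence while reference reads never do. Measured het
  allele frequencies centre near 0.44–0.46 rather than 0.5 — consistent
  with the field observation that confirmed het calls sit well below 0.5
  — which is precisely why the calling threshold is 0.3 and not higher.
  At 60× this leaves a ~0.1–1% per-site chance that a true het falls
  under the frequency floor.
- **Pair-consistent coverage halves near target edges.** Positions within
  about one read length of the core boundary are covered mostly by pairs
  whose other mate lies beyond the 70-bp extension and cannot align;
  such half-pairs are excluded from statistics, so edge sites run at
  roughly half depth.
- **Identical-sequence regions stay silent.** Pairs wholly inside an
  exact duplication are discarded as ties by design; variants there are
  not callable (reported as the tie rejection count, not as calls).
- **Clonal chaining.** With exact-endpoint single linkage, a duplicate
  can (rarely, ~1 per several thousand pairs) bridge an unrelated
  fragment into its clonal group; clone-present and clone-free runs then
  differ by one counted read at the affected columns.
- Single-sample calling only: no trio logic, no external annotation
  databases, no BAM/CRAM encoding, no probabilistic multi-mapping
  resolution.
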