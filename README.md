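# mist

Inverted-mapping variant calling for targeted and whole-exome sequencing.

Conventional exome pipelines map every read genome-wide and then inspect
alignments over the targeted exons. `mist` inverts that: each targeted exon
(extended by 70 bp of flank and merged with overlapping neighbours into
super-exons) acts as bait. Reads that share an exact 25-nt tile with the
extended exon are pulled from a k-mer index of the concatenated read pairs,
and only those reads are ever aligned — to the exon itself, not the genome.
Two artifact classes that dominate false calls are handled explicitly:

- **Paralogous read pairs.** Up to four non-overlapping 25-nt tiles are
  taken from each mate and looked up in a both-strand genome index. Tiles
  with more than 5 genome mappings are dropped; remaining hits are grouped
  into 500-nt origin windows and each window scores a *match number* (how
  many tiles support it). The top window must be unique — a tie means the
  pair fits two loci (gene/pseudogene, segmental duplication) and it is
  discarded — and must reach the target exon. Because introns evolve
  neutrally, a mate reaching into intron carries copy-specific tiles that
  break gene/pseudogene ties.
- **Clonal (PCR-duplicate) pairs.** Two pairs are clones when at least 3 of
  their 4 paired-end alignment endpoints on the target coincide exactly,
  which also catches duplicates whose one end moved under quality trimming.
  One representative per clonal group enters the statistics; the rest stay
  visible in SAM output flagged as duplicates.

Surviving reads get an optimal Smith–Waterman affine-gap alignment
(match +1, mismatch −3, gap −5 − 2·L) to the extended exon, pileups tally
per-base allele counts split by strand, and a site is called when
clonal-corrected coverage ≥ 15 and the non-reference allele frequency
≥ 0.3. Strand skew, defined per allele as (n⁺ − n⁻)/(n⁺ + n⁻), annotates
(never suppresses) calls whose reference/alternate skews differ by more
than 0.5. Every call carries its 21-nt reference flank and that flank's
exact genome occurrence count (a paralogy alarm), plus a coding-effect
classification against a transcript model. Outputs are VCF 4.2, SAM text,
a per-target five-column pileup text, a call TSV and a JSON run report.

A deterministic simulator (`mist sim`) generates the study conditions:
random genomes with optional exact or diverged-intron gene copies, diploid
SNVs/indels planted on haplotypes, 2×100 nt paired reads at configurable
depth with substitution errors and quality strings, clonal duplicates with
end jitter, and a truth table keyed to read ids.

## Worked example

```
mist sim --out demo/sim --seed 3
mist run --genome demo/sim/genome.fa --targets demo/sim/targets.bed \
         --fq1 demo/sim/reads_1.fastq --fq2 demo/sim/reads_2.fastq \
         --transcripts demo/sim/transcripts.tsv --out demo/out
```

prints

```
578 read pairs, 32 planted variants -> demo/sim
pairs: 578 in, 550 after QC, 548 retained, 106 clonal; 32 calls -> demo/out/calls.vcf
```

578 simulated pairs enter; 28 fail read QC (an ambiguous base, or any
16-nt window with mean quality < 10, discards the whole pair); 548 of the
QC survivors are retrieved for the target and pass the origin filter; 106
are collapsed as clonal duplicates; the caller emits exactly the 32
planted variants. The first VCF record,

```
chr1  12526  .  C  G  .  PASS  DP=25;AF=1;SR=0,0;SA=25,0;SKEWA=1;FLM=1;EFF=missense  GT  1/1
```

is a homozygous missense SNV with clonal-corrected depth 25 (`DP`), all 25
reads carrying the alternate allele (`AF=1`) on the plus strand
(`SA=25,0`, `SKEWA=1` — near the exon edge only one mate orientation
reaches the site; the reference allele shows no opposing evidence, so the
call is not skew-flagged), and a 21-nt flank unique in the genome
(`FLM=1`). `mist explain chr1:12526 --out demo/out` shows the underlying
pileup row, the call and the overlapping reads with duplicates counted.

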