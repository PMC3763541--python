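"""Deterministic synthetic data: genomes with paralogs, planted variants,
paired reads with errors and clonal duplicates, and a truth table.

The generator emulates a targeted capture experiment on a small genome:
random chromosome, exon targets with transcript models, optionally a
duplicated gene block (exact copy, or a pseudogene whose exonic sequence is
identical while the flanking intronic sequence has diverged neutrally),
diploid variants planted on one or both haplotypes, and 2 x 100 nt
paired-end fragments drawn around each exon at a configured depth with
uniform substitution errors and Phred-style quality strings.

Clonal duplicates model PCR over-amplification: a duplicated fragment
re-emits the template pair's base calls verbatim, optionally with one
fragment end truncated by up to 2 bp (mimicking quality trimming), which
exercises the 3-of-4-endpoint clonal rule downstream.

All randomness flows from one integer seed through per-fragment
SeedSequence-style streams, so outputs are byte-identical for identical
configurations and the base fragments do not change when the clonal
fraction changes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from mist.readprep import ReadPair
from mist.reference import GenomeRef, TranscriptModel
from mist.seq import left_align_indel, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedVariant:
    target_index: int
    offset: int  # within the target core
    vtype: str  # SNV | DEL | INS
    alt: str  # SNV: alt base; INS: inserted sequence; DEL: ignored
    zygosity: str  # het | hom
    del_length: int = 0
    ref: str = ""  # filled by plant_variants
    pos: int = 0  # 1-based genomic anchor, filled by plant_variants


@dataclass
class SimConfig:
    seed: int = 0
    chrom_length: int = 50_000
    n_targets: int = 1
    exon_length: tuple[int, int] = (1000, 1200)
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 60.0
    error_rate: float = 0.001
    clonal_fraction: float = 0.3
    clonal_jitter_fraction: float = 0.5
    clonal_jitter_max: int = 2
    lowq_fraction: float = 0.02
    paralog: str = "none"  # none | exact_copy | diverged_copy
    paralog_divergence: float = 0.05
    decoy_depth: float = 0.0  # read depth sampled from the paralog copy
    intron_flank: int = 400  # intron carried along with a duplicated gene block
    variants: list[PlantedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.clonal_fraction, self.lowq_fraction):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")


@dataclass
class SimDataset:
    genome: GenomeRef
    cores: list[tuple[str, int, int, str, str]]  # chrom, start, end, name, strand
    transcripts: list[TranscriptModel]
    pairs: list[ReadPair]
    truth_variants: list[PlantedVariant]
    truth_pairs: list[dict]
    decoy_core: tuple[str, int, int] | None = None


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def make_genome(config: SimConfig):
    """Random genome with evenly spaced exon cores, transcript models and
    (optionally) a duplicated gene block.

    For ``diverged_copy`` the duplicated block keeps the exon verbatim and
    mutates intronic bases at ``paralog_divergence`` — introns evolve
    neutrally and are copy-specific, which is exactly the signal the
    origin-window majority rule relies on.
    """
    rng = _rng(config.seed, 1)
    chrom = "chr1"
    seq = list(_random_dna(rng, config.chrom_length))
    rng_len = _rng(config.seed, 2)
    lo, hi = config.exon_length
    spacing = config.chrom_length // (config.n_targets + (2 if config.paralog != "none" else 1))
    cores = []
    transcripts = []
    for t in range(config.n_targets):
        exon_len = int(rng_len.integers(lo, hi + 1))
        start = spacing * t + spacing // 2
        end = start + exon_len
        if end + config.intron_flank >= config.chrom_length:
            raise ValueError("chrom_length too small for the requested targets")
        name = f"T{t}"
        cores.append((chrom, start, end, name, "+"))
        cds_len = 3 * (exon_len // 3)
        transcripts.append(
            TranscriptModel(
                transcript_id=name,
                chrom=chrom,
                strand="+",
                blocks=[(start, end)],
                cds_start=start,
                cds_end=start + cds_len,
            )
        )
    decoy_core = None
    if config.paralog != "none":
        src_chrom, s, e, _, _ = cores[0]
        block_lo = s - config.intron_flank
        block_hi = e + config.intron_flank
        block = seq[block_lo:block_hi]
        if config.paralog == "diverged_copy":
            rng_div = _rng(config.seed, 3)
            exon_rel = (s - block_lo, e - block_lo)
            for i in range(len(block)):
                if exon_rel[0] <= i < exon_rel[1]:
                    continue
                if rng_div.random() < config.paralog_divergence:
                    others = [b for b in "ACGT" if b != block[i]]
                    block[i] = others[int(rng_div.integers(0, 3))]
        dest = spacing * (config.n_targets + 1) - len(block) // 2
        seq[dest : dest + len(block)] = block
        decoy_core = (chrom, dest + (s - block_lo), dest + (e - block_lo))
    genome = GenomeRef({chrom: "".join(seq)})
    return genome, cores, transcripts, decoy_core


def random_variant_spec(
    config: SimConfig,
    core_len: int,
    n_het_snv: int = 20,
    n_hom_snv: int = 10,
    n_het_del: int = 1,
    n_hom_ins: int = 1,
    target_index: int = 0,
    min_gap: int = 28,
) -> list[PlantedVariant]:
    """Place non-overlapping variants within one target core.

    Variants are spread over equal slots with jitter so that any two are at
    least ``min_gap`` bases apart. Exact-match retrieval needs a clean
    25-mer in each read, so variants packed closer than a tile length would
    deplete the variant haplotype by construction — real exome variant
    spacing (~1 per kb) is far sparser than a tile.
    """
    rng = _rng(config.seed, 4, target_index)
    n_total = n_het_snv + n_hom_snv + n_het_del + n_hom_ins
    edge = 25  # keep clear of core edges (full flanks, clean edge tiles)
    w = (core_len - 2 * edge) / n_total
    if w < min_gap + 1:
        raise ValueError("core too small for the requested variant count at min_gap")
    jitter_max = max(1, int(w) - min_gap)
    offsets = [edge + round(i * w) + int(rng.integers(0, jitter_max)) for i in range(n_total)]
    kinds = (
        [("SNV", "het")] * n_het_snv
        + [("SNV", "hom")] * n_hom_snv
        + [("DEL", "het")] * n_het_del
        + [("INS", "hom")] * n_hom_ins
    )
    rng.shuffle(kinds)  # type: ignore[arg-type]
    out = []
    for off, (vtype, zyg) in zip(offsets, kinds):
        if vtype == "SNV":
            out.append(PlantedVariant(target_index, off, "SNV", "", zyg))
        elif vtype == "DEL":
            out.append(PlantedVariant(target_index, off, "DEL", "", zyg, del_length=2))
        else:
            ins = _random_dna(rng, 2)
            out.append(PlantedVariant(target_index, off, "INS", ins, zyg))
    return out


def plant_variants(
    genome: GenomeRef,
    cores: list[tuple[str, int, int, str, str]],
    variants: list[PlantedVariant],
    config: SimConfig,
):
    """Build the two haplotype sequences per target region and finalise the
    truth records (ref alleles, VCF-anchored genomic positions).

    The region extends ``insert_mean + 4*insert_sd`` beyond the core on both
    sides so every simulated fragment fits. Returns
    ``{target_index: (region_start, hapA, hapB)}``; het variants sit on
    haplotype A only, hom variants on both.
    """
    pad = int(config.insert_mean + 4 * config.insert_sd)
    rng = _rng(config.seed, 5)
    regions = {}
    by_target: dict[int, list[PlantedVariant]] = {}
    for v in variants:
        by_target.setdefault(v.target_index, []).append(v)
    for t, (chrom, cs, ce, _, _) in enumerate(cores):
        region_start = max(0, cs - pad)
        region_end = min(len(genome.sequences[chrom]), ce + pad)
        ref_seq = genome.slice(chrom, region_start, region_end)
        tvars = sorted(by_target.get(t, []), key=lambda v: v.offset)
        # overlap check on reference footprints
        prev_end = -1
        for v in tvars:
            span = v.del_length if v.vtype == "DEL" else 1
            if v.offset <= prev_end:
                raise ValueError("overlapping planted variants")
            prev_end = v.offset + span - 1
        # finalise truth records (ref allele, leftmost VCF anchor) once;
        # raw edits are stashed so both haplotypes apply identical changes
        edits = []  # (rel, vtype, payload)
        for v in tvars:
            rel = cs - region_start + v.offset
            if v.vtype == "SNV":
                ref_base = ref_seq[rel]
                if not v.alt:
                    others = [b for b in "ACGT" if b != ref_base]
                    v.alt = others[int(_rng(config.seed, 6, t, v.offset).integers(0, 3))]
                v.ref = ref_base
                v.pos = cs + v.offset + 1
                edits.append((rel, "SNV", v.alt, v.zygosity))
            elif v.vtype == "DEL":
                ref = ref_seq[rel - 1 : rel + v.del_length]
                a, v.ref, v.alt = left_align_indel(ref_seq, rel - 1, ref, ref[0])
                v.pos = region_start + a + 1  # leftmost anchor, 1-based
                edits.append((rel, "DEL", v.del_length, v.zygosity))
            elif v.vtype == "INS":
                ins = v.alt
                a, v.ref, v.alt = left_align_indel(ref_seq, rel, ref_seq[rel], ref_seq[rel] + ins)
                v.pos = region_start + a + 1
                edits.append((rel, "INS", ins, v.zygosity))
        haps = []
        for hap_name in ("A", "B"):
            s = list(ref_seq)
            for rel, vtype, payload, zyg in reversed(edits):
                if zyg == "het" and hap_name == "B":
                    continue
                if vtype == "SNV":
                    s[rel] = payload
                elif vtype == "DEL":
                    del s[rel : rel + payload]
                elif vtype == "INS":
                    s[rel] = ref_seq[rel] + payload
            haps.append("".join(s))
        regions[t] = (region_start, haps[0], haps[1])
    return regions


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        base = arr[i].decode()
        others = [b for b in "ACGT" if b != base]
        arr[i] = others[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def _quality(rng: np.random.Generator, n: int, lowq: bool) -> list[int]:
    qual = [35] * n
    if lowq and n >= 16:
        start = int(rng.integers(0, n - 16 + 1))
        for i in range(start, start + 16):
            qual[i] = 2
    return qual


def simulate_pairs(regions, cores, config: SimConfig, decoy_core=None, genome: GenomeRef | None = None):
    """Draw paired reads around every target core (plus, optionally, the
    paralog decoy) and return (pairs, truth_pair_rows).

    Pair counts target ``depth`` x read coverage over the core. Pair ids
    encode origin as ``T<t>|<hap>|<frag_start>-<frag_end>|<serial>`` with a
    ``d<j>`` suffix on clonal duplicates; fragment coordinates are region
    1-based in haplotype space.
    """
    rl = config.read_length
    pairs: list[ReadPair] = []
    truth_rows: list[dict] = []

    def emit_region(tag: str, tag_num: int, region_start: int, hapA: str, hapB: str, cs: int, ce: int, depth: float):
        core_len = ce - cs
        n_frag = int(round(depth * (core_len + config.insert_mean) / (2 * rl)))
        for i in range(n_frag):
            rng = _rng(config.seed, 11, tag_num, i)
            hap_name = "A" if rng.random() < 0.5 else "B"
            hap = hapA if hap_name == "A" else hapB
            flen = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            flen = max(rl, min(flen, len(hap)))
            lo = max(0, cs - region_start - flen + 1)
            hi = max(lo + 1, min(len(hap) - flen, ce - region_start))
            fstart = int(rng.integers(lo, hi))
            frag = hap[fstart : fstart + flen]
            r1 = _apply_errors(frag[:rl], rng, config.error_rate)
            r2 = _apply_errors(revcomp(frag[-rl:]), rng, config.error_rate)
            lowq1 = rng.random() < config.lowq_fraction
            lowq2 = rng.random() < config.lowq_fraction
            q1 = _quality(rng, rl, lowq1)
            q2 = _quality(rng, rl, lowq2)
            pid = f"{tag}|{hap_name}|{fstart + 1}-{fstart + flen}|{i}"
            pairs.append(ReadPair(pid, r1, r2, q1, q2))
            truth_rows.append(
                {"pair_id": pid, "origin": tag, "hap": hap_name,
                 "frag_start": region_start + fstart, "frag_end": region_start + fstart + flen,
                 "clone_of": ""}
            )
            rng_clone = _rng(config.seed, 13, tag_num, i)
            if rng_clone.random() < config.clonal_fraction:
                # duplicates re-emit the template's base calls and qualities;
                # optional truncation of the fragment-end mate models
                # quality trimming (shifts exactly one alignment endpoint)
                s2, dq2 = r2, list(q2)
                if rng_clone.random() < config.clonal_jitter_fraction:
                    j = int(rng_clone.integers(1, config.clonal_jitter_max + 1))
                    s2 = revcomp(revcomp(r2)[: len(r2) - j])
                    dq2 = dq2[: len(s2)]
                dup_id = f"{pid}d1"
                pairs.append(ReadPair(dup_id, r1, s2, list(q1), dq2))
                truth_rows.append(
                    {"pair_id": dup_id, "origin": tag, "hap": hap_name,
                     "frag_start": region_start + fstart, "frag_end": region_start + fstart + flen,
                     "clone_of": pid}
                )

    for t, (chrom, cs, ce, name, _) in enumerate(cores):
        region_start, hapA, hapB = regions[t]
        emit_region(f"T{t}", t, region_start, hapA, hapB, cs, ce, config.depth)

    if decoy_core is not None and config.decoy_depth > 0:
        if genome is None:
            raise ValueError("decoy simulation needs the genome")
        chrom, ds, de = decoy_core
        pad = int(config.insert_mean + 4 * config.insert_sd)
        region_start = max(0, ds - pad)
        region_end = min(len(genome.sequences[chrom]), de + pad)
        ref = genome.slice(chrom, region_start, region_end)
        emit_region("DECOY", 1_000_000, region_start, ref, ref, ds, de, config.decoy_depth)

    return pairs, truth_rows


def simulate_dataset(config: SimConfig, default_variants: bool = True) -> SimDataset:
    """One-call generator: genome, annotations, reads and truth."""
    genome, cores, transcripts, decoy_core = make_genome(config)
    variants = list(config.variants)
    if not variants and default_variants:
        core_len = cores[0][2] - cores[0][1]
        variants = random_variant_spec(config, core_len)
    regions = plant_variants(genome, cores, variants, config)
    pairs, truth_rows = simulate_pairs(regions, cores, config, decoy_core, genome)
    return SimDataset(
        genome=genome,
        cores=cores,
        transcripts=transcripts,
        pairs=pairs,
        truth_variants=variants,
        truth_pairs=truth_rows,
        decoy_core=decoy_core,
    )


# ---------------------------------------------------------------- file emit

def write_dataset(ds: SimDataset, out_dir, phred_offset: int = 33) -> dict:
    """Write genome FASTA, targets BED6, transcript table, paired FASTQ and
    truth TSVs; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "targets": os.path.join(out_dir, "targets.bed"),
        "transcripts": os.path.join(out_dir, "transcripts.tsv"),
        "fq1": os.path.join(out_dir, "reads_1.fastq"),
        "fq2": os.path.join(out_dir, "reads_2.fastq"),
        "truth_variants": os.path.join(out_dir, "truth_variants.tsv"),
        "truth_pairs": os.path.join(out_dir, "truth_pairs.tsv"),
    }
    with open(paths["genome"], "w") as fh:
        for name, seq in ds.genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["targets"], "w") as fh:
        for chrom, s, e, name, strand in ds.cores:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")
    with open(paths["transcripts"], "w") as fh:
        for tx in ds.transcripts:
            starts = ",".join(str(s) for s, _ in tx.blocks) + ","
            ends = ",".join(str(e) for _, e in tx.blocks) + ","
            fh.write(
                "\t".join(
                    [
                        tx.transcript_id, tx.transcript_id, tx.chrom, tx.strand,
                        str(tx.tx_start), str(tx.tx_end),
                        str(tx.cds_start), str(tx.cds_end),
                        str(len(tx.blocks)), starts, ends,
                    ]
                )
                + "\n"
            )
    with open(paths["fq1"], "w") as f1, open(paths["fq2"], "w") as f2:
        for p in ds.pairs:
            q1 = "".join(chr(q + phred_offset) for q in p.qual1)
            q2 = "".join(chr(q + phred_offset) for q in p.qual2)
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q2}\n")
    with open(paths["truth_variants"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\ttype\tzygosity\texpected_freq\n")
        chrom = ds.cores[0][0]
        for v in ds.truth_variants:
            freq = 1.0 if v.zygosity == "hom" else 0.5
            fh.write(f"{chrom}\t{v.pos}\t{v.ref}\t{v.alt if v.vtype != 'DEL' else v.alt}\t{v.vtype}\t{v.zygosity}\t{freq}\n")
    with open(paths["truth_pairs"], "w") as fh:
        fh.write("pair_id\torigin\thap\tfrag_start\tfrag_end\tclone_of\n")
        for row in ds.truth_pairs:
            fh.write(
                f"{row['pair_id']}\t{row['origin']}\t{row['hap']}\t{row['frag_start']}\t{row['frag_end']}\t{row['clone_of']}\n"
            )
    return paths
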