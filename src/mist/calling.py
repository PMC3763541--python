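"""Variant calling from clonal-corrected pileups.

A non-reference allele is called when the clonal-excluded coverage at the
site is at least ``min_coverage`` (default 15) and the allele's frequency
is at least ``min_alt_freq`` (default 0.3); Sanger follow-up in the
original study placed the false-positive regime below those values. Since
sequencing is strand-independent, both alleles should draw roughly equally
from the two strands; the signed strand skew (n+ - n-)/(n+ + n-) is
recorded per allele and a call is *flagged* (never suppressed) when the
reference and variant skews differ by more than ``skew_delta`` — a variant
whose reference allele is equally skewed remains credible.

Each call carries its 21-nt reference flank (10 nt per side) and the exact
count of that flank's genome occurrences, which exposes paralogous sites,
plus a coding-effect classification against a transcript model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from mist.pileup import PileupColumn
from mist.reference import ExonTarget, GenomeRef, TranscriptModel
from mist.seq import count_overlapping, left_align_indel, revcomp


@dataclass
class CallerConfig:
    min_coverage: int = 15
    min_alt_freq: float = 0.3
    skew_delta: float = 0.5
    flank_pad: int = 10

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0 < self.min_alt_freq <= 1):
            raise ValueError("min_alt_freq must be in (0, 1]")


@dataclass
class VariantCall:
    target_id: str
    chrom: str
    pos: int  # 1-based genomic, VCF-anchored for indels
    ref_allele: str
    alt_allele: str
    vtype: str  # SNV | INS | DEL
    coverage: int
    alt_count: int
    ref_plus: int
    ref_minus: int
    alt_plus: int
    alt_minus: int
    skew_ref: float | None = None
    skew_alt: float | None = None
    skew_flagged: bool = False
    flank21: str = ""
    flank_mappings: int = 0
    effect: str | None = None
    genotype: str = "het"

    @property
    def alt_freq(self) -> float:
        return self.alt_count / self.coverage


def strand_skew(n_plus: int, n_minus: int) -> float:
    """Signed strand imbalance in [-1, 1]; 0 means perfect balance."""
    total = n_plus + n_minus
    if total < 1:
        raise ValueError("strand skew undefined for zero total")
    return (n_plus - n_minus) / total


def skew_flag(skew_ref: float | None, skew_alt: float | None, delta: float = 0.5) -> bool:
    """Suspect iff |skew_alt - skew_ref| > delta; a skewed variant whose
    reference allele is similarly skewed is not flagged. Undefined skews
    (allele absent on both strands) never flag."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if skew_ref is None or skew_alt is None:
        return False
    return abs(skew_alt - skew_ref) > delta


def _skew_or_none(p: int, m: int) -> float | None:
    return strand_skew(p, m) if p + m > 0 else None


def _make_call(
    target: ExonTarget,
    col: PileupColumn,
    pos: int,
    ref: str,
    alt: str,
    vtype: str,
    coverage: int,
    alt_pm: tuple[int, int],
    config: CallerConfig,
) -> VariantCall:
    ref_pm = col.counts.get(col.ref_base, [0, 0])
    sr = _skew_or_none(ref_pm[0], ref_pm[1])
    sa = _skew_or_none(alt_pm[0], alt_pm[1])
    alt_count = alt_pm[0] + alt_pm[1]
    return VariantCall(
        target_id=target.target_id,
        chrom=target.chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        vtype=vtype,
        coverage=coverage,
        alt_count=alt_count,
        ref_plus=ref_pm[0],
        ref_minus=ref_pm[1],
        alt_plus=alt_pm[0],
        alt_minus=alt_pm[1],
        skew_ref=sr,
        skew_alt=sa,
        skew_flagged=skew_flag(sr, sa, config.skew_delta),
        genotype="hom" if alt_count / coverage >= 0.75 else "het",
    )


def call_variants(
    pileup: list[PileupColumn],
    target: ExonTarget,
    config: CallerConfig | None = None,
) -> list[VariantCall]:
    """Emit SNV/INS/DEL calls from one target's clonal-excluded pileup.

    Every qualifying non-reference allele at a site yields its own call.
    Runs of adjacent qualifying deletion columns are merged into a single
    left-anchored DEL; insertions are anchored at their preceding offset
    with the most frequent inserted sequence as the allele. Positions are
    converted to 1-based genomic coordinates.
    """
    config = config or CallerConfig()
    calls: list[VariantCall] = []
    n = len(pileup)

    def qualifies(cov: int, count: int) -> bool:
        return cov >= config.min_coverage and count >= config.min_alt_freq * cov

    del_run: list[int] = []

    def flush_del_run() -> None:
        if not del_run:
            return
        start = del_run[0]
        end = del_run[-1] + 1
        if start > 0:
            col = pileup[start]
            anchor = target.sequence[start - 1]
            deleted = target.sequence[start:end]
            calls.append(
                _make_call(
                    target,
                    col,
                    target.start + start,  # anchor offset start-1, 1-based
                    anchor + deleted,
                    anchor,
                    "DEL",
                    col.coverage(),
                    tuple(col.counts.get("del", [0, 0])),
                    config,
                )
            )
        del_run.clear()

    for i, col in enumerate(pileup):
        cov = col.coverage()
        if cov == 0:
            flush_del_run()
            continue
        for base in "ACGT":
            if base == col.ref_base:
                continue
            pm = col.counts.get(base)
            if pm and qualifies(cov, pm[0] + pm[1]):
                calls.append(
                    _make_call(
                        target, col, target.start + i + 1, col.ref_base, base,
                        "SNV", cov, tuple(pm), config,
                    )
                )
        dpm = col.counts.get("del")
        if dpm and qualifies(cov, dpm[0] + dpm[1]):
            if del_run and del_run[-1] == i - 1:
                del_run.append(i)
            else:
                flush_del_run()
                del_run.append(i)
        else:
            flush_del_run()
        ipm = col.counts.get("ins")
        if ipm and qualifies(cov, ipm[0] + ipm[1]) and col.ins_seqs:
            ins_seq = max(col.ins_seqs, key=lambda s: (sum(col.ins_seqs[s]), s))
            anchor = col.ref_base
            calls.append(
                _make_call(
                    target, col, target.start + i + 1, anchor, anchor + ins_seq,
                    "INS", cov, tuple(ipm), config,
                )
            )
    flush_del_run()
    # canonical leftmost placement for indels (repeat context makes
    # equivalent anchors; the truth set and the caller must agree)
    for c in calls:
        if c.vtype in ("DEL", "INS"):
            anchor = c.pos - 1 - target.start
            anchor, ref, alt = left_align_indel(target.sequence, anchor, c.ref_allele, c.alt_allele)
            c.pos = target.start + anchor + 1
            c.ref_allele, c.alt_allele = ref, alt
    calls.sort(key=lambda c: (c.chrom, c.pos, c.alt_allele))
    return calls


def flank_context(
    call: VariantCall,
    target: ExonTarget,
    genome: GenomeRef,
    flank_pad: int = 10,
) -> tuple[str, int]:
    """21-nt reference context of a call (clamped at target edges) and its
    exact occurrence count across both strands of the genome.

    A flank mapping to many locations marks a potentially paralogous call.
    """
    offset = call.pos - 1 - target.start  # offset of the (anchor) base
    lo = max(0, offset - flank_pad)
    hi = min(len(target.sequence), offset + flank_pad + 1)
    flank = target.sequence[lo:hi]
    rc = revcomp(flank)
    n = 0
    for seq in genome.sequences.values():
        n += count_overlapping(seq, flank)
        if rc != flank:
            n += count_overlapping(seq, rc)
    return flank, n


def annotate_effect(call: VariantCall, transcript: TranscriptModel | None, genome: GenomeRef) -> str | None:
    """Classify a call against one transcript model.

    SNVs inside the CDS are classified by codon comparison under the
    standard genetic code (synonymous / missense / nonsense / stop_loss);
    exonic non-CDS positions are UTR, intra-transcript non-exonic positions
    intronic, and positions in a non-coding transcript noncoding. CDS
    indels are classified frameshift vs inframe. Calls outside the
    transcript return None.
    """
    if transcript is None or call.chrom != transcript.chrom:
        return None
    pos0 = call.pos - 1
    if not (transcript.tx_start <= pos0 < transcript.tx_end):
        return None
    in_exon = any(s <= pos0 < e for s, e in transcript.blocks)
    if not in_exon:
        return "intronic"
    if not transcript.is_coding:
        return "noncoding"
    if call.vtype in ("INS", "DEL"):
        if not (transcript.cds_start <= pos0 < transcript.cds_end):
            return "UTR"
        delta = abs(len(call.alt_allele) - len(call.ref_allele))
        return "frameshift" if delta % 3 else "inframe"
    if not (transcript.cds_start <= pos0 < transcript.cds_end):
        return "UTR"
    # build the spliced CDS and locate the variant within it
    chrom_seq = genome.sequences[transcript.chrom]
    cds_seq = []
    cds_pos = None
    seen = 0
    for s, e in transcript.blocks:
        lo, hi = max(s, transcript.cds_start), min(e, transcript.cds_end)
        if lo >= hi:
            continue
        cds_seq.append(chrom_seq[lo:hi])
        if lo <= pos0 < hi:
            cds_pos = seen + (pos0 - lo)
        seen += hi - lo
    cds = "".join(cds_seq)
    if cds_pos is None:
        return "UTR"
    alt_base = call.alt_allele
    if transcript.strand == "-":
        cds = revcomp(cds)
        cds_pos = len(cds) - 1 - cds_pos
        alt_base = revcomp(alt_base)
    codon_i = cds_pos // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "UTR"  # CDS length not a multiple of 3 at the tail
    within = cds_pos % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_loss"
    return "missense"


def annotate_calls(
    calls: list[VariantCall],
    target: ExonTarget,
    genome: GenomeRef,
    transcripts: list[TranscriptModel],
    config: CallerConfig | None = None,
) -> None:
    """Attach flank context and coding effect to every call in place."""
    config = config or CallerConfig()
    for call in calls:
        call.flank21, call.flank_mappings = flank_context(call, target, genome, config.flank_pad)
        tx = next(
            (
                t
                for t in transcripts
                if t.chrom == call.chrom and t.tx_start <= call.pos - 1 < t.tx_end
            ),
            None,
        )
        call.effect = annotate_effect(call, tx, genome)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mist
##INFO=<ID=DP,Number=1,Type=Integer,Description="Clonal-excluded coverage">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=SR,Number=2,Type=Integer,Description="Reference allele strand counts (+,-)">
##INFO=<ID=SA,Number=2,Type=Integer,Description="Alternate allele strand counts (+,-)">
##INFO=<ID=SKEWR,Number=1,Type=Float,Description="Reference allele strand skew">
##INFO=<ID=SKEWA,Number=1,Type=Float,Description="Alternate allele strand skew">
##INFO=<ID=FLM,Number=1,Type=Integer,Description="Genome mappings of the 21-nt flank">
##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect">
##FILTER=<ID=skew,Description="Reference/alternate strand-skew difference exceeds threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (allele-frequency based)">
"""


def write_vcf(calls: list[VariantCall], genome: GenomeRef, config: CallerConfig | None = None) -> str:
    """Render calls as VCF 4.2 text (single sample, GT from allele frequency)."""
    order = [(c.chrom, c.pos) for c in calls]
    if order != sorted(order):
        raise ValueError("calls must be sorted by (chrom, pos)")
    lines = [_VCF_HEADER.rstrip("\n")]
    for name, seq in genome.sequences.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE")
    for c in calls:
        info = [
            f"DP={c.coverage}",
            f"AF={c.alt_freq:.6g}",
            f"SR={c.ref_plus},{c.ref_minus}",
            f"SA={c.alt_plus},{c.alt_minus}",
        ]
        if c.skew_ref is not None:
            info.append(f"SKEWR={c.skew_ref:.6g}")
        if c.skew_alt is not None:
            info.append(f"SKEWA={c.skew_alt:.6g}")
        info.append(f"FLM={c.flank_mappings}")
        if c.effect:
            info.append(f"EFF={c.effect}")
        gt = "1/1" if c.genotype == "hom" else "0/1"
        lines.append(
            "\t".join(
                [
                    c.chrom,
                    str(c.pos),
                    ".",
                    c.ref_allele,
                    c.alt_allele,
                    ".",
                    "skew" if c.skew_flagged else "PASS",
                    ";".join(info),
                    "GT",
                    gt,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def calls_to_tsv(calls: list[VariantCall]) -> str:
    """Tabular mirror of the recorded per-variant fields."""
    header = [
        "target_id", "chrom", "pos", "ref", "alt", "type", "coverage", "alt_count",
        "alt_freq", "ref_plus", "ref_minus", "alt_plus", "alt_minus",
        "skew_ref", "skew_alt", "skew_flagged", "flank21", "flank_mappings",
        "effect", "genotype",
    ]
    rows = ["\t".join(header)]
    for c in calls:
        rows.append(
            "\t".join(
                str(x) if x is not None else "."
                for x in [
                    c.target_id, c.chrom, c.pos, c.ref_allele, c.alt_allele, c.vtype,
                    c.coverage, c.alt_count, f"{c.alt_freq:.4f}",
                    c.ref_plus, c.ref_minus, c.alt_plus, c.alt_minus,
                    None if c.skew_ref is None else f"{c.skew_ref:.3f}",
                    None if c.skew_alt is None else f"{c.skew_alt:.3f}",
                    int(c.skew_flagged), c.flank21, c.flank_mappings,
                    c.effect, c.genotype,
                ]
            )
        )
    return "\n".join(rows) + "\n"
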