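"""End-to-end orchestration: reference prep -> read QC -> subset indexing ->
per-target retrieval -> paralog filter -> alignment -> clonal collapse ->
pileup -> calling -> writers.

Per-target work is independent; execution is serial but results are
contract-identical to any parallel schedule (targets are processed in
sorted order and every per-target step is deterministic).
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

from mist import calling, pileup as pileup_mod, retrieval
from mist.align import AlignScoring, LocalAligner
from mist.calling import CallerConfig, VariantCall
from mist.index import build_index
from mist.readprep import (
    DEFAULT_QC_MIN_AVG,
    DEFAULT_QC_WINDOW,
    ReadPair,
    filter_pairs,
    read_paired_fastq,
    split_subsets,
)
from mist.reference import (
    DEFAULT_EXTENSION,
    GenomeRef,
    TranscriptModel,
    extend_exon,
    load_genome,
    load_targets_bed,
    load_transcripts_table,
    merge_super_exons,
)


@dataclass
class RunConfig:
    genome: str = ""
    targets: str = ""
    fastq1: str = ""
    fastq2: str = ""
    transcripts: str | None = None
    outdir: str = "mist_out"
    tile_size: int = 25
    tile_step: int = 1
    read_tiles: int = 4
    max_genome_mappings: int = 5
    origin_window: int = 500
    insert_margin: int = 0
    qc_window: int = DEFAULT_QC_WINDOW
    qc_min_avg: float = DEFAULT_QC_MIN_AVG
    extension: int = DEFAULT_EXTENSION
    min_coverage: int = 15
    min_alt_freq: float = 0.3
    skew_delta: float = 0.5
    subsets: int = 4
    phred_offset: int = 33


@dataclass
class RunReport:
    pairs_input: int = 0
    qc_rejected: dict = field(default_factory=dict)
    pairs_passed_qc: int = 0
    candidates: int = 0
    origin_rejected: dict = field(default_factory=dict)
    pairs_retained: int = 0
    pairs_aligned: int = 0
    alignment_failures: int = 0
    clonal_members: int = 0
    calls_emitted: int = 0
    per_target: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)


def call_sample(
    genome: GenomeRef,
    core_targets: list[tuple[str, int, int, str, str]],
    pairs: list[ReadPair],
    transcripts: list[TranscriptModel] | None = None,
    config: RunConfig | None = None,
) -> tuple[list[VariantCall], dict, RunReport]:
    """Run the full pipeline in memory.

    Returns (calls, per_target_artifacts, report); ``per_target_artifacts``
    maps target_id to a dict with the target, its pileup columns and the
    per-mate alignments (for SAM/pileup writers and site dossiers).
    """
    cfg = config or RunConfig()
    transcripts = transcripts or []
    report = RunReport()
    t0 = time.perf_counter()

    # reference prep: extend each core by the flank pad, merge super-exons
    extended = [
        extend_exon((chrom, s, e), genome, cfg.extension, strand=strand,
                    target_id=name, source_ids=[name])
        for chrom, s, e, name, strand in core_targets
    ]
    targets = merge_super_exons(extended)
    report.stage_seconds["reference_prep"] = time.perf_counter() - t0

    # read QC
    t0 = time.perf_counter()
    report.pairs_input = len(pairs)
    survivors, qc_log = filter_pairs(pairs, cfg.qc_window, cfg.qc_min_avg)
    report.qc_rejected = {"ambiguous": qc_log.ambiguous, "quality": qc_log.quality}
    report.pairs_passed_qc = len(survivors)
    pairs_by_id = {p.pair_id: p for p in survivors}
    report.stage_seconds["read_qc"] = time.perf_counter() - t0

    # indexes: one per read subset (forward only) + genome (both strands)
    t0 = time.perf_counter()
    read_indexes = []
    if survivors:
        for subset in split_subsets(survivors, cfg.subsets):
            if not subset:
                continue
            subjects = {p.pair_id: p.concat for p in subset}
            if all(len(s) < cfg.tile_size for s in subjects.values()):
                continue
            read_indexes.append(
                build_index(subjects, cfg.tile_size, index_revcomp=False, subject_kind="reads")
            )
    genome_index = build_index(genome.sequences, cfg.tile_size, index_revcomp=True)
    report.stage_seconds["indexing"] = time.perf_counter() - t0

    aligner = LocalAligner(AlignScoring())
    caller_cfg = CallerConfig(
        min_coverage=cfg.min_coverage,
        min_alt_freq=cfg.min_alt_freq,
        skew_delta=cfg.skew_delta,
    )

    all_calls: list[VariantCall] = []
    artifacts: dict = {}
    t_retr = t_align = t_call = 0.0
    for target in sorted(targets, key=lambda t: (t.chrom, t.start)):
        t0 = time.perf_counter()
        rr = retrieval.run_target_retrieval(
            target, read_indexes, genome_index, pairs_by_id,
            tile_step=cfg.tile_step,
            window_span=cfg.origin_window,
            max_mappings=cfg.max_genome_mappings,
            max_tiles=cfg.read_tiles,
            insert_margin=cfg.insert_margin,
        )
        report.candidates += rr.candidate_count
        for reason, n in rr.rejections.items():
            report.origin_rejected[reason] = report.origin_rejected.get(reason, 0) + n
        report.pairs_retained += len(rr.retained)
        t_retr += time.perf_counter() - t0

        t0 = time.perf_counter()
        pair_alignments: dict = {}
        for pid in rr.retained:
            pair = pairs_by_id[pid]
            m1 = aligner.align(pair.seq1, target.sequence)
            m2 = aligner.align(pair.seq2, target.sequence)
            for mate, aln in ((1, m1), (2, m2)):
                if aln is None:
                    continue
                aln.pair_id = pid
                aln.mate = mate
                aln.target_id = target.target_id
            if m1 is None or m2 is None:
                # statistics use pair-consistent coverage only: the clonal
                # rule needs all four endpoints, and half-pairs would let
                # uncollapsible duplicates inflate coverage. They remain
                # visible in SAM (mate-unmapped flag).
                report.alignment_failures += 1
            else:
                report.pairs_aligned += 1
            pair_alignments[pid] = (m1, m2)
        both = {pid: (m1, m2) for pid, (m1, m2) in pair_alignments.items()
                if m1 is not None and m2 is not None}
        groups = pileup_mod.find_clonal_groups(both)
        report.clonal_members += sum(len(g.members) - 1 for g in groups)
        aligned_all = [aln for m1, m2 in both.values() for aln in (m1, m2)]
        columns = pileup_mod.build_pileup(aligned_all, target)
        t_align += time.perf_counter() - t0

        t0 = time.perf_counter()
        calls = calling.call_variants(columns, target, caller_cfg)
        calling.annotate_calls(calls, target, genome, transcripts, caller_cfg)
        all_calls.extend(calls)
        t_call += time.perf_counter() - t0

        report.per_target[target.target_id] = {
            "candidates": rr.candidate_count,
            "retained": len(rr.retained),
            "rejections": dict(rr.rejections),
            "clonal_groups": len(groups),
            "calls": len(calls),
        }
        artifacts[target.target_id] = {
            "target": target,
            "columns": columns,
            "pair_alignments": pair_alignments,
            "clonal_groups": groups,
        }
    report.stage_seconds["retrieval"] = t_retr
    report.stage_seconds["align_pileup"] = t_align
    report.stage_seconds["calling"] = t_call

    all_calls.sort(key=lambda c: (c.chrom, c.pos, c.alt_allele))
    report.calls_emitted = len(all_calls)
    return all_calls, artifacts, report


def write_outputs(
    calls: list[VariantCall],
    artifacts: dict,
    genome: GenomeRef,
    outdir: str,
    config: RunConfig,
    report: RunReport,
) -> dict:
    """Write calls.vcf, calls.tsv, alignments.sam, pileups/ and report.json."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "calls.vcf"),
        "tsv": os.path.join(outdir, "calls.tsv"),
        "sam": os.path.join(outdir, "alignments.sam"),
        "pileups": os.path.join(outdir, "pileups"),
        "report": os.path.join(outdir, "report.json"),
    }
    caller_cfg = CallerConfig(config.min_coverage, config.min_alt_freq, config.skew_delta)
    with open(paths["vcf"], "w") as fh:
        fh.write(calling.write_vcf(calls, genome, caller_cfg))
    with open(paths["tsv"], "w") as fh:
        fh.write(calling.calls_to_tsv(calls))
    sam_pairs = {}
    targets_by_id = {}
    for tid, art in artifacts.items():
        targets_by_id[tid] = art["target"]
        sam_pairs.update(art["pair_alignments"])
    with open(paths["sam"], "w") as fh:
        fh.write(pileup_mod.write_sam(sam_pairs, targets_by_id, genome))
    for tid, art in artifacts.items():
        pileup_mod.write_pileup_text(art["columns"], art["target"], paths["pileups"])
    with open(paths["report"], "w") as fh:
        json.dump({"config": asdict(config), "report": asdict(report)}, fh, indent=2, default=str)
    return paths


def run_pipeline(config: RunConfig) -> RunReport:
    """File-based entry point used by the CLI: load inputs, call, write."""
    genome = load_genome(config.genome)
    cores = load_targets_bed(config.targets)
    transcripts = load_transcripts_table(config.transcripts) if config.transcripts else []
    pairs = read_paired_fastq(config.fastq1, config.fastq2, config.phred_offset)
    calls, artifacts, report = call_sample(genome, cores, pairs, transcripts, config)
    write_outputs(calls, artifacts, genome, config.outdir, config, report)
    return report


def explain_site(outdir: str, chrom: str, pos: int) -> str:
    """Text dossier for one genomic site from a previous run's outputs:
    the pileup row (clonal-corrected and raw coverage), any VCF record,
    and the SAM records overlapping the site (duplicates marked)."""
    lines = [f"site {chrom}:{pos}"]
    pileup_dir = os.path.join(outdir, "pileups")
    found = False
    if os.path.isdir(pileup_dir):
        for fname in sorted(os.listdir(pileup_dir)):
            base = fname.split(".pileup")[0]
            fchrom, span = base.rsplit("_", 1)
            start0, end = (int(x) for x in span.split("-"))
            if fchrom == chrom and start0 < pos <= end:
                rel = pos - start0
                with open(os.path.join(pileup_dir, fname)) as fh:
                    for line in fh:
                        if int(line.split("\t", 1)[0]) == rel:
                            lines.append(f"pileup {fname}: {line.rstrip()}")
                            found = True
                            break
    if not found:
        lines.append("site not covered by any target fragment")
        return "\n".join(lines) + "\n"
    vcf_path = os.path.join(outdir, "calls.vcf")
    if os.path.exists(vcf_path):
        with open(vcf_path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.split("\t")
                if f[0] == chrom and int(f[1]) == pos:
                    lines.append(f"call: {line.rstrip()}")
    sam_path = os.path.join(outdir, "alignments.sam")
    if os.path.exists(sam_path):
        n_reads = n_dups = 0
        with open(sam_path) as fh:
            for line in fh:
                if line.startswith("@"):
                    continue
                f = line.split("\t")
                flag, rname, p, cigar = int(f[1]), f[2], int(f[3]), f[5]
                if flag & 0x4 or rname != chrom or cigar == "*":
                    continue
                span = sum(
                    int(n) for n, op in _cigar_tokens(cigar) if op in "MDN"
                )
                if p <= pos < p + span:
                    n_reads += 1
                    if flag & 0x400:
                        n_dups += 1
        lines.append(f"overlapping reads: {n_reads} ({n_dups} clonal duplicates)")
    return "\n".join(lines) + "\n"


def _cigar_tokens(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""
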