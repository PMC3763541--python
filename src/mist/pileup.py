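"""Clonal-pair collapse and strand-aware pileup construction.

PCR over-amplification produces clonal read pairs: several sequenced copies
of one fragment. They are recognised from paired-end alignment geometry —
two pairs are clones when at least three of the four outer alignment
endpoints (mate1 start/end, mate2 start/end on the target) coincide
exactly, which also catches copies whose one end varies from quality
trimming. Within a clonal group one representative pair is kept for
statistics; the rest are flagged and excluded from the clonal-corrected
pileup counts (they remain visible in ``raw_counts`` and in SAM output,
flagged as duplicates).

The pileup tallies per-offset, per-strand allele counts (A/C/G/T, deleted
base, insertion after the offset) over the whole extended target, emitting
zero-coverage columns too.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from mist.align import LocalAlignment
from mist.reference import ExonTarget, GenomeRef
from mist.seq import DNA_ALPHABET

ALLELES = ("A", "C", "G", "T", "del", "ins")


@dataclass
class ClonalGroup:
    members: list[str]
    representative: str
    end_signature: tuple[int, int, int, int]


@dataclass
class PileupColumn:
    """Per-base, per-strand allele tallies over one target offset.

    ``counts`` excludes clonal (non-representative) pairs; ``raw_counts``
    includes every aligned read. Keys are alleles, values [plus, minus].
    Insertion sequences observed after this offset are kept alongside the
    aggregate 'ins' count so indel calls can report an allele string.
    """

    target_id: str
    offset: int
    ref_base: str
    counts: dict[str, list[int]] = field(default_factory=dict)
    raw_counts: dict[str, list[int]] = field(default_factory=dict)
    ins_seqs: dict[str, list[int]] = field(default_factory=dict)

    def count(self, allele: str, raw: bool = False) -> int:
        table = self.raw_counts if raw else self.counts
        pm = table.get(allele)
        return pm[0] + pm[1] if pm else 0

    def coverage(self, raw: bool = False) -> int:
        """Reads covering this offset (base or deletion; insertions are
        extra events after the offset, not coverage)."""
        return sum(self.count(a, raw) for a in ("A", "C", "G", "T", "del"))


def _signature(m1: LocalAlignment, m2: LocalAlignment) -> tuple[int, int, int, int]:
    return (m1.target_start, m1.target_end, m2.target_start, m2.target_end)


def find_clonal_groups(
    pair_alignments: dict[str, tuple[LocalAlignment, LocalAlignment]],
) -> list[ClonalGroup]:
    """Greedy single-linkage grouping on the 4-endpoint signature.

    Pairs are visited in sorted pair_id order; a pair joins the first
    existing group in which *any member* shares >= 3 of 4 endpoint
    coordinates (exact integer equality), else founds a new group.
    Linking against members rather than only the group's first pair keeps
    a jittered duplicate attached to its template even when the template
    itself was absorbed earlier by a coincidentally similar fragment. The
    representative is the group's first (lexicographically smallest) pair;
    every other member has ``is_clonal`` set on both mates.
    """
    groups: list[ClonalGroup] = []
    member_sigs: list[list[tuple[int, int, int, int]]] = []
    for pid in sorted(pair_alignments):
        m1, m2 = pair_alignments[pid]
        sig = _signature(m1, m2)
        joined = None
        for g, sigs in zip(groups, member_sigs):
            if any(sum(a == b for a, b in zip(sig, s)) >= 3 for s in sigs):
                joined = g
                sigs.append(sig)
                break
        if joined is None:
            groups.append(ClonalGroup(members=[pid], representative=pid, end_signature=sig))
            member_sigs.append([sig])
        else:
            joined.members.append(pid)
            m1.is_clonal = True
            m2.is_clonal = True
    return groups


def build_pileup(
    alignments: list[LocalAlignment],
    target: ExonTarget,
    exclude_clonal: bool = True,
) -> list[PileupColumn]:
    """Walk every alignment's operations into per-offset allele tallies.

    Deletions count at each deleted offset; an insertion is attributed to
    the reference offset preceding the inserted bases (left-anchored).
    Columns with zero coverage are emitted with empty tallies.
    """
    columns = [
        PileupColumn(target_id=target.target_id, offset=i, ref_base=target.sequence[i])
        for i in range(len(target.sequence))
    ]

    def bump(table: dict[str, list[int]], allele: str, strand: str) -> None:
        pm = table.setdefault(allele, [0, 0])
        pm[0 if strand == "+" else 1] += 1

    for aln in alignments:
        si = 0 if aln.strand == "+" else 1
        clonal = aln.is_clonal and exclude_clonal
        t = aln.target_start
        r = aln.read_start
        for op, length in aln.ops:
            if op in ("M", "X"):
                for j in range(length):
                    base = aln.aligned_seq[r + j]
                    if base in DNA_ALPHABET:
                        col = columns[t + j]
                        bump(col.raw_counts, base, aln.strand)
                        if not clonal:
                            bump(col.counts, base, aln.strand)
                t += length
                r += length
            elif op == "D":
                for j in range(length):
                    col = columns[t + j]
                    bump(col.raw_counts, "del", aln.strand)
                    if not clonal:
                        bump(col.counts, "del", aln.strand)
                t += length
            elif op == "I":
                if t > 0:
                    col = columns[t - 1]
                    bump(col.raw_counts, "ins", aln.strand)
                    if not clonal:
                        bump(col.counts, "ins", aln.strand)
                        ins = aln.aligned_seq[r : r + length]
                        col.ins_seqs.setdefault(ins, [0, 0])[si] += 1
                r += length
            else:
                raise ValueError(f"unknown alignment op {op!r}")
    return columns


def _mutant_allele(col: PileupColumn) -> str | None:
    best = None
    best_n = 0
    for allele in ALLELES[:5]:
        if allele == col.ref_base:
            continue
        n = col.count(allele)
        if n > best_n:
            best, best_n = allele, n
    return best


def format_pileup_rows(columns: list[PileupColumn]) -> list[str]:
    """Five tab-separated columns per row: 1-based position relative to the
    fragment start, reference allele, total coverage with ``(+f/-r)``
    strand split, mutant-allele coverage in the same form (or '.'), and the
    mutant allele (or '.')."""
    rows = []
    for col in columns:
        p, m = 0, 0
        for allele in ("A", "C", "G", "T", "del"):
            pm = col.counts.get(allele)
            if pm:
                p += pm[0]
                m += pm[1]
        total = f"{p + m}(+{p}/-{m})"
        mut = _mutant_allele(col)
        if mut is None:
            mut_cov, mut_allele = ".", "."
        else:
            mp, mm = col.counts[mut]
            mut_cov = f"{mp + mm}(+{mp}/-{mm})"
            mut_allele = mut
        rows.append("\t".join([str(col.offset + 1), col.ref_base, total, mut_cov, mut_allele]))
    return rows


def write_pileup_text(columns: list[PileupColumn], target: ExonTarget, out_dir) -> str:
    """Write the pileup for one target; the filename carries the fragment's
    genomic position (1-based start)."""
    if any(a.offset > b.offset for a, b in zip(columns, columns[1:])):
        raise ValueError("pileup columns must be sorted by offset")
    os.makedirs(out_dir, exist_ok=True)
    fname = f"{target.chrom}_{target.start}-{target.end}.pileup.txt"
    path = os.path.join(out_dir, fname)
    with open(path, "w") as fh:
        for row in format_pileup_rows(columns):
            fh.write(row + "\n")
    return path


def _cigar(aln: LocalAlignment) -> str:
    parts = []
    if aln.read_start > 0:
        parts.append(f"{aln.read_start}S")
    for op, length in aln.ops:
        sam_op = "M" if op in ("M", "X") else op
        if parts and parts[-1].endswith(sam_op):
            prev = int(parts[-1][:-1])
            parts[-1] = f"{prev + length}{sam_op}"
        else:
            parts.append(f"{length}{sam_op}")
    tail = aln.read_length - aln.read_end
    if tail > 0:
        parts.append(f"{tail}S")
    return "".join(parts)


def write_sam(
    pair_alignments: dict[str, tuple[LocalAlignment | None, LocalAlignment | None]],
    targets: dict[str, ExonTarget],
    genome: GenomeRef,
) -> str:
    """Render alignments as SAM v1 text, lifted to genomic coordinates.

    Clonal members carry the duplicate flag (0x400); an unaligned mate is
    emitted as an unmapped record placed at its mate's position.
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in genome.sequences:
        lines.append(f"@SQ\tSN:{name}\tLN:{len(genome.sequences[name])}")
    lines.append("@PG\tID:mist\tPN:mist")
    for pid in sorted(pair_alignments):
        m1, m2 = pair_alignments[pid]
        for mate, aln, other in ((1, m1, m2), (2, m2, m1)):
            flag = 0x1 | (0x40 if mate == 1 else 0x80)
            if aln is not None and other is not None:
                flag |= 0x2
            if aln is None:
                flag |= 0x4
            if other is None:
                flag |= 0x8
            if aln is not None and aln.strand == "-":
                flag |= 0x10
            if other is not None and other.strand == "-":
                flag |= 0x20
            if aln is not None and aln.is_clonal:
                flag |= 0x400
            anchor = aln if aln is not None else other
            if anchor is None:
                continue
            tgt = targets[anchor.target_id]
            pos = tgt.start + anchor.target_start + 1
            if aln is None:
                lines.append(
                    "\t".join(
                        [pid, str(flag), tgt.chrom, str(pos), "0", "*", "=", str(pos), "0", "*", "*"]
                    )
                )
                continue
            tlen = 0
            pnext = pos
            if other is not None:
                other_tgt = targets[other.target_id]
                pnext = other_tgt.start + other.target_start + 1
                lo = min(tgt.start + aln.target_start, other_tgt.start + other.target_start)
                hi = max(tgt.start + aln.target_end, other_tgt.start + other.target_end)
                span = hi - lo
                tlen = span if pos <= pnext else -span
            lines.append(
                "\t".join(
                    [
                        pid,
                        str(flag),
                        tgt.chrom,
                        str(pos),
                        "60",
                        _cigar(aln),
                        "=",
                        str(pnext),
                        str(tlen),
                        aln.aligned_seq,
                        "*",
                    ]
                )
            )
    return "\n".join(lines) + "\n"
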