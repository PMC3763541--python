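"""Reference preparation: genome loading, exon extension, super-exon merging.

Targeted calling works against *extended* exon sequences: each core exon is
padded by a configurable flank (default 70 bp, a function of the average
insert size) so that read pairs reaching into introns still align fully.
Extended exons that overlap or touch are merged into "super-exons" so that a
read spanning a shared boundary is counted once.

Coordinates are 0-based half-open internally; emitted formats (VCF, pileup)
convert to 1-based on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO

DEFAULT_EXTENSION = 70


@dataclass
class GenomeRef:
    """A reference genome held in memory as uppercase DNA strings."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass
class ExonTarget:
    """A targeted exonic region with flanking extension.

    ``start``/``end`` are the extended bounds, ``core_start``/``core_end``
    the pre-extension exon; ``sequence`` is the genome slice of
    ``[start, end)``.
    """

    target_id: str
    chrom: str
    start: int
    end: int
    strand: str
    core_start: int
    core_end: int
    extension: int
    sequence: str
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.start <= self.core_start < self.core_end <= self.end):
            raise ValueError(
                f"{self.target_id}: core [{self.core_start},{self.core_end}) "
                f"not contained in [{self.start},{self.end})"
            )
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"{self.target_id}: sequence length mismatch")


@dataclass
class TranscriptModel:
    """Gene model used for coding-effect annotation.

    ``blocks`` are sorted, non-overlapping exon intervals; the CDS span
    [cds_start, cds_end) must lie within the blocks' union. A transcript
    with cds_start == cds_end is non-coding.
    """

    transcript_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.blocks, self.blocks[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(f"{self.transcript_id}: blocks not sorted/disjoint")

    @property
    def tx_start(self) -> int:
        return self.blocks[0][0]

    @property
    def tx_end(self) -> int:
        return self.blocks[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start


def load_genome(fasta_path) -> GenomeRef:
    """Load a FASTA file into a :class:`GenomeRef` (uppercased; N allowed)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record: {record.id}")
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record: {record.id}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return GenomeRef(sequences)


def extend_exon(
    core_interval: tuple[str, int, int],
    genome: GenomeRef,
    pad: int = DEFAULT_EXTENSION,
    *,
    strand: str = "+",
    target_id: str | None = None,
    source_ids: list[str] | None = None,
) -> ExonTarget:
    """Extend a core exon interval by ``pad`` bp on both sides, clamped to
    the chromosome, and attach the genome slice."""
    chrom, core_start, core_end = core_interval
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if chrom not in genome.sequences:
        raise ValueError(f"unknown chromosome {chrom!r}")
    chrom_len = len(genome.sequences[chrom])
    if not (0 <= core_start < core_end <= chrom_len):
        raise ValueError(
            f"core interval [{core_start},{core_end}) outside {chrom} (len {chrom_len})"
        )
    start = max(0, core_start - pad)
    end = min(chrom_len, core_end + pad)
    tid = target_id or f"{chrom}:{core_start}-{core_end}"
    return ExonTarget(
        target_id=tid,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        core_start=core_start,
        core_end=core_end,
        extension=pad,
        sequence=genome.slice(chrom, start, end),
        source_ids=list(source_ids or [tid]),
    )


def merge_super_exons(targets: list[ExonTarget]) -> list[ExonTarget]:
    """Merge overlapping or abutting extended targets into super-exons.

    The merged interval is the union of the inputs; the merged core spans
    the union of the input cores and source ids are pooled. Abutting
    (zero-overlap) targets merge too, so a boundary read is never reported
    under two targets.
    """
    if not targets:
        return []
    ordered = sorted(targets, key=lambda t: (t.chrom, t.start, t.end))
    merged: list[ExonTarget] = [replace(ordered[0], source_ids=list(ordered[0].source_ids))]
    for t in ordered[1:]:
        last = merged[-1]
        if t.chrom == last.chrom and t.start <= last.end:
            new_end = max(last.end, t.end)
            if t.end > last.end:
                seq = last.sequence + t.sequence[last.end - t.start:]
            else:
                seq = last.sequence
            src = list(dict.fromkeys(last.source_ids + t.source_ids))
            merged[-1] = ExonTarget(
                target_id=f"{last.chrom}:{last.start}-{new_end}",
                chrom=last.chrom,
                start=last.start,
                end=new_end,
                strand=last.strand if last.strand == t.strand else "+",
                core_start=min(last.core_start, t.core_start),
                core_end=max(last.core_end, t.core_end),
                extension=max(last.extension, t.extension),
                sequence=seq,
                source_ids=src,
            )
        else:
            merged.append(replace(t, source_ids=list(t.source_ids)))
    return merged


def load_targets_bed(bed_path) -> list[tuple[str, int, int, str, str]]:
    """Read core exon intervals from a BED6 (or BED4/BED3) file.

    Returns (chrom, start, end, name, strand) tuples, 0-based half-open.
    """
    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            out.append((chrom, start, end, name, strand))
    return out


def load_transcripts_table(path) -> list[TranscriptModel]:
    """Read transcript models from a refFlat-style tab table.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds (starts/ends comma-separated).
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            starts = [int(x) for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
            out.append(
                TranscriptModel(
                    transcript_id=f[1],
                    chrom=f[2],
                    strand=f[3],
                    blocks=list(zip(starts, ends)),
                    cds_start=int(f[6]),
                    cds_end=int(f[7]),
                )
            )
    return out


def targets_from_transcripts(transcripts: list[TranscriptModel]) -> list[tuple[str, int, int, str, str]]:
    """Core exon intervals (one per exon block) from transcript models."""
    out = []
    for tx in transcripts:
        for i, (s, e) in enumerate(tx.blocks):
            out.append((tx.chrom, s, e, f"{tx.transcript_id}.exon{i}", tx.strand))
    return out
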