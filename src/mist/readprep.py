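"""FASTQ pair QC, concatenation and subset splitting.

A read pair is discarded when either mate contains an ambiguous base or has
any 16-nt window with mean Phred quality < 10 (strictly). Quality scores
play no further role downstream: at calling coverage the chance of two
independent Q30 reads erring at the same site is ~1e-6, so base qualities
are not propagated past this stage.

Surviving pairs are concatenated mate1 + '$' + mate2 for indexing; the '$'
separator is outside the DNA alphabet, so no k-mer window spans the mate
junction. Pairs are split deterministically into n subsets (pair i goes to
subset i mod n) to mirror parallel index construction.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from itertools import zip_longest
from typing import Iterable, Sequence

from mist.seq import DNA_ALPHABET

PAIR_SEPARATOR = "$"
DEFAULT_QC_WINDOW = 16
DEFAULT_QC_MIN_AVG = 10.0


@dataclass
class ReadPair:
    """A paired-end read with optional per-base Phred scores."""

    pair_id: str
    seq1: str
    seq2: str
    qual1: Sequence[int] | None = None
    qual2: Sequence[int] | None = None

    def __post_init__(self) -> None:
        for seq, qual, mate in ((self.seq1, self.qual1, 1), (self.seq2, self.qual2, 2)):
            if qual is not None and len(qual) != len(seq):
                raise ValueError(f"{self.pair_id}/{mate}: quality/sequence length mismatch")

    @property
    def concat(self) -> str:
        return self.seq1 + PAIR_SEPARATOR + self.seq2


@dataclass
class RejectionLog:
    input: int = 0
    ambiguous: int = 0
    quality: int = 0
    passed: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"input": self.input, "ambiguous": self.ambiguous,
                "quality": self.quality, "passed": self.passed}


def has_ambiguous_bases(pair: ReadPair) -> bool:
    """True iff any base of either mate is outside A/C/G/T (N, IUPAC codes...)."""
    return any(c not in DNA_ALPHABET for c in pair.seq1) or any(
        c not in DNA_ALPHABET for c in pair.seq2
    )


def fails_quality_window(
    qual: Sequence[int],
    window: int = DEFAULT_QC_WINDOW,
    min_avg: float = DEFAULT_QC_MIN_AVG,
) -> bool:
    """True iff any sliding window (step 1) has mean quality strictly < min_avg.

    Reads shorter than ``window`` are judged as a single whole-read window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(qual)
    if n == 0:
        return False
    w = min(window, n)
    total = sum(qual[:w])
    if total < min_avg * w:
        return True
    for i in range(w, n):
        total += qual[i] - qual[i - w]
        if total < min_avg * w:
            return True
    return False


def filter_pairs(
    pairs: Iterable[ReadPair],
    window: int = DEFAULT_QC_WINDOW,
    min_avg: float = DEFAULT_QC_MIN_AVG,
) -> tuple[list[ReadPair], RejectionLog]:
    """Apply both QC rules pair-wise; a pair survives only if both mates pass.

    Ambiguous-base rejection is checked first, so each rejected pair is
    counted under exactly one reason (conservation: input == passed +
    ambiguous + quality).
    """
    log = RejectionLog()
    survivors: list[ReadPair] = []
    for pair in pairs:
        log.input += 1
        if has_ambiguous_bases(pair):
            log.ambiguous += 1
            continue
        bad_q = False
        for qual in (pair.qual1, pair.qual2):
            if qual is not None and fails_quality_window(qual, window, min_avg):
                bad_q = True
                break
        if bad_q:
            log.quality += 1
            continue
        log.passed += 1
        survivors.append(pair)
    return survivors, log


def split_subsets(pairs: Sequence[ReadPair], n: int = 4) -> list[list[ReadPair]]:
    """Deterministic partition: pair i goes to subset i mod n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [list(pairs[i::n]) for i in range(n)]


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _parse_fastq(handle):
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not qual and seq:
            raise ValueError("truncated FASTQ record")
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ header: {header!r}")
        yield header[1:].split()[0], seq.upper(), qual


def read_paired_fastq(path1, path2, phred_offset: int = 33) -> list[ReadPair]:
    """Read two synchronized FASTQ files (gzip-transparent) into pairs.

    Pair ids are the read names with a trailing ``/1``/``/2`` stripped; a
    record-count mismatch between the files is an error.
    """
    pairs: list[ReadPair] = []
    with _open_maybe_gzip(path1) as h1, _open_maybe_gzip(path2) as h2:
        for rec1, rec2 in zip_longest(_parse_fastq(h1), _parse_fastq(h2)):
            if rec1 is None or rec2 is None:
                raise ValueError("mate count mismatch between FASTQ files")
            name1, seq1, q1 = rec1
            name2, seq2, q2 = rec2
            pid = name1[:-2] if name1.endswith(("/1", "/2")) else name1
            pairs.append(
                ReadPair(
                    pair_id=pid,
                    seq1=seq1,
                    seq2=seq2,
                    qual1=[ord(c) - phred_offset for c in q1],
                    qual2=[ord(c) - phred_offset for c in q2],
                )
            )
    return pairs
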