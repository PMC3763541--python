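"""Exact-match k-mer index over genome or concatenated read pairs.

The retrieval stage needs one primitive: enumerate all exact occurrences of
a fixed-length tile in a subject set. With a fixed tile size a hash map of
k-mers is equivalent to a suffix array for this contract and is what is
built here. The genome index is queried on both strands (reverse-complement
occurrences are reported with strand '-'); the read index is forward-only —
tiles from both exon strands are queried against it instead.

Windows containing N (or the read-pair separator character) are never
indexed: a tile across the mate junction matches nothing real.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

from mist.seq import DNA_ALPHABET, revcomp


class Hit(NamedTuple):
    seq_id: str
    offset: int
    strand: str


@dataclass
class SequenceIndex:
    k: int
    subject_kind: str = "genome"
    index_revcomp: bool = False
    entries: dict[str, list[Hit]] = field(default_factory=dict)
    subject_lengths: dict[str, int] = field(default_factory=dict)


def build_index(
    subjects: Mapping[str, str],
    k: int,
    index_revcomp: bool = False,
    subject_kind: str = "genome",
) -> SequenceIndex:
    """Index every valid k-mer window of every subject.

    Content is deterministic regardless of mapping order: subjects are
    processed in sorted id order. ``index_revcomp`` only marks that queries
    should also be answered on the reverse strand; storage is forward k-mers
    either way.
    """
    if k < 8:
        raise ValueError("tile size k must be >= 8")
    if not subjects:
        raise ValueError("no subjects to index")
    if all(len(s) < k for s in subjects.values()):
        raise ValueError(f"k={k} larger than every subject")
    idx = SequenceIndex(k=k, subject_kind=subject_kind, index_revcomp=index_revcomp)
    entries = idx.entries
    for sid in sorted(subjects):
        seq = subjects[sid]
        idx.subject_lengths[sid] = len(seq)
        # run-aware scan: only windows of pure A/C/G/T are keyed
        valid_run = 0
        for i, c in enumerate(seq):
            valid_run = valid_run + 1 if c in DNA_ALPHABET else 0
            if valid_run >= k:
                off = i - k + 1
                entries.setdefault(seq[off : off + k], []).append(Hit(sid, off, "+"))
    return idx


def query_exact(index: SequenceIndex, tile: str) -> list[Hit]:
    """All exact occurrences of ``tile`` (reverse-complement occurrences
    included, with strand '-', when the index was built for both strands)."""
    if len(tile) != index.k:
        raise ValueError(f"tile length {len(tile)} != index k {index.k}")
    hits = list(index.entries.get(tile, ()))
    if index.index_revcomp:
        rc = revcomp(tile)
        hits.extend(Hit(h.seq_id, h.offset, "-") for h in index.entries.get(rc, ()))
    return hits


def count_genome_mappings(index: SequenceIndex, tile: str, cap: int = 5) -> int:
    """Number of genome occurrences of ``tile``, truncated at ``cap``+1.

    Any value > ``cap`` means "too many mappings"; counting past cap+1 is
    unnecessary for the discard rule.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n = len(index.entries.get(tile, ()))
    if index.index_revcomp and n <= cap:
        n += len(index.entries.get(revcomp(tile), ()))
    return min(n, cap + 1)
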