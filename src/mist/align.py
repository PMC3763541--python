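"""Optimal local alignment of retrieved reads to extended exon sequences.

Retrieval already guarantees near-identity between a surviving read and its
target, so no heuristic seeding is needed: each read is aligned with an
optimal Smith-Waterman affine-gap alignment (both orientations tried, best
kept). Scoring defaults are BLAST-like: match +1, mismatch -3, gap open -5
plus -2 per gap base (a length-L gap costs 5 + 2L). Alignments scoring
below ``min_score`` or covering less than ``min_frac`` of the read are
rejected.

The dynamic programming itself is delegated to Bio.Align.PairwiseAligner
(local mode); this module owns the scoring convention, orientation choice,
acceptance thresholds and the M/X/I/D operation decomposition used by the
pileup builder.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from mist.seq import revcomp

Op = tuple[str, int]


@dataclass(frozen=True)
class AlignScoring:
    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 30
    min_frac: float = 0.5


DEFAULT_SCORING = AlignScoring()


@dataclass
class LocalAlignment:
    """A local alignment of one mate to one target sequence.

    Coordinates are 0-based half-open; ``read_start``/``read_end`` and
    ``aligned_seq`` refer to the aligned orientation (the reverse
    complement of the input read when ``strand`` is '-'). ``ops`` is a list
    of (op, length) with op in {M (match), X (mismatch), I (insertion in
    read), D (deletion from read)}.
    """

    target_start: int
    target_end: int
    read_start: int
    read_end: int
    strand: str
    ops: list[Op]
    score: float
    aligned_seq: str
    read_length: int
    pair_id: str = ""
    mate: int = 0
    target_id: str = ""
    is_clonal: bool = False


class LocalAligner:
    """Reusable aligner bound to one scoring scheme."""

    def __init__(self, scoring: AlignScoring = DEFAULT_SCORING):
        self.scoring = scoring
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        # PairwiseAligner charges open for the first gap base and extend for
        # the rest; our convention charges open + extend per gap base.
        aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
        aligner.extend_gap_score = scoring.gap_extend
        self._aligner = aligner

    def align(self, read_seq: str, target_seq: str) -> LocalAlignment | None:
        """Best local alignment of the read (either orientation) to the
        target, or None if it fails the score/coverage thresholds."""
        if not read_seq or not target_seq:
            raise ValueError("empty sequence")
        fwd_score = self._aligner.score(target_seq, read_seq)
        rc = revcomp(read_seq)
        rev_score = self._aligner.score(target_seq, rc)
        if fwd_score >= rev_score:
            strand, seq, score = "+", read_seq, fwd_score
        else:
            strand, seq, score = "-", rc, rev_score
        if score < self.scoring.min_score:
            return None
        aln = self._aligner.align(target_seq, seq)[0]
        t_blocks, q_blocks = aln.aligned
        ops: list[Op] = []
        prev_t = prev_q = None
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            if prev_t is not None:
                if ts > prev_t:
                    ops.append(("D", int(ts - prev_t)))
                if qs > prev_q:
                    ops.append(("I", int(qs - prev_q)))
            run_op = None
            run_len = 0
            for t_i, q_i in zip(range(ts, te), range(qs, qe)):
                op = "M" if target_seq[t_i] == seq[q_i] else "X"
                if op == run_op:
                    run_len += 1
                else:
                    if run_op is not None:
                        ops.append((run_op, run_len))
                    run_op, run_len = op, 1
            if run_op is not None:
                ops.append((run_op, run_len))
            prev_t, prev_q = int(te), int(qe)
        target_start, target_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
        read_start, read_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
        if read_end - read_start < self.scoring.min_frac * len(seq):
            return None
        return LocalAlignment(
            target_start=target_start,
            target_end=target_end,
            read_start=read_start,
            read_end=read_end,
            strand=strand,
            ops=ops,
            score=float(score),
            aligned_seq=seq,
            read_length=len(seq),
        )


def align_local(
    read_seq: str,
    target_seq: str,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> LocalAlignment | None:
    """Convenience wrapper constructing a :class:`LocalAligner` per call."""
    return LocalAligner(scoring).align(read_seq, target_seq)
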