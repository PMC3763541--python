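"""Tile-based read retrieval and paralogous-pair filtering.

Candidate pairs for a target are those sharing at least one exact 25-nt
tile with the extended exon (either strand). Each candidate is then
origin-checked by a majority rule over its own tiles: up to four
non-overlapping tiles per mate are looked up in the genome index, tiles
with more than five genome mappings are dropped, remaining hits are grouped
into 500-nt origin windows, and the window supported by the most tiles is
the pair's origin. A tie means the pair is consistent with two or more loci
(gene/pseudogene, segmental duplication) and the pair is discarded; an
origin window that does not reach the target exon discards the pair as
off-target. For most exons at least one mate extends into intron, which
evolves neutrally and is copy-specific, so true-locus windows win the
majority against pseudogenes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from mist.index import SequenceIndex, query_exact
from mist.readprep import ReadPair
from mist.reference import ExonTarget
from mist.seq import DNA_ALPHABET, revcomp

DEFAULT_TILE_SIZE = 25
DEFAULT_READ_TILES = 4
DEFAULT_MAX_GENOME_MAPPINGS = 5
DEFAULT_ORIGIN_WINDOW = 500
DEFAULT_MONO_RUN = 10
DEFAULT_DI_SPAN = 12


@dataclass
class OriginWindow:
    """A candidate genomic origin for a read pair: a fixed-span window
    anchored at the smallest supporting tile-hit coordinate, scored by the
    number of distinct tiles hitting it."""

    chrom: str
    window_start: int
    window_end: int
    match_number: int


@dataclass
class RetrievalResult:
    target_id: str
    retained: list[str] = field(default_factory=list)
    rejections: Counter = field(default_factory=Counter)

    @property
    def candidate_count(self) -> int:
        return len(self.retained) + sum(self.rejections.values())


def tile_target(target_sequence: str, k: int = DEFAULT_TILE_SIZE, step: int = 1) -> list[str]:
    """All k-length tiles of the target at offsets 0, step, 2*step, ...,
    plus the final window flush with the sequence end; N-containing tiles
    are skipped."""
    L = len(target_sequence)
    if k > L:
        raise ValueError(f"sequence length {L} shorter than tile size {k}")
    if step < 1:
        raise ValueError("step must be >= 1")
    offsets = list(range(0, L - k + 1, step))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    tiles = []
    for off in offsets:
        t = target_sequence[off : off + k]
        if all(c in DNA_ALPHABET for c in t):
            tiles.append(t)
    return tiles


def is_low_complexity(
    tile: str,
    mono_run: int = DEFAULT_MONO_RUN,
    di_span: int = DEFAULT_DI_SPAN,
) -> bool:
    """True iff the tile contains a mononucleotide run >= ``mono_run`` bases
    or a period-2 (dinucleotide tandem) stretch spanning >= ``di_span``
    bases. Such tiles match pervasively and carry no positional signal."""
    n = len(tile)
    run = 1
    for i in range(1, n):
        run = run + 1 if tile[i] == tile[i - 1] else 1
        if run >= mono_run:
            return True
    span = 2
    for i in range(2, n):
        span = span + 1 if tile[i] == tile[i - 2] else 2
        if span >= di_span:
            return True
    return False


def select_read_tiles(
    read_seq: str,
    k: int = DEFAULT_TILE_SIZE,
    max_tiles: int = DEFAULT_READ_TILES,
) -> list[str]:
    """Up to ``max_tiles`` non-overlapping k-tiles, evenly spaced across the
    read including both ends; low-complexity or N-containing tiles are
    dropped without replacement. A read shorter than k yields no tiles."""
    if max_tiles < 1:
        raise ValueError("max_tiles must be >= 1")
    L = len(read_seq)
    if L < k:
        return []
    n = min(max_tiles, L // k)
    if n == 1:
        offsets = [0]
    else:
        offsets = [round(i * (L - k) / (n - 1)) for i in range(n)]
    tiles = []
    for off in offsets:
        t = read_seq[off : off + k]
        if all(c in DNA_ALPHABET for c in t) and not is_low_complexity(t):
            tiles.append(t)
    return tiles


def retrieve_candidates(read_index: SequenceIndex, tiles: list[str]) -> set[str]:
    """Pair ids whose concatenated string contains at least one tile from
    either strand of the target."""
    candidates: set[str] = set()
    seen: set[str] = set()
    for tile in tiles:
        for q in (tile, revcomp(tile)):
            if q in seen:
                continue
            seen.add(q)
            for hit in query_exact(read_index, q):
                candidates.add(hit.seq_id)
    return candidates


def assign_origin(
    pair: ReadPair,
    genome_index: SequenceIndex,
    window_span: int = DEFAULT_ORIGIN_WINDOW,
    max_mappings: int = DEFAULT_MAX_GENOME_MAPPINGS,
    max_tiles: int = DEFAULT_READ_TILES,
) -> tuple[OriginWindow | None, str | None]:
    """Majority-rule origin assignment for one read pair.

    Returns ``(window, None)`` on success or ``(None, reason)`` with reason
    in {"no_tiles", "too_many_mappings", "tie"}. Deterministic and
    independent of tile evaluation order (hits are sorted before grouping).
    """
    k = genome_index.k
    tiles = select_read_tiles(pair.seq1, k, max_tiles) + select_read_tiles(pair.seq2, k, max_tiles)
    if not tiles:
        return None, "no_tiles"

    def collect(tile_list):
        collected: list[tuple[str, int, int]] = []
        kept = False
        for tile_idx, tile in enumerate(tile_list):
            tile_hits = query_exact(genome_index, tile)
            if len(tile_hits) > max_mappings:
                continue
            kept = True
            for h in tile_hits:
                collected.append((h.seq_id, h.offset, tile_idx))
        return collected, kept

    # (chrom, pos, tile_idx) for every genome hit of every surviving tile
    hits, any_tile_kept = collect(tiles)
    if not any_tile_kept:
        return None, "too_many_mappings"
    if not hits:
        # the evenly spaced tiles all straddle variants or errors: fall
        # back to every k-mer window of both mates (the selection rule is
        # "up to" four tiles). A pair retrieved by an exact target match
        # always carries at least one mappable k-mer, so this recovers the
        # origin evidence - including ties at duplicated loci.
        dense = [
            seq[i : i + k]
            for seq in (pair.seq1, pair.seq2)
            for i in range(0, max(0, len(seq) - k + 1))
        ]
        dense = [
            t for t in dense
            if all(c in DNA_ALPHABET for c in t) and not is_low_complexity(t)
        ]
        if dense:
            hits, any_tile_kept = collect(dense)
        if not any_tile_kept:
            return None, "too_many_mappings"
        if not hits:
            # nothing in either mate maps anywhere (e.g. the only shared
            # tile was low-complexity): no ambiguity evidence against the
            # exact-match candidacy that retrieved the pair
            return None, "no_hits"
    hits.sort()
    # greedy fixed-span windows anchored at the minimum hit coordinate of
    # each cluster; all hits within [anchor, anchor+span) support the window
    windows: list[OriginWindow] = []
    i = 0
    while i < len(hits):
        chrom, anchor, _ = hits[i]
        chrom_len = genome_index.subject_lengths.get(chrom)
        end = anchor + window_span
        if chrom_len is not None:
            end = min(end, chrom_len)
        tile_ids = set()
        j = i
        while j < len(hits) and hits[j][0] == chrom and hits[j][1] < anchor + window_span:
            tile_ids.add(hits[j][2])
            j += 1
        windows.append(OriginWindow(chrom, anchor, end, len(tile_ids)))
        i = j
    best = max(w.match_number for w in windows)
    top = [w for w in windows if w.match_number == best]
    if len(top) > 1:
        return None, "tie"
    return top[0], None


def validate_origin(window: OriginWindow, target: ExonTarget, insert_margin: int = 0) -> bool:
    """True iff the origin window, widened by ``insert_margin``, reaches the
    target's core exon (closed containment: abutting coordinates count)."""
    if insert_margin < 0:
        raise ValueError("insert_margin must be >= 0")
    if window.chrom != target.chrom:
        return False
    return (
        window.window_start - insert_margin <= target.core_end
        and window.window_end + insert_margin >= target.core_start
    )


def run_target_retrieval(
    target: ExonTarget,
    read_indexes: list[SequenceIndex],
    genome_index: SequenceIndex,
    pairs_by_id: dict[str, ReadPair],
    *,
    tile_step: int = 1,
    window_span: int = DEFAULT_ORIGIN_WINDOW,
    max_mappings: int = DEFAULT_MAX_GENOME_MAPPINGS,
    max_tiles: int = DEFAULT_READ_TILES,
    insert_margin: int = 0,
) -> RetrievalResult:
    """Retrieve candidates for one target and apply the origin filter.

    ``read_indexes`` may be one index or several subset indexes; candidate
    sets are unioned, so the result is invariant to the subset count.
    """
    tiles = tile_target(target.sequence, genome_index.k, tile_step)
    candidates: set[str] = set()
    for ridx in read_indexes:
        candidates |= retrieve_candidates(ridx, tiles)
    result = RetrievalResult(target_id=target.target_id)
    for pid in sorted(candidates):
        window, reason = assign_origin(
            pairs_by_id[pid], genome_index, window_span, max_mappings, max_tiles
        )
        if window is None:
            if reason == "no_hits":
                # no tile maps anywhere: no ambiguity evidence against the
                # exact-match candidacy that retrieved the pair here
                result.retained.append(pid)
            else:
                result.rejections[reason] += 1
        elif not validate_origin(window, target, insert_margin):
            result.rejections["off_target"] += 1
        else:
            result.retained.append(pid)
    return result
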