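"""Small sequence helpers shared across modules."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def is_dna(seq: str) -> bool:
    """True iff every base is one of A/C/G/T (uppercase)."""
    return all(c in DNA_ALPHABET for c in seq)


def left_align_indel(seq: str, anchor: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Canonical leftmost representation of a pure indel.

    ``anchor`` is the 0-based offset of the shared leading base in ``seq``;
    ``ref``/``alt`` follow the VCF convention (deletion: ref = anchor +
    deleted bases, alt = anchor; insertion: ref = anchor, alt = anchor +
    inserted bases). Within a repeat, equivalent placements are shifted to
    the leftmost one.
    """
    if len(ref) > 1 and len(alt) == 1:  # deletion
        L = len(ref) - 1
        while anchor > 0 and anchor + L < len(seq) and seq[anchor] == seq[anchor + L]:
            anchor -= 1
        return anchor, seq[anchor : anchor + L + 1], seq[anchor]
    if len(alt) > 1 and len(ref) == 1:  # insertion
        ins = alt[1:]
        while anchor > 0 and ins[-1] == seq[anchor]:
            ins = seq[anchor] + ins[:-1]
            anchor -= 1
        return anchor, seq[anchor], seq[anchor] + ins
    return anchor, ref, alt


def count_overlapping(haystack: str, needle: str) -> int:
    """Number of (possibly overlapping) exact occurrences of needle."""
    if not needle:
        raise ValueError("empty query string")
    n = 0
    pos = haystack.find(needle)
    while pos != -1:
        n += 1
        pos = haystack.find(needle, pos + 1)
    return n
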