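"""Semi-global (infix) edit-distance alignment of short fragments against read segments.

A fragment is located inside a longer segment by an alignment in which the
whole fragment must align but unaligned flanks of the segment are free
("HW" mode in edlib terms).  The quality of a hit is its *alignment
identity*

    I = (|A| - E) / |A|

where ``|A|`` is the number of columns of the infix alignment (matches,
mismatches and interior gaps; free flanks excluded) and ``E`` its edit
distance.  Requiring ``I >= T`` bounds the edit distance of any admissible
hit by ``k = ceil(|f| * (1/T - 1))``, which lets the aligner prune early.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction

import edlib

__all__ = [
    "AlignmentHit",
    "FORWARD",
    "REVERSE",
    "alignment_identity",
    "max_edit_distance",
    "reverse_complement",
    "semi_global_align",
    "validate_dna",
]

FORWARD = "+"
REVERSE = "-"

_FRAGMENT_ALPHABET = frozenset("ACGT")
_READ_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def validate_dna(s: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    """Uppercase *s* and reject characters outside the DNA alphabet."""
    s = s.upper()
    alphabet = _READ_ALPHABET if allow_n else _FRAGMENT_ALPHABET
    bad = set(s) - alphabet
    if bad:
        raise ValueError(f"invalid character(s) {sorted(bad)} in {what}")
    return s


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement (N maps to N)."""
    s = validate_dna(s, allow_n=True)
    return s.translate(_COMPLEMENT)[::-1]


def alignment_identity(alignment_length: int, edit_distance: int) -> float:
    """Identity (|A| - E) / |A| of an alignment with |A| columns and E edits."""
    if alignment_length <= 0:
        raise ValueError("alignment_length must be positive")
    if not 0 <= edit_distance <= alignment_length:
        raise ValueError("edit_distance must lie in [0, alignment_length]")
    return (alignment_length - edit_distance) / alignment_length


def max_edit_distance(fragment_length: int, T: float) -> int:
    """Edit-distance cap implied by an identity threshold.

    Any infix hit of a fragment ``f`` with identity ``>= T`` satisfies
    ``E <= |A| (1-T)`` and ``|A| <= |f| + E``, hence
    ``E <= |f| (1/T - 1)``.  Alignments exceeding this bound can never
    clear the threshold and are pruned.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be positive")
    if not 0 < T <= 1:
        raise ValueError("identity threshold T must lie in (0, 1]")
    # exact rational arithmetic so e.g. T=0.75, |f|=20 gives ceil(20/3)=7
    return math.ceil(fragment_length * (1 / Fraction(T) - 1))


@dataclass(frozen=True)
class AlignmentHit:
    """One fragment located on a target segment.

    ``start``/``end`` are 0-based half-open coordinates on the segment;
    ``alignment_length`` counts aligned columns over the infix region only.
    """

    start: int
    end: int
    edit_distance: int
    alignment_length: int
    identity: float
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if self.edit_distance > self.alignment_length:
            raise ValueError("edit_distance exceeds alignment_length")

    def identity_fraction(self) -> Fraction:
        """Exact rational identity, used for deterministic tie-breaking."""
        return Fraction(self.alignment_length - self.edit_distance, self.alignment_length)


def _cigar_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))


def semi_global_align(fragment: str, segment: str, k: int) -> AlignmentHit | None:
    """Best infix alignment of *fragment* within *segment*, capped at *k* edits.

    Returns the minimum-edit-distance placement if that minimum is <= k,
    else ``None``.  Among equal-distance placements the leftmost end
    position wins, then the shortest alignment (edlib reports optimal end
    positions in ascending order and its traceback of the first one is
    deterministic).

    ``N`` bases in the segment mismatch every fragment base.
    """
    fragment = validate_dna(fragment, what="fragment")
    if not fragment:
        raise ValueError("fragment must be non-empty")
    if k < 0:
        raise ValueError("k must be non-negative")
    segment = validate_dna(segment, allow_n=True, what="segment")
    if len(segment) < 1:
        return None
    res = edlib.align(fragment, segment, mode="HW", task="path", k=k)
    dist = res["editDistance"]
    if dist < 0 or res["cigar"] is None:
        return None
    start, end_incl = res["locations"][0]
    if start is None:
        start = 0
    if end_incl < start:
        # optimum consumed no target base (every fragment base inserted, so
        # dist == |fragment|); an equal-cost alignment substitutes one
        # segment base instead — report that non-degenerate form
        return AlignmentHit(
            start=start,
            end=start + 1,
            edit_distance=dist,
            alignment_length=len(fragment),
            identity=alignment_identity(len(fragment), dist),
        )
    length = _cigar_columns(res["cigar"])
    return AlignmentHit(
        start=start,
        end=end_incl + 1,
        edit_distance=dist,
        alignment_length=length,
        identity=alignment_identity(length, dist),
    )
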