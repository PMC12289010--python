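"""Greedy recursive covering of a read by known fragments.

Every fragment in the pool is aligned (infix mode) to the uncovered
segment; the placement with the highest alignment identity wins, provided
it clears the minimum identity threshold ``T``.  The winning span is fixed,
the segment splits into the flanking sub-segments, and each is processed
recursively.  Recursion stops on segments of at most ``min_segment_len``
bases or when no fragment reaches identity ``T`` — such stretches remain
uncovered.

Ties are broken deterministically: first by exact rational identity, then
by fragment order in the library ("first fragment wins"), then forward
orientation before reverse complement, then by the positional rule of the
aligner (leftmost end, shortest alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .alignment import (
    FORWARD,
    REVERSE,
    max_edit_distance,
    reverse_complement,
    semi_global_align,
    validate_dna,
)
from .fragments import FragmentLibrary

__all__ = ["Covering", "Placement", "best_placement", "cover_read", "coverage_fraction"]

DEFAULT_T = 0.75
DEFAULT_MIN_SEGMENT_LEN = 5


@dataclass(frozen=True)
class Placement:
    """One fragment assigned to a span of a read (0-based, half-open)."""

    read_id: str
    fragment_id: str
    orientation: str
    start: int
    end: int
    edit_distance: int
    identity: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Covering:
    """The ordered, non-overlapping fragment tiling of one read."""

    read_id: str
    read_length: int
    placements: list[Placement] = field(default_factory=list)

    @property
    def uncovered(self) -> list[tuple[int, int]]:
        """Maximal uncovered intervals; together with placements they partition the read."""
        gaps = []
        pos = 0
        for p in self.placements:
            if p.start > pos:
                gaps.append((pos, p.start))
            pos = p.end
        if pos < self.read_length:
            gaps.append((pos, self.read_length))
        return gaps

    @property
    def covered_bases(self) -> int:
        return sum(len(p) for p in self.placements)

    @property
    def covered_fraction(self) -> float:
        return coverage_fraction(self)


def coverage_fraction(covering: Covering) -> float:
    """Fraction of read bases lying under a placement (0.0 for an empty read)."""
    if covering.read_length == 0:
        return 0.0
    return covering.covered_bases / covering.read_length


def _rc_cache(library: FragmentLibrary) -> dict[str, str]:
    return {f.id: reverse_complement(f.sequence) for f in library}


def best_placement(
    segment: str,
    library: FragmentLibrary,
    T: float = DEFAULT_T,
    search_rc: bool = True,
    *,
    read_id: str = "",
    offset: int = 0,
    _rc: dict[str, str] | None = None,
) -> Placement | None:
    """Highest-identity placement of any library fragment on *segment*.

    Returns ``None`` when no fragment reaches identity ``T``.  *offset*
    shifts coordinates so the placement is expressed on the full read.
    """
    if len(library) == 0:
        raise ValueError("fragment library is empty")
    if not 0 < T <= 1:
        raise ValueError("identity threshold T must lie in (0, 1]")
    threshold = Fraction(T)
    rc = _rc if _rc is not None else (_rc_cache(library) if search_rc else {})
    best: tuple[Fraction, Placement] | None = None
    for frag in library:
        k = max_edit_distance(len(frag), T)
        orientations = [(FORWARD, frag.sequence)]
        if search_rc:
            orientations.append((REVERSE, rc[frag.id]))
        for orientation, query in orientations:
            hit = semi_global_align(query, segment, k)
            if hit is None:
                continue
            ident = hit.identity_fraction()
            if ident < threshold:
                continue
            # strict > : earlier fragments and forward orientation win ties
            if best is None or ident > best[0]:
                best = (
                    ident,
                    Placement(
                        read_id=read_id,
                        fragment_id=frag.id,
                        orientation=orientation,
                        start=offset + hit.start,
                        end=offset + hit.end,
                        edit_distance=hit.edit_distance,
                        identity=hit.identity,
                    ),
                )
    return best[1] if best else None


def cover_read(
    read: str,
    library: FragmentLibrary,
    T: float = DEFAULT_T,
    min_segment_len: int = DEFAULT_MIN_SEGMENT_LEN,
    search_rc: bool = True,
    read_id: str = "read",
) -> Covering:
    """Greedy recursive fragment covering of one read.

    Segments of length <= *min_segment_len* are never aligned; a segment on
    which no fragment reaches identity ``T`` remains uncovered.  The result
    is deterministic for fixed inputs, and covering a batch of reads equals
    covering each read independently.
    """
    read = validate_dna(read, allow_n=True, what=f"read {read_id!r}")
    rc = _rc_cache(library) if search_rc else {}
    placements: list[Placement] = []
    # explicit stack; left sub-segment processed before right (convention only:
    # disjoint segments make the outcome order-independent)
    stack: list[tuple[int, int]] = [(0, len(read))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo <= min_segment_len:
            continue
        placed = best_placement(
            read[lo:hi], library, T, search_rc, read_id=read_id, offset=lo, _rc=rc
        )
        if placed is None:
            continue
        placements.append(placed)
        stack.append((placed.end, hi))
        stack.append((lo, placed.start))
    placements.sort(key=lambda p: p.start)
    return Covering(read_id=read_id, read_length=len(read), placements=placements)
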