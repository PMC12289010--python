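"""Design, mutate, validate, read and write fragment libraries.

A fragment library is the ordered pool of short known DNA sequences that
ligated products — and hence reads — are composed of.  Order matters: it is
the tie-break order when several fragments reach the same alignment
identity on a read segment.

The designer rejection-samples random sequences under three constraints a
practitioner would impose on ligation oligos:

* no homopolymer runs longer than ``max_homopolymer`` (runs are a known
  nanopore error hotspot);
* Wallace-rule melting temperature (2(A+T) + 4(G+C)) within ``tm_window``
  degrees of a per-length-class midpoint, so fragments of one length
  anneal comparably;
* mutual orthogonality: pairwise edit distance, including against reverse
  complements, of at least ``min_pairwise_edit`` across the whole library,
  so fragments are not confusable under sequencing error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .alignment import reverse_complement, validate_dna

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "LibraryDesignError",
    "design_library",
    "mutate_pool",
    "read_library",
    "similarity_pool",
    "validate_design",
    "wallace_tm",
    "write_library",
]


class LibraryDesignError(RuntimeError):
    """Raised when the rejection sampler exhausts its attempt budget."""


@dataclass(frozen=True)
class Fragment:
    id: str
    sequence: str
    role: str = "internal"  # or "cap"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, what=f"fragment {self.id!r}"))
        if not self.sequence:
            raise ValueError("fragment sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FragmentLibrary:
    """Ordered fragment pool plus the design metadata that produced it."""

    fragments: list[Fragment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise ValueError("fragment ids must be unique within a library")

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __getitem__(self, key):
        if isinstance(key, str):
            for f in self.fragments:
                if f.id == key:
                    return f
            raise KeyError(key)
        return self.fragments[key]

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.fragments]


def wallace_tm(sequence: str) -> int:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C), adequate for short oligos."""
    gc = sequence.count("G") + sequence.count("C")
    return 2 * (len(sequence) - gc) + 4 * gc


def _max_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _min_cross_edit(seq: str, others: list[str]) -> int:
    """Minimum edit distance of seq (and its rc) against every other sequence."""
    rc = reverse_complement(seq)
    best = len(seq) + max((len(o) for o in others), default=0)
    for other in others:
        for query in (seq, rc):
            d = edlib.align(query, other, mode="NW", task="distance")["editDistance"]
            best = min(best, d)
    return best


def design_library(
    lengths: list[int] | range = range(10, 21),
    per_length: int = 2,
    min_pairwise_edit: int = 4,
    tm_window: int = 4,
    max_homopolymer: int = 1,
    seed: int | np.random.Generator = 0,
    max_attempts_per_fragment: int = 200_000,
) -> FragmentLibrary:
    """Rejection-sample an orthogonal fragment library.

    The defaults produce the 22-fragment pool used throughout: two
    fragments of each length 10-20 nt, homopolymer-free, within a 4-degree
    Wallace-Tm window per length class, and pairwise edit distance >= 4 in
    both orientations across the whole library.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("lengths must be non-empty")
    if per_length < 1:
        raise ValueError("per_length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[Fragment] = []
    sequences: list[str] = []
    for n in lengths:
        # per-length Tm midpoint: balanced GC content under the Wallace rule
        tm_target = 2 * n + 2 * round(n / 2)
        for i in range(per_length):
            for attempt in range(max_attempts_per_fragment):
                seq = "".join(rng.choice(bases, size=n))
                if _max_run(seq) > max_homopolymer:
                    continue
                if abs(wallace_tm(seq) - tm_target) > tm_window:
                    continue
                if sequences and _min_cross_edit(seq, sequences) < min_pairwise_edit:
                    continue
                accepted.append(Fragment(id=f"F{n}_{i + 1}", sequence=seq))
                sequences.append(seq)
                break
            else:
                raise LibraryDesignError(
                    f"could not satisfy constraints for length {n} "
                    f"(min_pairwise_edit={min_pairwise_edit}, tm_window={tm_window}, "
                    f"max_homopolymer={max_homopolymer}) within "
                    f"{max_attempts_per_fragment} attempts"
                )
    return FragmentLibrary(
        fragments=accepted,
        metadata={
            "lengths": lengths,
            "per_length": per_length,
            "min_pairwise_edit": min_pairwise_edit,
            "tm_window": tm_window,
            "max_homopolymer": max_homopolymer,
        },
    )


def validate_design(
    library: FragmentLibrary,
    min_pairwise_edit: int = 4,
    tm_window: int = 4,
    max_homopolymer: int = 1,
) -> dict:
    """Independently re-check the design constraints on an existing library.

    Returns a report dict with the worst value observed per constraint and
    an overall ``ok`` flag; does not share code paths with the sampler's
    accept/reject test beyond the elementary Tm/run helpers.
    """
    longest_run = max(_max_run(f.sequence) for f in library)
    min_edit = min(
        _min_cross_edit(f.sequence, [g.sequence for g in library.fragments[i + 1 :]])
        for i, f in enumerate(library.fragments[:-1])
    )
    worst_tm_dev = 0
    by_length: dict[int, list[Fragment]] = {}
    for f in library:
        by_length.setdefault(len(f), []).append(f)
    for n, frags in by_length.items():
        target = 2 * n + 2 * round(n / 2)
        worst_tm_dev = max(worst_tm_dev, max(abs(wallace_tm(f.sequence) - target) for f in frags))
    ok = (
        longest_run <= max_homopolymer
        and min_edit >= min_pairwise_edit
        and worst_tm_dev <= tm_window
    )
    return {
        "ok": ok,
        "longest_homopolymer": longest_run,
        "min_pairwise_edit": min_edit,
        "max_tm_deviation": worst_tm_dev,
    }


def mutate_pool(
    base: FragmentLibrary,
    n_mutations: int,
    seed: int | np.random.Generator = 0,
) -> FragmentLibrary:
    """Derive a pool by applying exactly *n_mutations* substitutions per fragment.

    Mutated positions are distinct and each substitution changes the base,
    so every derived sequence is at edit distance <= n_mutations from its
    source (equal in the absence of coincidental equivalences).  Small
    ``n_mutations`` therefore yields a pool highly similar to *base*.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    derived: list[Fragment] = []
    for frag in base:
        if n_mutations > len(frag):
            raise ValueError(f"n_mutations={n_mutations} exceeds length of fragment {frag.id!r}")
        seq = list(frag.sequence)
        positions = rng.choice(len(seq), size=n_mutations, replace=False)
        for pos in positions:
            alternatives = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alternatives[rng.integers(len(alternatives))]
        derived.append(Fragment(id=f"{frag.id}m{n_mutations}", sequence="".join(seq), role=frag.role))
    return FragmentLibrary(fragments=derived, metadata={**base.metadata, "n_mutations": n_mutations})


def similarity_pool(
    lengths: list[int] | range = range(10, 21),
    n_mutations: int = 4,
    seed: int | np.random.Generator = 0,
    max_homopolymer: int = 1,
) -> FragmentLibrary:
    """Pool of two fragments per length whose within-pair divergence is controlled.

    For each length a random homopolymer-free fragment is drawn and paired
    with a copy carrying exactly *n_mutations* substitutions.  Small n
    gives a pool of highly similar (easily confusable) fragments; large n
    approaches an orthogonal pool.  Used to probe how fragment similarity
    degrades covering accuracy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    firsts: list[Fragment] = []
    for n in lengths:
        while True:
            seq = "".join(rng.choice(bases, size=n))
            if _max_run(seq) <= max_homopolymer:
                break
        firsts.append(Fragment(id=f"S{n}_1", sequence=seq))
    partners = mutate_pool(FragmentLibrary(firsts), n_mutations, seed=rng)
    interleaved: list[Fragment] = []
    for a, b in zip(firsts, partners):
        interleaved.append(a)
        interleaved.append(Fragment(id=a.id.replace("_1", "_2"), sequence=b.sequence))
    return FragmentLibrary(interleaved, metadata={"n_mutations": n_mutations})


# ---------------------------------------------------------------------------
# serialization: FASTA (headers are fragment ids) and CSV (id,sequence,role)


def write_library(library: FragmentLibrary, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "fasta")
    if fmt == "fasta":
        with open(path, "w") as fh:
            for frag in library:
                fh.write(f">{frag.id}\n{frag.sequence}\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "sequence", "role"])
            for frag in library:
                writer.writerow([frag.id, frag.sequence, frag.role])
    else:
        raise ValueError(f"unknown library format {fmt!r}")


def read_library(path: str | Path, fmt: str | None = None) -> FragmentLibrary:
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "fasta")
    fragments: list[Fragment] = []
    seen: set[str] = set()
    if fmt == "fasta":
        current_id: str | None = None
        chunks: list[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if current_id is not None:
                        fragments.append(Fragment(id=current_id, sequence="".join(chunks)))
                    current_id = line[1:].split()[0]
                    if not current_id:
                        raise ValueError(f"{path}:{lineno}: empty FASTA header")
                    if current_id in seen:
                        raise ValueError(f"{path}:{lineno}: duplicate fragment id {current_id!r}")
                    seen.add(current_id)
                    chunks = []
                elif current_id is None:
                    raise ValueError(f"{path}:{lineno}: sequence before first FASTA header")
                else:
                    chunks.append(line)
        if current_id is not None:
            fragments.append(Fragment(id=current_id, sequence="".join(chunks)))
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "id" not in reader.fieldnames or "sequence" not in reader.fieldnames:
                raise ValueError(f"{path}:1: CSV library requires 'id' and 'sequence' columns")
            for lineno, row in enumerate(reader, start=2):
                if row["id"] in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate fragment id {row['id']!r}")
                seen.add(row["id"])
                fragments.append(
                    Fragment(id=row["id"], sequence=row["sequence"], role=row.get("role") or "internal")
                )
    else:
        raise ValueError(f"unknown library format {fmt!r}")
    if not fragments:
        raise ValueError(f"{path}: no fragments found")
    return FragmentLibrary(fragments)
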