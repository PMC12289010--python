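"""Simulated nanopore-style reads with ground truth.

Three regimes are provided, mirroring how concatenated-fragment sequencing
runs are stress-tested:

* uniform error rates over the whole read (0%..30%);
* a positional profile with a very noisy read start — around 40% per-base
  error over the first ten bases, decaying to ~15% at base 20 and ~2%
  beyond base 40 — as observed on real nanopore data, with the tail of the
  read simulated at the mean rate of profile positions 51..100;
* fully random reads (no fragments at all), on which every reported
  placement is by construction a false positive.

Reads are built by concatenating fragments drawn uniformly with
replacement; errors are applied per emitted base, and ground-truth
fragment intervals are propagated through every edit so they stay aligned
to the mutated sequence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .fragments import FragmentLibrary

__all__ = [
    "ErrorProfile",
    "SimulatedRead",
    "TruthInterval",
    "UNIFORM_MIX",
    "apply_errors",
    "concatenate_fragments",
    "default_nanopore_profile",
    "profile_from_fastq",
    "read_truth",
    "simulate_profile_dataset",
    "simulate_random_reads",
    "simulate_uniform_dataset",
    "write_fastq",
    "write_truth",
]

# substitution / insertion / deletion shares of error events
UNIFORM_MIX = (1 / 3, 1 / 3, 1 / 3)

_BASES = np.array(list("ACGT"))
PLACEHOLDER_QUALITY = "I"  # simulated reads carry no quality model


@dataclass(frozen=True)
class TruthInterval:
    fragment_id: str
    orientation: str
    start: int
    end: int


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    truth: tuple[TruthInterval, ...] = ()


@dataclass(frozen=True)
class ErrorProfile:
    """Per-position error probabilities for the first L bases plus a tail rate."""

    per_position_rates: tuple[float, ...]
    tail_rate: float

    def __post_init__(self) -> None:
        if any(not 0 <= r <= 1 for r in self.per_position_rates) or not 0 <= self.tail_rate <= 1:
            raise ValueError("error rates must lie in [0, 1]")

    def rate(self, position: int) -> float:
        if position < len(self.per_position_rates):
            return self.per_position_rates[position]
        return self.tail_rate


def default_nanopore_profile(L: int = 100) -> ErrorProfile:
    """Positional profile shaped like real nanopore read starts.

    0.40 over positions 1-10 (1-based), linear decay to 0.15 at position
    20, linear decay to 0.02 at position 40, constant 0.02 thereafter;
    the tail rate is the mean over positions 51..100.
    """
    rates = []
    for pos in range(1, L + 1):
        if pos <= 10:
            rates.append(0.40)
        elif pos <= 20:
            rates.append(0.40 + (0.15 - 0.40) * (pos - 10) / 10)
        elif pos <= 40:
            rates.append(0.15 + (0.02 - 0.15) * (pos - 20) / 20)
        else:
            rates.append(0.02)
    tail = float(np.mean(rates[50:100])) if L >= 100 else float(np.mean(rates[len(rates) // 2 :]))
    return ErrorProfile(per_position_rates=tuple(rates), tail_rate=tail)


def concatenate_fragments(
    library: FragmentLibrary,
    n_fragments: int = 10,
    seed: int | np.random.Generator = 0,
    read_id: str = "read",
) -> SimulatedRead:
    """Error-free read: *n_fragments* fragments drawn uniformly with replacement."""
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if len(library) == 0:
        raise ValueError("fragment library is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts: list[str] = []
    truth: list[TruthInterval] = []
    pos = 0
    for _ in range(n_fragments):
        frag = library[int(rng.integers(len(library)))]
        parts.append(frag.sequence)
        truth.append(TruthInterval(frag.id, "+", pos, pos + len(frag)))
        pos += len(frag)
    return SimulatedRead(read_id=read_id, sequence="".join(parts), truth=tuple(truth))


def apply_errors(
    read: SimulatedRead,
    profile_or_rate: ErrorProfile | float,
    mix: tuple[float, float, float] = UNIFORM_MIX,
    seed: int | np.random.Generator = 0,
    *,
    return_edit_positions: bool = False,
) -> SimulatedRead | tuple[SimulatedRead, tuple[int, ...]]:
    """Introduce sequencing errors, keeping truth intervals aligned.

    Each source base independently suffers an edit with the probability
    attached to its output position (so a positional profile tracks
    position-in-the-sequenced-read).  Substitutions pick a different base
    uniformly; insertions insert one uniform base before the current base;
    deletions drop the base.  An insertion falling on an interval boundary
    is assigned to the left interval.
    """
    if abs(sum(mix) - 1) > 1e-9 or any(m < 0 for m in mix):
        raise ValueError("mix must be three non-negative numbers summing to 1")
    if isinstance(profile_or_rate, ErrorProfile):
        rate_at = profile_or_rate.rate
    else:
        r = float(profile_or_rate)
        if not 0 <= r <= 1:
            raise ValueError("error rate must lie in [0, 1]")
        rate_at = lambda _pos: r  # noqa: E731
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_sub, p_ins, _ = mix
    out: list[str] = []
    n = len(read.sequence)
    newpos = [0] * (n + 1)  # source offset -> output offset
    edit_positions: list[int] = []
    for i, base in enumerate(read.sequence):
        event = None
        if rng.random() < rate_at(len(out)):
            u = rng.random()
            event = "sub" if u < p_sub else ("ins" if u < p_sub + p_ins else "del")
            # an insertion before base i belongs to the interval left of i,
            # except at the very start of the read where no left interval exists
            edit_positions.append(i - 1 if event == "ins" and i > 0 else i)
        if event == "ins":
            out.append(str(rng.choice(_BASES)))
        newpos[i] = len(out)  # after any insertion: boundary insertions go left
        if event == "sub":
            out.append(str(rng.choice([b for b in "ACGT" if b != base])))
        elif event != "del":
            out.append(base)
    newpos[n] = len(out)
    newpos[0] = 0  # an insertion before the first base belongs to the first interval
    truth = tuple(
        replace(t, start=newpos[t.start], end=newpos[t.end]) for t in read.truth
    )
    result = SimulatedRead(read_id=read.read_id, sequence="".join(out), truth=truth)
    if return_edit_positions:
        return result, tuple(edit_positions)
    return result


# ---------------------------------------------------------------------------
# dataset-level generators


def _simulate_dataset(
    library: FragmentLibrary,
    n_reads: int,
    n_fragments: int,
    profile_or_rate: ErrorProfile | float,
    seed: int | np.random.Generator,
    prefix: str,
    mix: tuple[float, float, float] = UNIFORM_MIX,
) -> list[SimulatedRead]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        clean = concatenate_fragments(library, n_fragments, rng, read_id=f"{prefix}_{i:05d}")
        reads.append(apply_errors(clean, profile_or_rate, mix, rng))
    return reads


def simulate_uniform_dataset(
    library: FragmentLibrary,
    n_reads: int = 1000,
    n_fragments: int = 10,
    rate: float = 0.05,
    seed: int | np.random.Generator = 0,
    mix: tuple[float, float, float] = UNIFORM_MIX,
) -> list[SimulatedRead]:
    """Concatenated-fragment reads under a uniform per-base error rate."""
    tag = f"sim{int(round(rate * 100))}"
    return _simulate_dataset(library, n_reads, n_fragments, rate, seed, tag, mix)


def simulate_profile_dataset(
    library: FragmentLibrary,
    n_reads: int = 1000,
    n_fragments: int = 10,
    profile: ErrorProfile | None = None,
    seed: int | np.random.Generator = 0,
    mix: tuple[float, float, float] = UNIFORM_MIX,
) -> list[SimulatedRead]:
    """Concatenated-fragment reads under a positional (non-uniform) error profile."""
    if profile is None:
        profile = default_nanopore_profile()
    return _simulate_dataset(library, n_reads, n_fragments, profile, seed, "simnu", mix)


def simulate_random_reads(
    n_reads: int = 1000,
    read_length: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[SimulatedRead]:
    """Reads of i.i.d. uniform bases; every placement on them is a false positive."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        seq = "".join(rng.choice(_BASES, size=read_length))
        reads.append(SimulatedRead(read_id=f"simrand_{i:05d}", sequence=seq))
    return reads


# ---------------------------------------------------------------------------
# FASTQ / truth-table I/O


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    """Phred+33 FASTQ with a constant placeholder quality (covering ignores qualities)."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{PLACEHOLDER_QUALITY * len(read.sequence)}\n")


def write_truth(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates: 0-based, half-open\n")
        writer = csv.writer(fh)
        writer.writerow(["read_id", "ordinal", "fragment_id", "orientation", "start", "end"])
        for read in reads:
            for ordinal, t in enumerate(read.truth):
                writer.writerow([read.read_id, ordinal, t.fragment_id, t.orientation, t.start, t.end])


def read_truth(path: str | Path) -> dict[str, list[TruthInterval]]:
    truths: dict[str, list[TruthInterval]] = {}
    with open(path, newline="") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows):
            truths.setdefault(row["read_id"], []).append(
                TruthInterval(
                    fragment_id=row["fragment_id"],
                    orientation=row["orientation"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
    return truths


def profile_from_fastq(path: str | Path, L: int = 100) -> ErrorProfile:
    """Positional error profile from FASTQ Phred+33 qualities.

    Per-position mean of p = 10^(-Q/10) over all reads covering that
    position, for the first *L* positions; the tail rate is the mean over
    positions 51..100 (1-based).
    """
    from Bio import SeqIO

    sums = np.zeros(L)
    counts = np.zeros(L, dtype=np.int64)
    n_reads = 0
    for record in SeqIO.parse(str(path), "fastq"):
        n_reads += 1
        quals = record.letter_annotations["phred_quality"][:L]
        probs = 10 ** (-np.asarray(quals, dtype=float) / 10)
        sums[: len(probs)] += probs
        counts[: len(probs)] += 1
    if n_reads == 0:
        raise ValueError(f"{path}: no FASTQ records")
    with np.errstate(invalid="ignore"):
        rates = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    lo, hi = min(50, L), min(100, L)
    tail_block = rates[lo:hi][counts[lo:hi] > 0]
    tail = float(tail_block.mean()) if tail_block.size else float(rates[counts > 0].mean())
    return ErrorProfile(per_position_rates=tuple(rates.tolist()), tail_rate=tail)
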