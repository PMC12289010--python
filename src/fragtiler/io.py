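"""Reading reads, and the two CSV outputs of a covering run.

All CSV coordinates are 0-based, half-open; every file starts with a
comment line saying so.  The placements CSV has one row per detected
fragment (a read with several fragments occupies several rows), grouped by
read and sorted by start; the coverage CSV has one row per read with the
percentage of its bases lying under a placement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .covering import Covering, Placement

__all__ = [
    "RunConfig",
    "read_fastq",
    "read_placements",
    "write_coverage_csv",
    "write_placements_csv",
]

COORDINATE_COMMENT = "# coordinates: 0-based, half-open\n"


@dataclass
class RunConfig:
    """Parameters of one covering run."""

    identity_threshold: float = 0.75
    min_segment_len: int = 5
    search_rc: bool = True
    seed: int = 0
    threads: int = 1  # per-read parallelism contract; results are order-stable

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity threshold T must lie in (0, 1]")
        if self.min_segment_len < 0:
            raise ValueError("min_segment_len must be >= 0")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, uppercase sequence) from a Phred+33 FASTQ file."""
    try:
        for record in SeqIO.parse(str(path), "fastq"):
            yield record.id, str(record.seq).upper()
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ ({exc})") from exc


def write_placements_csv(coverings: list[Covering], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(COORDINATE_COMMENT)
        writer = csv.writer(fh)
        writer.writerow(
            ["read_id", "fragment_id", "orientation", "start", "end", "edit_distance", "identity"]
        )
        for covering in coverings:
            for p in covering.placements:
                writer.writerow(
                    [p.read_id, p.fragment_id, p.orientation, p.start, p.end,
                     p.edit_distance, f"{p.identity:.4f}"]
                )


def write_coverage_csv(coverings: list[Covering], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(COORDINATE_COMMENT)
        writer = csv.writer(fh)
        writer.writerow(["read_id", "read_length", "covered_bases", "percent_covered"])
        for c in coverings:
            writer.writerow(
                [c.read_id, c.read_length, c.covered_bases, f"{100 * c.covered_fraction:.1f}"]
            )


def read_placements(path: str | Path) -> dict[str, list[Placement]]:
    """Parse a placements CSV back into per-read placement lists."""
    placements: dict[str, list[Placement]] = {}
    with open(path, newline="") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows):
            placements.setdefault(row["read_id"], []).append(
                Placement(
                    read_id=row["read_id"],
                    fragment_id=row["fragment_id"],
                    orientation=row["orientation"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    edit_distance=int(row["edit_distance"]),
                    identity=float(row["identity"]),
                )
            )
    return placements
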