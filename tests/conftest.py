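"""Shared fixtures and the independent quadratic infix-alignment oracle.

The oracle is a plain dynamic program kept deliberately separate from the
production aligner (which delegates to edlib): tests that compare the two
are meaningful only while they share no code.
"""

import numpy as np
import pytest

import fragtiler as ft


def infix_edit_distance(fragment: str, segment: str) -> int:
    """Minimum edit distance of fragment aligned inside segment, O(|f|·|s|).

    Free leading/trailing segment bases: row 0 is all zeros and the answer
    is the minimum over the last row.  N never matches.
    """
    m, n = len(fragment), len(segment)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if fragment[i - 1] == segment[j - 1] != "N" else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev) if m else 0


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


@pytest.fixture(scope="session")
def library() -> ft.FragmentLibrary:
    """Designed orthogonal 22-fragment pool (two per length 10-20 nt)."""
    return ft.design_library(seed=1)


@pytest.fixture(scope="session")
def tiny_library() -> ft.FragmentLibrary:
    """Hand-picked orthogonal pool for exact, hand-checkable cases."""
    return ft.FragmentLibrary(
        [
            ft.Fragment("F1", "ACGTACGTGA"),
            ft.Fragment("F2", "TGCATGCACT"),
            ft.Fragment("F3", "GACTGACTTG"),
        ]
    )
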