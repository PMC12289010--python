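"""Tests for read simulation, error application, and the profile extractor."""

import numpy as np
import pytest
from scipy import stats

import fragtiler as ft
from fragtiler.simulate import (
    ErrorProfile,
    SimulatedRead,
    TruthInterval,
    apply_errors,
    concatenate_fragments,
    default_nanopore_profile,
    profile_from_fastq,
    read_truth,
    simulate_profile_dataset,
    simulate_random_reads,
    simulate_uniform_dataset,
    write_fastq,
    write_truth,
)


def assert_truth_tiles(read: SimulatedRead):
    pos = 0
    for t in read.truth:
        assert t.start == pos and t.end >= t.start
        pos = t.end
    assert pos == len(read.sequence)


# --- concatenation --------------------------------------------------------


def test_single_fragment_read(tiny_library):
    r = concatenate_fragments(tiny_library, 1, seed=0)
    assert len(r.truth) == 1
    t = r.truth[0]
    assert (t.start, t.end) == (0, len(r.sequence))
    assert r.sequence == tiny_library[t.fragment_id].sequence


def test_ten_fragment_read_length_and_tiling(library):
    r = concatenate_fragments(library, 10, seed=1)
    assert 100 <= len(r.sequence) <= 200
    assert len(r.truth) == 10
    assert_truth_tiles(r)
    for t in r.truth:
        assert r.sequence[t.start : t.end] == library[t.fragment_id].sequence


# --- error application ----------------------------------------------------


def test_rate_zero_is_identity(library):
    clean = concatenate_fragments(library, 10, seed=2)
    noisy = apply_errors(clean, 0.0, seed=3)
    assert noisy.sequence == clean.sequence and noisy.truth == clean.truth


def test_deletion_only_at_rate_one_empties_read(tiny_library):
    clean = concatenate_fragments(tiny_library, 3, seed=4)
    gone = apply_errors(clean, 1.0, mix=(0, 0, 1), seed=5)
    assert gone.sequence == ""
    assert all(t.start == t.end == 0 for t in gone.truth)


def test_error_count_within_binomial_bounds():
    n = 10_000
    read = SimulatedRead("r", "A" * n, ())
    noisy = apply_errors(read, 0.1, mix=(1.0, 0.0, 0.0), seed=6)
    n_subs = sum(1 for b in noisy.sequence if b != "A")
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.1)
    assert lo <= n_subs <= hi


def test_invalid_mix_rejected(tiny_library):
    clean = concatenate_fragments(tiny_library, 2, seed=0)
    with pytest.raises(ValueError):
        apply_errors(clean, 0.1, mix=(0.5, 0.5, 0.5), seed=0)


def test_truth_coordinates_propagate_through_errors(library):
    """Each propagated interval differs from its source fragment by at most
    the number of edits that fell inside that interval."""
    import edlib

    rng = np.random.default_rng(7)
    for _ in range(20):
        clean = concatenate_fragments(library, 8, seed=rng)
        noisy, edits = apply_errors(clean, 0.1, seed=rng, return_edit_positions=True)
        assert_truth_tiles(noisy)
        for src, t in zip(clean.truth, noisy.truth):
            n_inside = sum(1 for pos in edits if src.start <= pos < src.end)
            piece = noisy.sequence[t.start : t.end]
            frag = library[t.fragment_id].sequence
            d = edlib.align(frag, piece, mode="NW", task="distance")["editDistance"]
            assert d <= n_inside


def test_positional_profile_hits_requested_rates():
    """Empirical per-position error frequency matches the profile within binomial bounds."""
    profile = ErrorProfile(per_position_rates=(0.4,) * 10 + (0.02,) * 90, tail_rate=0.02)
    n = 2000
    rng = np.random.default_rng(8)
    first_pos_errors = 0
    for _ in range(n):
        read = SimulatedRead("r", "ACGTACGTACGTACGTACGT", ())
        noisy = apply_errors(read, profile, mix=(1, 0, 0), seed=rng)
        if noisy.sequence[0] != "A":
            first_pos_errors += 1
    # substitutions change the base 100% of the time at position 0
    lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.4)
    assert lo <= first_pos_errors <= hi


# --- dataset generators ---------------------------------------------------


def test_uniform_dataset_shape(library):
    reads = simulate_uniform_dataset(library, n_reads=20, n_fragments=10, rate=0.05, seed=9)
    assert len(reads) == 20
    for r in reads:
        assert len(r.truth) == 10
        assert_truth_tiles(r)


def test_profile_dataset_zero_profile_is_error_free(library):
    profile = ErrorProfile(per_position_rates=(0.0,) * 100, tail_rate=0.0)
    reads = simulate_profile_dataset(library, n_reads=5, profile=profile, seed=10)
    for r in reads:
        assert_truth_tiles(r)
        for t in r.truth:
            assert r.sequence[t.start : t.end] == library[t.fragment_id].sequence


def test_default_profile_shape():
    p = default_nanopore_profile()
    assert p.per_position_rates[0] == pytest.approx(0.40)
    assert p.per_position_rates[19] == pytest.approx(0.15)
    assert p.per_position_rates[45] == pytest.approx(0.02)
    assert p.tail_rate == pytest.approx(np.mean(p.per_position_rates[50:100]))


def test_random_reads_properties():
    reads = simulate_random_reads(n_reads=100, read_length=1000, seed=11)
    assert all(len(r.sequence) == 1000 and r.truth == () for r in reads)
    counts = np.array(
        [sum(r.sequence.count(b) for r in reads) for b in "ACGT"], dtype=float
    )
    # 99% multinomial bound per base on 100,000 draws
    lo, hi = stats.binom.ppf([0.0025, 0.9975], 100_000, 0.25)
    assert all(lo <= c <= hi for c in counts)


def test_seed_determinism_bytes(library, tmp_path):
    for i, out in enumerate(["a.fastq", "b.fastq"]):
        reads = simulate_uniform_dataset(library, n_reads=10, rate=0.1, seed=13)
        write_fastq(reads, tmp_path / out)
        write_truth(reads, tmp_path / out.replace(".fastq", ".csv"))
    assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_truth_round_trip(library, tmp_path):
    reads = simulate_uniform_dataset(library, n_reads=5, rate=0.05, seed=14)
    write_truth(reads, tmp_path / "truth.csv")
    back = read_truth(tmp_path / "truth.csv")
    for r in reads:
        assert back[r.read_id] == list(r.truth)


# --- profile extraction ---------------------------------------------------


def _write_fastq(path, records):
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def test_profile_from_constant_qualities(tmp_path):
    path = tmp_path / "r.fastq"
    _write_fastq(path, [("r1", "A" * 120, "I" * 120)])  # Q40
    p = profile_from_fastq(path)
    assert all(r == pytest.approx(1e-4) for r in p.per_position_rates)
    assert p.tail_rate == pytest.approx(1e-4)


def test_profile_q10_gives_rate_point_one(tmp_path):
    path = tmp_path / "r.fastq"
    _write_fastq(path, [("r1", "A" * 100, "+" * 100)])  # Q10
    p = profile_from_fastq(path)
    assert p.per_position_rates[0] == pytest.approx(0.1)


def test_profile_averages_across_reads(tmp_path):
    path = tmp_path / "r.fastq"
    _write_fastq(path, [("r1", "A", "+"), ("r2", "A", "5")])  # Q10 and Q20
    p = profile_from_fastq(path, L=1)
    assert p.per_position_rates[0] == pytest.approx((0.1 + 0.01) / 2)


def test_profile_empty_fastq_is_error(tmp_path):
    path = tmp_path / "empty.fastq"
    path.write_text("")
    with pytest.raises(ValueError):
        profile_from_fastq(path)
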