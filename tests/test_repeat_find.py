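from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from cmsscan.genome_io import CircularGenome, reverse_complement
from cmsscan.repeat_find import (
    RepeatError,
    RepeatPair,
    find_repeats,
    predict_subgenomes,
    verify_repeat,
)
from ._oracles import brute_force_repeats
from .conftest import random_dna


def _plant(rng, n, copies, min_len=500):
    """Random linear-style sequence with planted repeat copies.

    ``copies``: list of (position, core, orientation) — guard bases around
    each copy stop maximal extension at the core length.
    """
    seq = list(random_dna(rng, n))
    for i, (pos, core, orient) in enumerate(copies):
        body = core if orient == "+" else reverse_complement(core)
        guard = "AC"[i % 2]
        seq[pos : pos + len(body) + 2] = guard + body + guard
    return "".join(seq)


def test_planted_direct_repeat_found_exactly(rng):
    core = random_dna(rng, 600)
    seq = _plant(rng, 2200, [(100, core, "+"), (1300, core, "+")])
    g = CircularGenome("g", seq, circular=False)
    pairs = find_repeats(g, min_repeat_length=500)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.length, p.orientation) == (600, "direct")
    assert (p.pos_a, p.pos_b) == (101, 1301)
    assert verify_repeat(g, p)


def test_planted_inverted_repeat_found(rng):
    core = random_dna(rng, 600)
    seq = _plant(rng, 2200, [(100, core, "+"), (1300, core, "-")])
    g = CircularGenome("g", seq, circular=False)
    pairs = find_repeats(g, min_repeat_length=500)
    assert len(pairs) == 1
    assert pairs[0].orientation == "inverted"
    assert pairs[0].length == 600
    assert verify_repeat(g, pairs[0])


def test_repeat_free_sequence_yields_nothing(rng):
    for _ in range(5):
        seq = random_dna(rng, 3000)
        if not brute_force_repeats(seq, 100):
            g = CircularGenome("g", seq, circular=False)
            assert find_repeats(g, min_repeat_length=100) == []
            return
    pytest.fail("could not draw a repeat-free random sequence")


def test_equivalence_with_quadratic_bruteforce(rng):
    core_a = random_dna(rng, 160)
    core_b = random_dna(rng, 140)
    seq = _plant(
        rng,
        1600,
        [(50, core_a, "+"), (700, core_a, "+"), (1000, core_b, "+"), (1350, core_b, "-")],
        min_len=100,
    )
    g = CircularGenome("g", seq, circular=False)
    found = {
        (p.length, p.pos_a, p.pos_b, p.orientation)
        for p in find_repeats(g, min_repeat_length=100)
    }
    oracle = {
        hit for hit in brute_force_repeats(seq, 100)
    }
    assert found == oracle


def test_min_length_monotonicity(rng):
    core = random_dna(rng, 800)
    seq = _plant(rng, 3000, [(100, core, "+"), (1800, core, "+")])
    g = CircularGenome("g", seq, circular=False)
    lax = find_repeats(g, min_repeat_length=400)
    strict = find_repeats(g, min_repeat_length=900)
    assert len(strict) <= len(lax)


def test_origin_spanning_repeat_found(rng):
    core = random_dna(rng, 600)
    left = random_dna(rng, 900)
    right = random_dna(rng, 700)
    # second copy wraps the origin: its tail occupies the genome start
    seq = core[300:] + "A" + left + "C" + core + "C" + right + core[:300]
    g = CircularGenome("g", seq, circular=True)
    pairs = find_repeats(g, min_repeat_length=500)
    assert any(p.length >= 600 and verify_repeat(g, p) for p in pairs)


def test_all_reported_pairs_verify(study_sim):
    cms = study_sim.genomes["cms"]
    pairs = find_repeats(cms)
    assert all(verify_repeat(cms, p) for p in pairs)
    assert sorted(p.length for p in pairs) == sorted(
        r.length for r in study_sim.truth.repeats
    )


@pytest.mark.parametrize(
    "pos_a,pos_b,expected", [(10, 60, (50, 50)), (10, 30, (20, 80))]
)
def test_subgenome_sizes(pos_a, pos_b, expected, rng):
    g = CircularGenome("g", random_dna(rng, 100))
    rep = RepeatPair(length=10, pos_a=pos_a, pos_b=pos_b, orientation="direct")
    assert predict_subgenomes(g, rep).circle_sizes == expected


@given(st.integers(200, 5000), st.data())
def test_subgenome_sizes_sum_to_genome_length(L, data):
    pos_a = data.draw(st.integers(0, L - 2))
    pos_b = data.draw(st.integers(pos_a + 1, L - 1))
    g = CircularGenome("g", "ACGT" * ((L + 3) // 4))
    g = CircularGenome("g", g.sequence[:L])
    rep = RepeatPair(length=50, pos_a=pos_a, pos_b=pos_b, orientation="direct")
    sizes = predict_subgenomes(g, rep).circle_sizes
    assert sizes[0] + sizes[1] == L


def test_inverted_repeat_has_no_subgenomes(rng):
    g = CircularGenome("g", random_dna(rng, 500))
    rep = RepeatPair(length=50, pos_a=10, pos_b=200, orientation="inverted")
    with pytest.raises(RepeatError):
        predict_subgenomes(g, rep)
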