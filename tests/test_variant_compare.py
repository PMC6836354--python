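from __future__ import annotations

import itertools

import pytest

from cmsscan.genome_io import CircularGenome
from cmsscan.orf_screen import CODON_TABLE
from cmsscan.synthetic_data import simulate_divergent_copy
from cmsscan.variant_compare import (
    VariantError,
    classify_substitution,
    compare_cds,
    summarize_genome_diff,
)


def test_hand_checked_substitution():
    snps, indels = compare_cds("demo", "ATGGAATAA", "ATGAAATAA")
    assert indels == []
    assert len(snps) == 1
    s = snps[0]
    assert (s.cds_position, s.ref_nt, s.alt_nt) == (4, "G", "A")
    assert (s.ref_aa, s.alt_aa) == ("E", "K")
    assert s.effect == "nonsynonymous"
    assert s.substitution_class == "transition"
    assert s.codon_index == 2


def test_identical_cds_yield_no_records():
    assert compare_cds("x", "ATGAAATAA", "ATGAAATAA") == ([], [])


@pytest.mark.parametrize(
    "ref,alt,expected",
    [("C", "T", "transition"), ("A", "G", "transition"), ("C", "A", "transversion")],
)
def test_classify_substitution_examples(ref, alt, expected):
    assert classify_substitution(ref, alt) == expected


def test_all_twelve_ordered_pairs_split_4_to_8():
    classes = [
        classify_substitution(a, b)
        for a, b in itertools.permutations("ACGT", 2)
    ]
    assert classes.count("transition") == 4
    assert classes.count("transversion") == 8


def test_identical_nucleotides_not_a_variant():
    with pytest.raises(VariantError):
        classify_substitution("A", "A")


def test_fourfold_degenerate_third_positions_always_synonymous():
    fourfold = [
        p for p in ("GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT")
        if len({CODON_TABLE[p + b] for b in "ACGT"}) == 1
    ]
    assert len(fourfold) == 8  # sanity: the standard code has 8 such families
    for prefix in fourfold:
        for b1, b2 in itertools.permutations("ACGT", 2):
            snps, _ = compare_cds(
                "x", "ATG" + prefix + b1 + "TAA", "ATG" + prefix + b2 + "TAA"
            )
            assert [s.effect for s in snps] == ["synonymous"]


def test_compare_is_symmetric_with_ref_alt_swapped(rng):
    codons = [c for c, aa in CODON_TABLE.items() if aa not in "*M"]
    a = "ATG" + "".join(rng.choice(codons, size=60)) + "TAA"
    b = list(a)
    for p in rng.choice(range(3, len(a) - 3), size=8, replace=False):
        b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[p]]
    b = "".join(b)
    fwd, _ = compare_cds("g", a, b)
    rev, _ = compare_cds("g", b, a)
    assert {(s.cds_position, s.ref_nt, s.alt_nt) for s in fwd} == {
        (s.cds_position, s.alt_nt, s.ref_nt) for s in rev
    }
    assert {s.effect for s in fwd} == {s.effect for s in rev}


def test_in_frame_indel_reported_in_amino_acids():
    a = "ATG" + "GAA" * 40 + "TAA"
    b = a[:60] + "CAGCCGAGCAAGCAACCGAGCAAGCAACCGAGC" + a[60:]  # 33 nt
    snps, indels = compare_cds("rps3", a, b)
    assert snps == []
    assert len(indels) == 1
    i = indels[0]
    assert i.length == 33
    assert i.in_frame and i.aa_length == 11
    assert i.kind == "insertion"


def test_internal_stop_warns():
    with pytest.warns(UserWarning):
        compare_cds("x", "ATGTAAAAATAA", "ATGTAAAAATAA")


def test_planted_snp_recovery_on_trio(tiny_sim):
    truth = {
        (s.gene, s.cds_position, s.ref_nt, s.alt_nt, s.effect, s.substitution_class)
        for s in tiny_sim.truth.snps
        if s.scope == "cms_vs_maintainer"
    }
    g = tiny_sim.genomes
    maint_cds = {
        a.gene_name: a.extract(g["maintainer"]) for a in tiny_sim.annotations["maintainer"]
    }
    cms_cds = {a.gene_name: a.extract(g["cms"]) for a in tiny_sim.annotations["cms"]}
    found = set()
    for gene in maint_cds:
        if gene in cms_cds:
            snps, _ = compare_cds(gene, maint_cds[gene], cms_cds[gene])
            found |= {
                (s.gene, s.cds_position, s.ref_nt, s.alt_nt, s.effect, s.substitution_class)
                for s in snps
            }
    assert found == truth


def test_genome_diff_identical(rng):
    from .conftest import random_dna

    g = CircularGenome("a", random_dna(rng, 2000))
    diff = summarize_genome_diff(g, g, min_block=100)
    assert diff.snp_count == 0
    assert diff.gap_count == 0
    assert diff.identity == 100.0


def test_genome_diff_recovers_planted_variants():
    a, b, truth = simulate_divergent_copy(length=40_000, n_snps=12, n_gaps=8, seed=3)
    diff = summarize_genome_diff(a, b)
    assert diff.snp_count == truth["snps"]
    assert diff.gap_count == truth["gaps"]
    assert diff.gap_length_histogram[">5"] == 0
    assert diff.coverage > 99.0
    assert 99.0 < diff.identity < 100.0


def test_genome_diff_unrelated_genomes_warns(rng):
    from .conftest import random_dna

    a = CircularGenome("a", random_dna(rng, 3000))
    b = CircularGenome("b", random_dna(rng, 3000))
    with pytest.warns(UserWarning):
        diff = summarize_genome_diff(a, b)
    assert diff.snp_count == 0 and diff.identity == 0.0
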