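from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from cmsscan.genome_io import (
    CircularGenome,
    FeatureAnnotation,
    GenomeError,
    annotation_summary,
    circular_slice,
    gc_content,
    read_genome,
    reverse_complement,
    write_genome,
)

dna = st.text(alphabet="ACGTN", min_size=1, max_size=200)


def test_fasta_parsing_uppercases_and_maps_u(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text(">g1 test\nacgu\n")
    genome, anns = read_genome(p, "fasta")
    assert genome.sequence == "ACGT"
    assert genome.id == "g1"
    assert anns == []


def test_genbank_join_coordinates(tmp_path):
    record = "\n".join(
        [
            "LOCUS       test                 100 bp    DNA     circular PLN 01-JAN-2020",
            "FEATURES             Location/Qualifiers",
            "     CDS             join(10..30,50..70)",
            '                     /gene="demo"',
            "ORIGIN",
            "        1 "
            + " ".join("acgtacgtac" for _ in range(6))[:66].strip(),
            "//",
        ]
    )
    p = tmp_path / "t.gb"
    p.write_text(record)
    genome, anns = read_genome(p, "genbank")
    assert len(anns) == 1
    assert anns[0].gene_name == "demo"
    # GenBank 1-based inclusive -> 0-based half-open
    assert anns[0].segments == [(9, 30, "+"), (49, 70, "+")]


def test_invalid_characters_rejected():
    with pytest.raises(GenomeError):
        CircularGenome("bad", "ACGTR")
    with pytest.raises(GenomeError):
        CircularGenome("empty", "")


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 50.0), ("AANT", 0.0), ("GGCC", 100.0), ("ACT", 33.33)],
)
def test_gc_content_examples(seq, expected):
    assert gc_content(CircularGenome("x", seq)) == expected


def test_gc_content_rounds_half_up():
    # 9 G+C of 16 counted bases = 56.25 -> stays; 1/8 = 12.50 exact;
    # half-up case: 5/16 = 31.25 must NOT round to 31.2
    assert gc_content("G" * 5 + "A" * 11) == 31.25
    assert gc_content("GCA") == pytest.approx(66.67)


def test_gc_content_all_n_is_error():
    with pytest.raises(GenomeError):
        gc_content(CircularGenome("n", "NNNN"))


@given(dna)
def test_gc_invariant_under_reverse_complement(seq):
    if set(seq) <= {"N"}:
        return
    assert gc_content(seq) == gc_content(reverse_complement(seq))


def test_circular_slice_wraps():
    g = CircularGenome("g", "ACGTACGTAC", circular=True)
    assert g.slice(8, 13) == "AC" + "ACG"
    assert g.slice(0, 10) == g.sequence


def test_linear_slice_beyond_end_errors():
    g = CircularGenome("g", "ACGT", circular=False)
    with pytest.raises(GenomeError):
        g.slice(2, 6)


@given(st.data())
def test_circular_slice_matches_doubled_string(data):
    seq = data.draw(st.text(alphabet="ACGT", min_size=2, max_size=50))
    g = CircularGenome("g", seq)
    start = data.draw(st.integers(0, len(seq) - 1))
    length = data.draw(st.integers(0, len(seq)))
    assert circular_slice(g, start, start + length) == (seq + seq)[start : start + length]


@given(st.text(alphabet="ACGTN", min_size=1, max_size=100))
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_reverse_complement_examples():
    assert reverse_complement("ATGC") == "GCAT"
    assert reverse_complement("NNA") == "TNN"
    with pytest.raises(GenomeError):
        reverse_complement("AXG")


def test_annotation_summary_counts():
    g = CircularGenome("g", "ACGT" * 30)
    assert annotation_summary(g, [])["CDS"] == 0
    anns = [
        FeatureAnnotation("a", "CDS", [(0, 9, "+")]),
        FeatureAnnotation("b", "CDS", [(10, 19, "-")]),
        FeatureAnnotation("c", "CDS", [(20, 29, "+")]),
        FeatureAnnotation("t", "tRNA", [(30, 40, "+")]),
        FeatureAnnotation("t", "tRNA", [(50, 60, "+")]),  # IR-style duplicate
    ]
    summary = annotation_summary(g, anns)
    assert summary["CDS"] == 3
    assert summary["tRNA"] == 2
    assert summary["rRNA"] == 0
    assert summary["duplicated"] == 1
    assert summary["length_bp"] == 120


def test_genbank_round_trip_preserves_sequence_and_coordinates(tmp_path, tiny_sim):
    genome = tiny_sim.genomes["maintainer"]
    anns = tiny_sim.annotations["maintainer"]
    out = tmp_path / "m.gb"
    write_genome(genome, out, "genbank", annotations=anns)
    back, back_anns = read_genome(out, "genbank")
    assert back.sequence == genome.sequence
    assert {(a.gene_name, tuple(a.segments)) for a in back_anns} == {
        (a.gene_name, tuple(a.segments)) for a in anns
    }


def test_feature_extraction_respects_strand(tiny_sim):
    genome = tiny_sim.genomes["maintainer"]
    for ann in tiny_sim.annotations["maintainer"]:
        cds = ann.extract(genome)
        assert cds.startswith("ATG"), ann.gene_name
        assert cds[-3:] in {"TAA", "TAG", "TGA"}
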