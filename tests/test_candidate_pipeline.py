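from __future__ import annotations

import pytest

from cmsscan.candidate_pipeline import (
    PipelineError,
    assign_origin,
    detect_chimera,
    genomic_context,
    rank_candidates,
)
from cmsscan.genome_io import CircularGenome, FeatureAnnotation, reverse_complement
from cmsscan.orf_screen import OrfRecord, translate
from cmsscan.tm_predict import TmResult
from .conftest import random_dna


def _orf(nt: str, orf_id="orfX", start=0, strand="+") -> OrfRecord:
    protein = translate(nt[:-3])
    return OrfRecord(
        orf_id=orf_id,
        genome_id="g",
        start=start,
        end=start + len(nt),
        strand=strand,
        nt_length=len(nt),
        sequence=nt,
        protein=protein,
        protein_length=len(protein),
    )


def _coding(rng, n_codons):
    body = "".join(rng.choice(["GAA", "AAG", "CAA", "AGC", "CCG", "GGA"], size=n_codons))
    return "ATG" + body + "TAA"


def test_core_gene_copy_is_not_chimeric(rng):
    gene = _coding(rng, 200)
    orf = _orf(gene)
    assert detect_chimera(orf, {"cox1": gene}) == []


def test_random_orf_has_no_chimera(rng):
    orf = _orf(_coding(rng, 150))
    genes = {"atp8": random_dna(rng, 500), "cox1": random_dna(rng, 1500)}
    assert detect_chimera(orf, genes) == []


def test_empty_core_set_rejected(rng):
    with pytest.raises(PipelineError):
        detect_chimera(_orf(_coding(rng, 120)), {})


def _build_chimeric_orf(rng, gene, frag_codons=58, inverted=False):
    """Frame-safe chimeric ORF: a codon-aligned gene fragment (~98% id)
    embedded between filler codons; retried until stop-free."""
    for _ in range(50):
        frag_len = 3 * frag_codons
        frag = list(gene[120 : 120 + frag_len])
        for p in rng.choice(frag_len, size=round(frag_len * 0.02), replace=False):
            frag[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[p]]
        body = "".join(frag)
        if inverted:
            body = reverse_complement(body)
        nt = _coding(rng, 80)[:-3] + body + _coding(rng, 90)[3:]
        if "*" not in translate(nt[:-3]):
            return _orf(nt)
    raise AssertionError("could not build a stop-free chimeric ORF")


def test_planted_fragment_detected(rng):
    gene = _coding(rng, 250)  # 753 nt, atp8-like
    orf = _build_chimeric_orf(rng, gene)  # 174 nt fragment @ ~98%
    hits = detect_chimera(orf, {"atp8": gene, "other": random_dna(rng, 900)})
    assert len(hits) == 1
    hit = hits[0]
    assert hit.core_gene == "atp8"
    assert 164 <= hit.fragment_length <= 184
    assert hit.identity >= 96.0


def test_chimera_detection_is_strand_safe(rng):
    gene = _coding(rng, 250)
    h_fwd = detect_chimera(_build_chimeric_orf(rng, gene), {"atp8": gene})
    h_rev = detect_chimera(_build_chimeric_orf(rng, gene, inverted=True), {"atp8": gene})
    assert len(h_fwd) == 1 and len(h_rev) == 1
    assert abs(h_fwd[0].fragment_length - h_rev[0].fragment_length) <= 6
    assert h_fwd[0].strand == "+"
    assert h_rev[0].strand == "-"


def test_context_overlapping_gene_is_distance_zero(rng):
    orf = _orf(_coding(rng, 110), start=100)
    anns = [FeatureAnnotation("nad1", "CDS", [(50, 600, "+")])]
    ctx = genomic_context(orf, anns, 10_000)
    assert ctx.gene_name == "nad1"
    assert ctx.distance == 0


def test_context_gap_upstream_of_gene(rng):
    orf = _orf(_coding(rng, 110), start=1000)  # ends at 1336
    anns = [
        FeatureAnnotation("nad3", "CDS", [(1439, 1700, "+")]),  # 103 bp right
        FeatureAnnotation("far", "CDS", [(5000, 5600, "+")]),
    ]
    ctx = genomic_context(orf, anns, 10_000)
    assert ctx.gene_name == "nad3"
    assert ctx.distance == 103
    assert ctx.relative_position == "upstream"


def test_context_without_annotations_is_none(rng):
    assert genomic_context(_orf(_coding(rng, 110)), [], 5000) is None


def test_context_wraps_around_origin(rng):
    orf = _orf(_coding(rng, 110), start=9000)  # ends 9336 on a 9400 circle
    anns = [FeatureAnnotation("gene", "CDS", [(36, 500, "+")])]
    ctx = genomic_context(orf, anns, 9400)
    assert ctx.distance == 100  # 64 to origin + 36 beyond it


def test_origin_assignment(rng):
    donor_seq = random_dna(rng, 8000)
    recipient_seq = random_dna(rng, 8000)
    orf_nt = _coding(rng, 140)
    donor = CircularGenome("d", donor_seq[:4000] + orf_nt + donor_seq[4000:])
    recipient = CircularGenome("r", recipient_seq)
    orf = _orf(orf_nt)
    assert assign_origin(orf, donor, recipient) == "donor_identical"
    assert assign_origin(orf, recipient, donor) == "recipient_identical"
    # half-donor, half-recipient chimera across the two parents
    half = len(orf_nt) // 2
    donor2 = CircularGenome("d2", donor_seq[:4000] + orf_nt[:half] + donor_seq[4000:])
    recipient2 = CircularGenome("r2", recipient_seq[:2000] + orf_nt[half:] + recipient_seq[2000:])
    assert assign_origin(orf, donor2, recipient2) == "recombinant"
    assert assign_origin(orf, CircularGenome("x", random_dna(rng, 5000)),
                         CircularGenome("y", random_dna(rng, 5000))) == "novel"


def test_origin_never_recombinant_for_identical_parents(rng):
    seq = random_dna(rng, 6000)
    orf_nt = _coding(rng, 140)
    g = CircularGenome("g", seq[:3000] + orf_nt + seq[3000:])
    orf = _orf(orf_nt)
    assert assign_origin(orf, g, g) != "recombinant"


def test_rank_candidates_tiers(rng):
    orfs = [_orf(_coding(rng, 120), orf_id=f"orf{i}") for i in range(3)]
    tm = {
        "orf0": TmResult("orf0", [(5, 30)], 1),
        "orf1": TmResult("orf1", [], 0),
        "orf2": TmResult("orf2", [(5, 30)], 1),
    }
    from cmsscan.candidate_pipeline import ChimeraHit

    chim = {
        "orf0": [ChimeraHit("orf0", "atp8", 175, 98.0, (10, 185), (5, 180))],
        "orf1": [ChimeraHit("orf1", "cox1", 133, 98.0, (10, 143), (5, 138))],
        "orf2": [],
    }
    reports = rank_candidates(orfs, tm, chim)
    tiers = {r.orf_id: r.rank_tier for r in reports}
    assert tiers == {"orf0": "candidate", "orf1": "supporting", "orf2": "supporting"}
    # candidate tier is the intersection of all three evidence classes
    for r in reports:
        if r.rank_tier == "candidate":
            assert r.specific and r.tm_count >= 1 and r.chimera


def test_rank_candidates_empty_and_mismatched(rng):
    assert rank_candidates([], {}, {}) == []
    orfs = [_orf(_coding(rng, 120), orf_id="orfA")]
    with pytest.raises(PipelineError):
        rank_candidates(orfs, {}, {"orfA": []})
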