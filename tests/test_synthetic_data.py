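from __future__ import annotations

import pytest

from cmsscan.genome_io import read_genome, reverse_complement
from cmsscan.orf_screen import translate
from cmsscan.synthetic_data import (
    DEFAULT_SNP_PLAN,
    SimConfig,
    SimulationError,
    simulate_trio,
    write_fixture_bundle,
)


def test_same_seed_is_byte_identical():
    a = simulate_trio(SimConfig.tiny(7))
    b = simulate_trio(SimConfig.tiny(7))
    for role in ("donor", "maintainer", "cms"):
        assert a.genomes[role].sequence == b.genomes[role].sequence


def test_different_seeds_differ():
    a = simulate_trio(SimConfig.tiny(1))
    b = simulate_trio(SimConfig.tiny(2))
    assert a.genomes["cms"].sequence != b.genomes["cms"].sequence


def test_truth_table_is_complete(tiny_sim):
    cfg = SimConfig.tiny(0)
    truth = tiny_sim.truth
    assert len(truth.orfs) == len(cfg.specific_orf_plan)
    assert len(truth.repeats) == len(cfg.repeat_plan)
    assert len(truth.snps) == len(cfg.snp_plan) + len(cfg.donor_private_snp_plan)
    assert len(truth.indels) == len(cfg.indel_plan)
    labels = [o.label for o in truth.orfs]
    assert len(set(labels)) == len(labels)


def test_planted_orfs_present_verbatim_in_cms_and_donor(tiny_sim):
    cms = tiny_sim.genomes["cms"].sequence
    donor = tiny_sim.genomes["donor"].sequence
    maintainer = tiny_sim.genomes["maintainer"].sequence
    for orf in tiny_sim.truth.orfs:
        body = orf.sequence if orf.strand == "+" else reverse_complement(orf.sequence)
        assert cms.count(body) == 1, orf.label
        assert donor.count(body) == 1, orf.label
        assert body not in maintainer, orf.label
        s, e = orf.cms_interval
        assert cms[s:e] == body


def test_planted_repeats_verbatim(tiny_sim):
    cms = tiny_sim.genomes["cms"].sequence
    for rep in tiny_sim.truth.repeats:
        a, b = rep.cms_positions
        copy_a = cms[a : a + rep.length]
        copy_b = cms[b : b + rep.length]
        if rep.orientation == "direct":
            assert copy_a == copy_b
        else:
            assert copy_a == reverse_complement(copy_b)


def test_synonymous_plants_never_change_protein(tiny_sim):
    g = tiny_sim.genomes
    maint = {a.gene_name: a.extract(g["maintainer"]) for a in tiny_sim.annotations["maintainer"]}
    cms = {a.gene_name: a.extract(g["cms"]) for a in tiny_sim.annotations["cms"]}
    syn_genes = {
        s.gene
        for s in tiny_sim.truth.snps
        if s.scope == "cms_vs_maintainer" and s.effect == "synonymous"
    }
    nonsyn = {
        s.gene for s in tiny_sim.truth.snps if s.effect == "nonsynonymous"
    }
    indel_genes = {i.gene for i in tiny_sim.truth.indels}
    for gene in syn_genes - nonsyn - indel_genes:
        assert translate(maint[gene]) == translate(cms[gene]), gene


def test_snp_plan_defaults_match_study_composition():
    effects = [s.effect for s in DEFAULT_SNP_PLAN]
    classes = [s.substitution_class for s in DEFAULT_SNP_PLAN]
    assert len(DEFAULT_SNP_PLAN) == 26
    assert effects.count("synonymous") == 10
    assert effects.count("nonsynonymous") == 16
    assert classes.count("transition") == 18
    assert len({s.gene for s in DEFAULT_SNP_PLAN}) == 12


def test_recipient_only_gene_absent_from_donor(tiny_sim):
    donor_genes = {a.gene_name for a in tiny_sim.annotations["donor"]}
    cms_genes = {a.gene_name for a in tiny_sim.annotations["cms"]}
    maint_genes = {a.gene_name for a in tiny_sim.annotations["maintainer"]}
    for gene in tiny_sim.truth.recipient_only_genes:
        assert gene not in donor_genes
        assert gene in cms_genes and gene in maint_genes


def test_infeasible_packing_raises():
    cfg = SimConfig.tiny(0)
    cfg.genome_length_donor = 30_000  # smaller than the planted features
    with pytest.raises(SimulationError):
        simulate_trio(cfg)


def test_fixture_bundle_round_trips(tmp_path):
    cfg = SimConfig.tiny(0)
    outdir = write_fixture_bundle(cfg, tmp_path / "bundle")
    reference = simulate_trio(cfg)
    for role in ("donor", "maintainer", "cms"):
        genome, _ = read_genome(outdir / f"{role}.fasta", "fasta")
        assert genome.sequence == reference.genomes[role].sequence
        assert (outdir / f"{role}.gff3").exists()
    gb, anns = read_genome(outdir / "maintainer.gb", "genbank")
    assert gb.sequence == reference.genomes["maintainer"].sequence
    assert len(anns) == len(reference.annotations["maintainer"])
    # truth files are bookkeeping only; the pipeline inputs stand alone
    import pandas as pd

    truth_orfs = pd.read_csv(outdir / "truth_orfs.tsv", sep="\t")
    assert len(truth_orfs) == len(reference.truth.orfs)
    (outdir / "truth_orfs.tsv").unlink()
    genome2, _ = read_genome(outdir / "cms.fasta", "fasta")
    assert genome2.sequence == reference.genomes["cms"].sequence
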