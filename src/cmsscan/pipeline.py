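"""End-to-end screen: ORFs -> specificity -> TM -> chimera -> context ->
origin -> ranking, plus variant, repeat and collinearity summaries.

This is the orchestration layer the CLI drives; each stage delegates to
its module and logs a machine-parsable per-stage count to stderr
(``stage=<name> n=<count>``).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import pandas as pd

from .align_core import ScoringScheme
from .candidate_pipeline import (
    CandidateReport,
    ChimeraHit,
    NearestGene,
    assign_origin,
    detect_chimera,
    genomic_context,
    rank_candidates,
)
from .config import RunConfig
from .genome_io import CircularGenome, FeatureAnnotation
from .orf_screen import OrfRecord, OrfScreenParams, call_presence, find_orfs
from .repeat_find import RepeatPair, find_repeats, predict_subgenomes
from .synteny import compare_genomes
from .tm_predict import TmResult, predict_tm
from .variant_compare import IndelRecord, SnpRecord, compare_cds


def _log(stage: str, n: int) -> None:
    print(f"stage={stage} n={n}", file=sys.stderr)


@dataclass
class PipelineResult:
    orfs: list[OrfRecord]
    specific: list[OrfRecord]
    tm: dict[str, TmResult]
    chimera: dict[str, list[ChimeraHit]]
    context: dict[str, NearestGene | None]
    origin: dict[str, str]
    candidates: list[CandidateReport]
    snps: list[SnpRecord]
    indels: list[IndelRecord]
    gene_presence: dict[str, str]  # gene -> which genome is missing it
    repeats: list[RepeatPair]
    synteny_vs_donor: dict[str, float] = field(default_factory=dict)
    synteny_vs_maintainer: dict[str, float] = field(default_factory=dict)

    def candidate_ids(self) -> list[str]:
        return [r.orf_id for r in self.candidates if r.rank_tier == "candidate"]

    def summary(self) -> dict:
        syn = sum(1 for s in self.snps if s.effect == "synonymous")
        return {
            "n_orfs": len(self.orfs),
            "n_specific": len(self.specific),
            "n_tm_positive": sum(
                1 for o in self.specific if self.tm[o.orf_id].count >= 1
            ),
            "n_candidates": len(self.candidate_ids()),
            "candidates": self.candidate_ids(),
            "snp_total": len(self.snps),
            "snp_synonymous": syn,
            "snp_nonsynonymous": len(self.snps) - syn,
            "snp_transitions": sum(
                1 for s in self.snps if s.substitution_class == "transition"
            ),
            "indels": [
                {"gene": i.gene, "length": i.length, "aa": i.aa_length}
                for i in self.indels
            ],
            "repeat_lengths": [r.length for r in self.repeats],
            "synteny_vs_donor": self.synteny_vs_donor,
            "synteny_vs_maintainer": self.synteny_vs_maintainer,
        }


def _cds_sequences(
    genome: CircularGenome, annotations: list[FeatureAnnotation]
) -> dict[str, str]:
    return {
        a.gene_name: a.extract(genome)
        for a in annotations
        if a.feature_type == "CDS"
    }


def run_full_pipeline(
    cms: CircularGenome,
    maintainer: CircularGenome,
    cms_annotations: list[FeatureAnnotation],
    maintainer_annotations: list[FeatureAnnotation],
    donor: CircularGenome | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run every stage on a cms/maintainer (and optionally donor) trio.

    The donor genome only feeds the origin stage; without it every ORF's
    origin is reported as unassigned ("novel").
    """
    config = config or RunConfig()
    scheme = ScoringScheme(
        config.alignment.match,
        config.alignment.mismatch,
        config.alignment.gap_open,
        config.alignment.gap_extend,
    )
    orf_params = OrfScreenParams(
        config.orf.min_protein_length, config.orf.coverage_min, config.orf.identity_min
    )

    orfs = find_orfs(cms, orf_params.min_protein_length)
    _log("orfs", len(orfs))
    specific = [
        orf
        for orf in orfs
        if call_presence(
            orf, maintainer, orf_params.coverage_min, orf_params.identity_min
        ).verdict
        == "absent"
    ]
    _log("specific", len(specific))

    tm = {
        orf.orf_id: predict_tm(
            orf.protein,
            threshold=config.tm.threshold,
            window=config.tm.window,
            min_segment_length=config.tm.min_segment_length,
            merge_gap=config.tm.merge_gap,
            orf_id=orf.orf_id,
        )
        for orf in specific
    }
    _log("tm", sum(1 for t in tm.values() if t.count >= 1))

    core_genes = _cds_sequences(maintainer, maintainer_annotations)
    chimera = {
        orf.orf_id: detect_chimera(
            orf,
            core_genes,
            min_fragment=config.chimera.min_fragment,
            min_identity=config.chimera.min_identity,
            scheme=scheme,
        )
        for orf in specific
    }
    _log("chimera", sum(1 for h in chimera.values() if h))

    context = {
        orf.orf_id: genomic_context(orf, cms_annotations, len(cms))
        for orf in specific
    }
    origin = {
        orf.orf_id: (
            assign_origin(orf, donor, maintainer) if donor is not None else "novel"
        )
        for orf in specific
    }
    candidates = rank_candidates(specific, tm, chimera, context, origin)
    _log("candidates", len([r for r in candidates if r.rank_tier == "candidate"]))

    # orthologous CDS comparison (maintainer as reference, cms as alternate)
    cms_cds = _cds_sequences(cms, cms_annotations)
    snps: list[SnpRecord] = []
    indels: list[IndelRecord] = []
    gene_presence: dict[str, str] = {}
    for gene in sorted(set(core_genes) | set(cms_cds)):
        if gene not in cms_cds:
            gene_presence[gene] = "absent_in_cms"
            continue
        if gene not in core_genes:
            gene_presence[gene] = "absent_in_maintainer"
            continue
        s, i = compare_cds(gene, core_genes[gene], cms_cds[gene], scheme)
        snps.extend(s)
        indels.extend(i)
    _log("snps", len(snps))

    repeats = find_repeats(
        cms, min_repeat_length=config.repeats.min_repeat_length, k=config.repeats.k
    )
    _log("repeats", len(repeats))

    syn_kwargs = dict(
        k=config.synteny.k,
        max_gap=config.synteny.max_gap,
        min_block=config.synteny.min_block,
        gap_identity_floor=config.synteny.gap_identity_floor,
        max_unbalanced=config.synteny.max_unbalanced,
    )
    synteny_vs_maintainer = _synteny_summary(cms, maintainer, syn_kwargs)
    synteny_vs_donor = (
        _synteny_summary(cms, donor, syn_kwargs) if donor is not None else {}
    )
    _log("synteny", int(synteny_vs_maintainer.get("n_blocks", 0)))

    return PipelineResult(
        orfs=orfs,
        specific=specific,
        tm=tm,
        chimera=chimera,
        context=context,
        origin=origin,
        candidates=candidates,
        snps=snps,
        indels=indels,
        gene_presence=gene_presence,
        repeats=repeats,
        synteny_vs_donor=synteny_vs_donor,
        synteny_vs_maintainer=synteny_vs_maintainer,
    )


def _synteny_summary(query, ref, kwargs) -> dict[str, float]:
    from .synteny import anchor_map, chain_blocks

    blocks, summary = chain_blocks(
        anchor_map(query, ref, k=kwargs["k"]),
        query,
        ref,
        max_gap=kwargs["max_gap"],
        min_block=kwargs["min_block"],
        gap_identity_floor=kwargs["gap_identity_floor"],
        max_unbalanced=kwargs["max_unbalanced"],
    )
    return summary


# ---------------------------------------------------------------------------
# tabular report helpers (Table 3/4/5 analogues)


def candidates_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for rep in result.candidates:
        best = rep.chimera[0] if rep.chimera else None
        rows.append(
            {
                "orf_id": rep.orf_id,
                "tier": rep.rank_tier,
                "tm_count": rep.tm_count,
                "chimeric_gene": best.core_gene if best else "",
                "fragment_bp": best.fragment_length if best else 0,
                "fragment_identity": best.identity if best else "",
                "nearest_gene": rep.nearest_gene.gene_name if rep.nearest_gene else "",
                "distance_bp": rep.nearest_gene.distance if rep.nearest_gene else "",
                "orf_position": rep.nearest_gene.relative_position
                if rep.nearest_gene
                else "",
                "origin": rep.origin,
            }
        )
    return pd.DataFrame(rows)


def snps_table(result: PipelineResult) -> pd.DataFrame:
    rows = [
        {
            "gene": s.gene,
            "cds_position": s.cds_position,
            "change": f"{s.ref_nt}-{s.alt_nt}",
            "codon": s.codon_index,
            "aa_change": f"{s.ref_aa}-{s.alt_aa}" if s.effect == "nonsynonymous" else "S",
            "effect": s.effect,
            "class": s.substitution_class,
        }
        for s in result.snps
    ]
    return pd.DataFrame(rows)


def repeats_table(result: PipelineResult, genome: CircularGenome) -> pd.DataFrame:
    rows = []
    for rep in result.repeats:
        row = {
            "length": rep.length,
            "pos_a": rep.pos_a + 1,
            "pos_b": rep.pos_b + 1,
            "orientation": rep.orientation,
            "identity": rep.identity,
        }
        if rep.orientation == "direct" and genome.circular:
            sizes = predict_subgenomes(genome, rep).circle_sizes
            row["subcircles"] = f"{sizes[0]}+{sizes[1]}"
        rows.append(row)
    return pd.DataFrame(rows)
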