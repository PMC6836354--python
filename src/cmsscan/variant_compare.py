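"""Orthologous CDS comparison and coding-variant classification.

Between a CMS line and its maintainer the handful of coding differences is
the short-list for functional divergence, so each substitution is labelled
synonymous/non-synonymous (from its codon context) and
transition/transversion, and each gap run becomes an indel record with its
frame consequence (a multiple-of-3 indel inserts/deletes whole codons).

Whole-genome comparisons (e.g. the near-identical chloroplast pair) are
summarized from synteny blocks as total SNP and gap counts with a gap
length histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

from .align_core import ScoringScheme, global_align
from .genome_io import CircularGenome
from .orf_screen import CODON_TABLE, STOP_CODONS, translate
from . import synteny as _synteny

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class VariantError(ValueError):
    pass


@dataclass
class SnpRecord:
    gene: str
    cds_position: int  # 1-based within the reference CDS
    ref_nt: str
    alt_nt: str
    codon_index: int  # 1-based
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | nonsynonymous
    substitution_class: str  # transition | transversion


@dataclass
class IndelRecord:
    gene: str
    cds_position: int  # 1-based position of the first affected ref base
    length: int
    in_frame: bool
    aa_length: int | None = None
    kind: str = "indel"  # insertion (in alt) | deletion (from ref)


def classify_substitution(ref_nt: str, alt_nt: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    ref_nt, alt_nt = ref_nt.upper(), alt_nt.upper()
    for nt in (ref_nt, alt_nt):
        if nt not in "ACGT":
            raise VariantError(f"not a nucleotide: {nt!r}")
    if ref_nt == alt_nt:
        raise VariantError(f"{ref_nt}->{alt_nt} is not a variant")
    if {ref_nt, alt_nt} <= PURINES or {ref_nt, alt_nt} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def compare_cds(
    gene_name: str,
    cds_a: str,
    cds_b: str,
    scheme: ScoringScheme | None = None,
) -> tuple[list[SnpRecord], list[IndelRecord]]:
    """Globally align two orthologous CDS and classify every difference.

    Substitutions get codon context from ``cds_a`` (the reference);
    codons hit by more than one substitution are classified jointly from
    the full alternate codon.  Positions are 1-based in ``cds_a``.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    for name, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) < 3:
            raise VariantError(f"CDS {name} of {gene_name} shorter than one codon")
        if "*" in translate(cds)[:-1]:
            warnings.warn(f"{gene_name}: CDS {name} has an internal stop codon")

    aln = global_align(cds_a, cds_b, scheme)
    # walk the cigar to get per-column coordinates
    subs: list[tuple[int, str, str]] = []  # (0-based a pos, ref, alt)
    indels: list[IndelRecord] = []
    ia = ib = 0
    num = ""
    for ch in aln.cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            ia += n
            ib += n
        elif ch == "X":
            for k in range(n):
                subs.append((ia + k, cds_a[ia + k], cds_b[ib + k]))
            ia += n
            ib += n
        elif ch == "I":  # present in a, absent in b: deletion from reference
            indels.append(
                IndelRecord(
                    gene=gene_name, cds_position=ia + 1, length=n,
                    in_frame=n % 3 == 0, aa_length=n // 3 if n % 3 == 0 else None,
                    kind="deletion",
                )
            )
            ia += n
        elif ch == "D":  # present in b only: insertion relative to reference
            indels.append(
                IndelRecord(
                    gene=gene_name, cds_position=ia + 1, length=n,
                    in_frame=n % 3 == 0, aa_length=n // 3 if n % 3 == 0 else None,
                    kind="insertion",
                )
            )
            ib += n

    # group substitutions by reference codon for joint effect classification
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for pos, ref, alt in subs:
        by_codon.setdefault(pos // 3, []).append((pos, ref, alt))
    records: list[SnpRecord] = []
    for codon_i, hits in sorted(by_codon.items()):
        ref_codon = cds_a[3 * codon_i : 3 * codon_i + 3]
        if len(ref_codon) < 3:
            continue  # trailing partial codon
        alt_codon = list(ref_codon)
        for pos, _, alt in hits:
            alt_codon[pos % 3] = alt
        ref_aa = CODON_TABLE.get(ref_codon, "X")
        alt_aa = CODON_TABLE.get("".join(alt_codon), "X")
        effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
        for pos, ref, alt in hits:
            records.append(
                SnpRecord(
                    gene=gene_name,
                    cds_position=pos + 1,
                    ref_nt=ref,
                    alt_nt=alt,
                    codon_index=codon_i + 1,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    effect=effect,
                    substitution_class=classify_substitution(ref, alt),
                )
            )
    records.sort(key=lambda r: r.cds_position)
    return records, indels


@dataclass
class GenomeDiffSummary:
    snp_count: int
    gap_count: int
    gap_length_histogram: dict[str, int] = field(default_factory=dict)
    coverage: float = 0.0
    identity: float = 0.0

    def __post_init__(self) -> None:
        assert self.snp_count >= 0 and self.gap_count >= 0
        assert self.identity <= 100.0


def summarize_genome_diff(
    a: CircularGenome,
    b: CircularGenome,
    k: int = 31,
    max_gap: int = 2000,
    min_block: int = 500,
) -> GenomeDiffSummary:
    """Column-wise variant summary of two broadly homologous genomes.

    Synteny blocks between ``a`` (query) and ``b`` are aligned column by
    column; substitution columns count as SNPs and maximal indel runs as
    gaps, binned into short (1-5 bp, the microindel class) and longer runs.
    Coverage and identity follow the synteny definitions.
    """
    blocks, summary = _synteny.chain_blocks(
        _synteny.anchor_map(a, b, k=k), a, b, max_gap=max_gap, min_block=min_block
    )
    if not blocks:
        warnings.warn(f"no homologous blocks between {a.id} and {b.id}")
        return GenomeDiffSummary(0, 0, {"1-5": 0, ">5": 0}, 0.0, 0.0)
    snp_count = sum(bl.mismatches for bl in blocks)
    gap_runs = [run for bl in blocks for run in bl.gap_runs]
    hist = {
        "1-5": sum(1 for g in gap_runs if g <= 5),
        ">5": sum(1 for g in gap_runs if g > 5),
    }
    return GenomeDiffSummary(
        snp_count=snp_count,
        gap_count=len(gap_runs),
        gap_length_histogram=hist,
        coverage=summary["coverage"],
        identity=summary["identity"],
    )
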