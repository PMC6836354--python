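"""Synthetic parental-pair + cybrid trio with a complete planted truth table.

The generator emulates the data situation of an alloplasmic CMS study:

* a *recipient* mitogenome (the fertile maintainer cytoplasm) carrying a
  realistic organelle gene set;
* a *donor* mitogenome sharing those genes (minus one recipient-private
  gene, cox2-2) but with a novel intergenic backbone, planted coding SNPs
  and one in-frame indel, long direct/inverted repeats, and donor-specific
  ORFs — some chimeric (embedding a core-gene fragment at ~98% identity)
  and some with engineered membrane-spanning stretches;
* a *cms* mitogenome built as a block mosaic: mostly donor, with a few
  recipient segments spliced in at variant-free shared genes (homologous
  junctions), as somatic-hybrid mitochondria recombine in vivo.

Everything planted is recorded in a :class:`TruthTable` sufficient to score
every pipeline stage.  Intergenic sequence is "sterilized" (stop codons
injected into chance ORFs on both strands) and every element boundary
carries a six-frame stop cassette, so the set of CMS-specific ORFs is
exactly the planted set — the property the parameter-recovery tests rely
on.  Defaults mirror the study conditions: 26 coding SNPs (10 synonymous /
16 non-synonymous, 18 transitions), a 33 bp in-frame rps3 insertion,
repeats of 9432/7383/2427 bp (inverted) and 1592 bp (direct), and 16
donor-specific ORFs of which 11 carry transmembrane stretches and 3 are
chimeric (atp8 or cox1 fragments).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (
    CircularGenome,
    FeatureAnnotation,
    GenomeSet,
    reverse_complement,
    write_genome,
    write_gff3,
)
from .orf_screen import CODON_TABLE, STOP_CODONS, translate
from .variant_compare import classify_substitution


class SimulationError(ValueError):
    pass


# six-frame stop cassette: TAA in all three forward frames, TAG (on the
# reverse strand) in all three reverse frames; contains no G, so it can
# never create an ATG with its neighbours' As and Ts alone
STOP_CASSETTE = "CTAACTAACTAA"

#: filler amino-acid alphabet: every residue scores <= 0 on the
#: Kyte-Doolittle scale, so filler regions can never form a predicted
#: membrane-spanning segment
SAFE_AA = "DEKNQSTGPRHY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
# Filler must never spell ATG in any frame of either strand, or chance
# ORFs would leak past the planted truth table.  Within the hydrophilic
# codon pool that means banning: CAT (an antisense ATG), CA-final codons
# (CA|T across a boundary), AT-final codons (xAT|G), and TGG (A|TG after
# an A-final codon).  No pool codon starts with AT or TG, none has a
# middle T, so no frame of filler-only sequence can contain ATG.
_FILLER_BANNED = {"CAT", "TCA", "ACA", "CCA", "GAT", "AAT", "TAT", "TGG"}
SAFE_CODONS = {
    aa: sorted(set(_CODONS_BY_AA[aa]) - _FILLER_BANNED) for aa in SAFE_AA
}
HYDROPHOBIC_CODONS = sorted(
    c for aa in "ILVF" for c in _CODONS_BY_AA[aa]
)
#: strongly hydrophilic subset (KD <= -3.5): flanks TM stretches so the
#: hydropathy window drops sharply between engineered segments
STRONG_HYDROPHILIC_AA = "DEKRNQ"

# shared mitochondrial gene set: (name, CDS length incl. stop, strand).
# Lengths are organelle-realistic and chosen so no gene's conceptual
# translation collides with a planted specific-ORF length (naming ties
# stay within the planted set).
GENE_TABLE: dict[str, tuple[int, str]] = {
    "atp1": (1530, "+"), "atp4": (597, "+"), "atp6": (783, "-"),
    "atp8": (480, "+"), "atp9": (225, "-"),
    "ccmB": (621, "+"), "ccmC": (753, "-"), "ccmFC": (1311, "+"),
    "ccmFN1": (1734, "+"), "ccmFN2": (849, "+"),
    "cob": (1182, "+"), "cox1": (1584, "-"), "cox2-1": (783, "+"),
    "cox2-2": (483, "+"), "cox3": (798, "-"),
    "matR": (1998, "-"), "orfX": (777, "+"),
    "nad1": (978, "+"), "nad2": (1467, "-"), "nad3": (357, "+"),
    "nad4": (1488, "-"), "nad4L": (303, "+"), "nad5": (2013, "+"),
    "nad6": (618, "+"), "nad7": (1176, "+"), "nad9": (573, "+"),
    "rpl2": (1029, "-"), "rpl5": (558, "+"), "rpl16": (537, "+"),
    "rps3": (1683, "+"), "rps4": (1068, "+"), "rps7": (447, "-"),
    "rps12": (378, "+"), "rps14": (312, "+"),
}
#: rps3 is two-exon; exon lengths of the recipient allele (sum = CDS length)
RPS3_EXONS = (72, 1611)
RPS3_INTRON = 264

#: gene order along both parental genomes (collinear by construction);
#: cox2-2 exists only in the recipient
GENE_ORDER = [
    "atp1", "rpl5", "cox1", "nad4",
    "atp4", "nad7", "rps4", "cob",            # mosaic cluster 1
    "ccmFN1", "orfX", "rpl2",
    "cox2-1", "nad2", "nad5", "nad1",         # mosaic cluster 2
    "matR", "rps7", "ccmFN2",
    "nad9", "cox2-2", "rpl16",                # mosaic cluster 3
    "rps3", "atp6", "ccmC", "ccmFC",
    "nad3", "rps12", "ccmB",
    "atp8", "atp9", "cox3", "nad4L", "nad6", "rps14",
]
RECIPIENT_ONLY_GENES = ("cox2-2",)

#: mosaic clusters: (left junction gene, interior genes, right junction gene);
#: junction genes carry no planted variants, so the splice is seamless
CLUSTERS = [
    ("atp4", ["nad7", "rps4"], "cob"),
    ("cox2-1", ["nad2", "nad5"], "nad1"),
    ("nad9", ["cox2-2"], "rpl16"),
]


@dataclass(frozen=True)
class SnpSpec:
    gene: str
    effect: str  # synonymous | nonsynonymous
    substitution_class: str  # transition | transversion


#: coding-SNP plan between maintainer and CMS gene copies:
#: 26 substitutions in 12 genes, 10 synonymous / 16 non-synonymous,
#: 18 transitions / 8 transversions
DEFAULT_SNP_PLAN = [
    SnpSpec("rpl5", "nonsynonymous", "transition"),
    SnpSpec("atp1", "synonymous", "transversion"),
    SnpSpec("atp1", "nonsynonymous", "transition"),
    SnpSpec("ccmFN1", "nonsynonymous", "transversion"),
    SnpSpec("ccmFN1", "nonsynonymous", "transition"),
    SnpSpec("cox1", "synonymous", "transition"),
    SnpSpec("cox1", "synonymous", "transversion"),
    SnpSpec("cox1", "synonymous", "transition"),
    SnpSpec("cox1", "synonymous", "transversion"),
    SnpSpec("nad4", "nonsynonymous", "transition"),
    SnpSpec("orfX", "synonymous", "transition"),
    SnpSpec("orfX", "nonsynonymous", "transition"),
    SnpSpec("orfX", "nonsynonymous", "transition"),
    SnpSpec("orfX", "nonsynonymous", "transition"),
    SnpSpec("orfX", "nonsynonymous", "transition"),
    SnpSpec("orfX", "nonsynonymous", "transition"),
    SnpSpec("rpl2", "nonsynonymous", "transition"),
    SnpSpec("rpl2", "nonsynonymous", "transition"),
    SnpSpec("rpl2", "nonsynonymous", "transversion"),
    SnpSpec("ccmFN2", "nonsynonymous", "transversion"),
    SnpSpec("rps7", "synonymous", "transition"),
    SnpSpec("matR", "nonsynonymous", "transition"),
    SnpSpec("matR", "nonsynonymous", "transition"),
    SnpSpec("rps12", "synonymous", "transversion"),
    SnpSpec("rps12", "synonymous", "transversion"),
    SnpSpec("nad3", "synonymous", "transition"),
]

#: donor-private SNPs (genes the mosaic takes from the recipient, so the
#: CMS line matches the recipient there and differs from the donor)
DEFAULT_DONOR_PRIVATE_SNP_PLAN = [
    SnpSpec("nad7", "nonsynonymous", "transition"),
    SnpSpec("rps4", "synonymous", "transition"),
    SnpSpec("nad2", "nonsynonymous", "transition"),
    SnpSpec("nad5", "nonsynonymous", "transition"),
]


@dataclass(frozen=True)
class ChimeraSpec:
    core_gene: str
    fragment_length: int
    identity: float  # percent identity of the planted fragment
    orf_offset_codons: int  # codon offset of the fragment inside the ORF


@dataclass(frozen=True)
class OrfSpec:
    label: str  # paper-style name used in the truth table
    protein_length: int
    tm_stretches: int = 0
    chimera: ChimeraSpec | None = None
    strand: str = "+"
    context: tuple[str, int] | None = None  # (gene placed right after, gap bp)


DEFAULT_ORF_PLAN = [
    OrfSpec("orf108a", 108, 1),
    OrfSpec("orf133a", 133, 0, strand="-"),
    OrfSpec("orf110", 110, 1),
    OrfSpec("orf309", 309, 3, ChimeraSpec("cox1", 133, 98.0, 150)),
    OrfSpec("orf257", 257, 6),
    OrfSpec("orf346", 346, 3, ChimeraSpec("cox1", 133, 98.0, 180),
            context=("nad3", 103)),
    OrfSpec("orf101b", 101, 0),
    OrfSpec("orf130", 130, 1, strand="-"),
    OrfSpec("orf224", 224, 2, ChimeraSpec("atp8", 175, 98.0, 100),
            context=("ccmB", 217)),
    OrfSpec("orf133b", 133, 0),
    OrfSpec("orf106", 106, 1),
    OrfSpec("orf115a", 115, 2),
    OrfSpec("orf170", 170, 1),
    OrfSpec("orf394", 394, 0, strand="-"),
    OrfSpec("orf192", 192, 1),
    OrfSpec("orf131", 131, 0),
]

DEFAULT_REPEAT_PLAN = [
    (9432, "inverted"),
    (7383, "inverted"),
    (2427, "inverted"),
    (1592, "direct"),
]


@dataclass(frozen=True)
class MosaicPlan:
    donor_fraction: float = 0.90
    n_blocks: int = 3  # recipient-derived blocks, one per cluster

    def __post_init__(self) -> None:
        if not 0.0 < self.donor_fraction < 1.0:
            raise SimulationError("donor_fraction must be in (0, 1)")
        if not 1 <= self.n_blocks <= len(CLUSTERS):
            raise SimulationError(f"n_blocks must be 1..{len(CLUSTERS)}")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic trio."""

    seed: int = 0
    genome_length_recipient: int = 221_862
    genome_length_donor: int = 240_024
    n_shared_genes: int = len(GENE_ORDER)
    snp_plan: list[SnpSpec] = field(default_factory=lambda: list(DEFAULT_SNP_PLAN))
    donor_private_snp_plan: list[SnpSpec] = field(
        default_factory=lambda: list(DEFAULT_DONOR_PRIVATE_SNP_PLAN)
    )
    indel_plan: list[tuple[str, int]] = field(
        default_factory=lambda: [("rps3", 33)]
    )
    repeat_plan: list[tuple[int, str]] = field(
        default_factory=lambda: list(DEFAULT_REPEAT_PLAN)
    )
    specific_orf_plan: list[OrfSpec] = field(
        default_factory=lambda: list(DEFAULT_ORF_PLAN)
    )
    mosaic_plan: MosaicPlan = field(default_factory=MosaicPlan)
    backbone_gc: float = 0.44
    min_spacer: int = 150

    def __post_init__(self) -> None:
        if self.n_shared_genes != len(GENE_ORDER):
            raise SimulationError(
                "the generator models the full shared gene set "
                f"({len(GENE_ORDER)} genes)"
            )
        for length, orient in self.repeat_plan:
            if orient not in ("direct", "inverted"):
                raise SimulationError(f"bad repeat orientation {orient!r}")
            if length < 200:
                raise SimulationError("repeat length must be >= 200")
        labels = [o.label for o in self.specific_orf_plan]
        if len(set(labels)) != len(labels):
            raise SimulationError("duplicate ORF labels in specific_orf_plan")

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimConfig":
        """A scaled-down configuration for fast tests: same gene set, two
        repeats and four specific ORFs on ~60/70 kb genomes."""
        return cls(
            seed=seed,
            genome_length_recipient=62_000,
            genome_length_donor=72_000,
            repeat_plan=[(2000, "direct"), (1200, "inverted")],
            specific_orf_plan=[
                OrfSpec("torf150", 150, 1, ChimeraSpec("atp8", 120, 98.0, 60)),
                OrfSpec("torf120", 120, 2),
                OrfSpec("torf135", 135, 0),
                OrfSpec("torf210", 210, 1, strand="-"),
            ],
        )


@dataclass
class PlantedOrf:
    label: str
    expected_name: str
    protein_length: int
    nt_length: int
    tm_stretches: int
    strand: str
    chimera: ChimeraSpec | None
    context: tuple[str, int] | None
    donor_interval: tuple[int, int] = (0, 0)
    cms_interval: tuple[int, int] = (0, 0)
    sequence: str = ""


@dataclass
class PlantedSnp:
    gene: str
    cds_position: int  # 1-based, recipient CDS coordinates
    codon_index: int
    ref_nt: str
    alt_nt: str
    effect: str
    substitution_class: str
    scope: str  # cms_vs_maintainer | donor_private


@dataclass
class PlantedIndel:
    gene: str
    cds_position: int  # 1-based first inserted base in the carrier CDS
    length: int
    aa_length: int


@dataclass
class PlantedRepeat:
    label: str
    length: int
    orientation: str
    donor_positions: tuple[int, int] = (0, 0)
    cms_positions: tuple[int, int] = (0, 0)


@dataclass
class TruthTable:
    seed: int
    orfs: list[PlantedOrf]
    snps: list[PlantedSnp]
    indels: list[PlantedIndel]
    repeats: list[PlantedRepeat]
    annotations: dict[str, list[FeatureAnnotation]]
    recipient_only_genes: tuple[str, ...]
    donor_fraction_config: float
    donor_fraction_actual: float
    recipient_block_intervals_cms: list[tuple[int, int]]

    def specific_orf_names(self) -> list[str]:
        return [o.expected_name for o in self.orfs]

    def candidate_names(self) -> list[str]:
        return [
            o.expected_name
            for o in self.orfs
            if o.chimera is not None and o.tm_stretches >= 1
        ]


@dataclass
class SimResult:
    genomes: GenomeSet
    annotations: dict[str, list[FeatureAnnotation]]
    truth: TruthTable


# ---------------------------------------------------------------------------
# sequence construction helpers


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _scan_orfs_linear(
    seq: str, min_nt: int, include_open: bool = False
) -> list[tuple[int, int, str]]:
    """ATG->stop runs >= min_nt on both strands, footprint coordinates.

    With ``include_open`` a run still open at the end of the sequence is
    reported too — needed when sterilizing a segment whose continuation
    (and eventual stop) lies outside the segment.
    """
    out = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        n = len(s)
        for frame in range(3):
            start = -1
            pos = frame
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start >= 0 and pos + 3 - start >= min_nt:
                        if strand == "+":
                            out.append((start, pos + 3, "+"))
                        else:
                            out.append((n - (pos + 3), n - start, "-"))
                    start = -1
                elif codon == "ATG" and start < 0:
                    start = pos
            if include_open and start >= 0 and pos + 3 - start >= min_nt:
                if strand == "+":
                    out.append((start, pos + 3, "+"))
                else:
                    out.append((n - (pos + 3), n - start, "-"))
    return out


def _sterilize(seq: str, rng: np.random.Generator, max_aa: int = 80) -> str:
    """Inject stop codons until no ATG->stop run of > max_aa codons remains
    on either strand.  Stops are written as TAA / TTA (no G), so no new ATG
    can be created."""
    min_nt = 3 * (max_aa + 1) + 3
    chars = list(seq)
    for _ in range(100):
        hits = _scan_orfs_linear("".join(chars), min_nt, include_open=True)
        if not hits:
            return "".join(chars)
        for s, e, strand in hits:
            mid_codon = (e - s) // 6  # an in-frame codon near the middle
            if strand == "+":
                p = s + 3 * mid_codon
                chars[p : p + 3] = "TAA"
            else:
                p = e - 3 * (mid_codon + 1)
                chars[p : p + 3] = "TTA"
    raise SimulationError("sterilization did not converge")


def _filler_codons(rng: np.random.Generator, n: int) -> str:
    aas = rng.choice(list(SAFE_AA), size=n)
    return "".join(
        SAFE_CODONS[aa][rng.integers(len(SAFE_CODONS[aa]))] for aa in aas
    )


def _make_cds(rng: np.random.Generator, length_nt: int) -> str:
    if length_nt % 3 != 0 or length_nt < 9:
        raise SimulationError(f"CDS length must be a multiple of 3 >= 9, got {length_nt}")
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + _filler_codons(rng, length_nt // 3 - 2) + stop


def _plant_snp(
    rng: np.random.Generator,
    cds: str,
    spec: SnpSpec,
    used_codons: set[int],
) -> tuple[str, PlantedSnp]:
    n_codons = len(cds) // 3
    for _ in range(2000):
        ci = int(rng.integers(1, n_codons - 1))
        if ci in used_codons:
            continue
        codon = cds[3 * ci : 3 * ci + 3]
        pos_in = int(rng.integers(3))
        ref = codon[pos_in]
        alts = [
            b
            for b in "ACGT"
            if b != ref
            and classify_substitution(ref, b) == spec.substitution_class
        ]
        rng.shuffle(alts)
        for alt in alts:
            new_codon = codon[:pos_in] + alt + codon[pos_in + 1 :]
            if new_codon in STOP_CODONS:
                continue
            effect = (
                "synonymous"
                if CODON_TABLE[new_codon] == CODON_TABLE[codon]
                else "nonsynonymous"
            )
            if effect != spec.effect:
                continue
            used_codons.add(ci)
            new_cds = cds[: 3 * ci] + new_codon + cds[3 * ci + 3 :]
            # self-check: a synonymous plant never changes the protein
            if spec.effect == "synonymous":
                assert translate(new_cds) == translate(cds)
            return new_cds, PlantedSnp(
                gene=spec.gene,
                cds_position=3 * ci + pos_in + 1,
                codon_index=ci + 1,
                ref_nt=ref,
                alt_nt=alt,
                effect=effect,
                substitution_class=spec.substitution_class,
                scope="",
            )
    raise SimulationError(f"could not plant SNP {spec} after 2000 attempts")


def _make_fragment(
    rng: np.random.Generator, gene_cds: str, spec: ChimeraSpec
) -> str:
    """A core-gene fragment mutated down to the target identity."""
    f = spec.fragment_length
    if f + 20 > len(gene_cds):
        raise SimulationError(f"fragment {f} nt exceeds {spec.core_gene} CDS")
    start = int(rng.integers(10, len(gene_cds) - f - 10))
    frag = list(gene_cds[start : start + f])
    n_mut = round(f * (1 - spec.identity / 100.0))
    for p in rng.choice(f, size=n_mut, replace=False):
        frag[p] = rng.choice([b for b in "ACGT" if b != frag[p]])
    return "".join(frag)


def _make_orf(
    rng: np.random.Generator,
    spec: OrfSpec,
    core_cds: dict[str, str],
) -> str:
    """Build the coding-strand nucleotide sequence of a planted ORF."""
    total = 3 * (spec.protein_length + 1)
    n_codons = total // 3
    # transmembrane stretches: 21 hydrophobic codons, 18 filler codons apart
    tm_slots: list[tuple[int, int]] = []
    start_codon = 8
    for i in range(spec.tm_stretches):
        s = start_codon + i * 39
        tm_slots.append((s, s + 21))
    if tm_slots and tm_slots[-1][1] > n_codons - 2:
        raise SimulationError(f"{spec.label}: TM stretches do not fit")
    frag_iv: tuple[int, int] | None = None
    if spec.chimera:
        off = 3 * spec.chimera.orf_offset_codons
        frag_iv = (off, off + spec.chimera.fragment_length)
        if frag_iv[1] > total - 3:
            raise SimulationError(f"{spec.label}: chimera fragment does not fit")
        for s, e in tm_slots:
            if 3 * s < frag_iv[1] and frag_iv[0] < 3 * e:
                raise SimulationError(f"{spec.label}: TM stretch overlaps fragment")

    for _ in range(300):
        seq: list[str | None] = [None] * total
        seq[0:3] = "ATG"
        seq[total - 3 : total] = ("TAA", "TAG", "TGA")[rng.integers(3)]
        if frag_iv:
            frag = _make_fragment(rng, core_cds[spec.chimera.core_gene], spec.chimera)
            seq[frag_iv[0] : frag_iv[1]] = frag
        for s, e in tm_slots:
            codons = rng.choice(HYDROPHOBIC_CODONS, size=e - s)
            seq[3 * s : 3 * e] = "".join(codons)
            # strongly hydrophilic guards on both sides of the stretch
            for gci in list(range(max(1, s - 9), s)) + list(
                range(e, min(n_codons - 1, e + 9))
            ):
                cell = seq[3 * gci : 3 * gci + 3]
                if any(x is not None for x in cell):
                    continue
                aa = STRONG_HYDROPHILIC_AA[rng.integers(len(STRONG_HYDROPHILIC_AA))]
                seq[3 * gci : 3 * gci + 3] = SAFE_CODONS[aa][
                    rng.integers(len(SAFE_CODONS[aa]))
                ]
        # fill whole free codons with safe filler, partial codons base-wise
        for ci in range(1, n_codons - 1):
            cell = seq[3 * ci : 3 * ci + 3]
            if all(x is None for x in cell):
                seq[3 * ci : 3 * ci + 3] = _filler_codons(rng, 1)
        for ci in range(n_codons):
            cell = seq[3 * ci : 3 * ci + 3]
            if any(x is None for x in cell):
                for _ in range(50):
                    filled = [
                        x if x is not None else str(rng.choice(list("ACT")))
                        for x in cell
                    ]
                    if "".join(filled) not in STOP_CODONS or ci == n_codons - 1:
                        seq[3 * ci : 3 * ci + 3] = filled
                        break
        nt = "".join(seq)  # type: ignore[arg-type]
        protein = translate(nt[:-3])
        if "*" in protein:
            continue
        # no secondary ORF may hide inside the planted one
        unit = STOP_CASSETTE + nt + STOP_CASSETTE
        secondary = [
            (s, e, st)
            for s, e, st in _scan_orfs_linear(unit, 243)
            if not (st == "+" and s == len(STOP_CASSETTE) and e == len(STOP_CASSETTE) + total)
        ]
        if secondary:
            continue
        return nt
    raise SimulationError(f"could not build ORF {spec.label}")


# ---------------------------------------------------------------------------
# genome assembly


def _repeat_label(idx: int, length: int, orient: str) -> str:
    return f"rep{idx}_{length}{orient[0]}"


def _interleave_order(n: int) -> list[int]:
    """Deterministic reordering of n items: even positions first, then odd
    positions, so adjacent items in the input land far apart in the output
    while relative order within each half is preserved."""
    return list(range(0, n, 2)) + list(range(1, n, 2))


Token = tuple  # ("gene", name) | ("orf", label) | ("repeat", label, copy) |
#               ("spacer",) | ("gap", n) | ("cspacer", cluster_idx)


def _layout_tokens(
    config: SimConfig, genome: str
) -> list[Token]:
    """Alternating spacer/element token list for one parental genome."""
    genes = [
        g
        for g in GENE_ORDER
        if genome == "recipient" or g not in RECIPIENT_ONLY_GENES
    ]
    cluster_genes: dict[str, int] = {}
    for idx, (gs, interior, ge) in enumerate(CLUSTERS[: config.mosaic_plan.n_blocks]):
        for g in interior:
            cluster_genes[g] = idx

    elements: list[Token] = [("gene", g) for g in genes]
    if genome == "donor":
        # context ORFs go directly before their gene with a fixed gap
        fixed_before: dict[str, OrfSpec] = {}
        floating: list[Token] = []
        for spec in config.specific_orf_plan:
            if spec.context:
                fixed_before[spec.context[0]] = spec
            else:
                floating.append(("orf", spec.label))
        for i, (length, orient) in enumerate(config.repeat_plan):
            label = _repeat_label(i, length, orient)
            floating.append(("repeat", label, 0))
            floating.append(("repeat", label, 1))
        # weave repeat copies between the ORFs so the two copies of a
        # repeat end up well separated along the genome
        floating = [floating[i] for i in _interleave_order(len(floating))]
        # insertion slots: boundaries not inside a cluster and not before a
        # context-pinned gene
        out: list[Token] = []
        slot_ok: list[bool] = []
        for g in genes:
            ok = g not in cluster_genes and g not in fixed_before
            # do not insert between a cluster's junction and interior
            if g in [c[2] for c in CLUSTERS[: config.mosaic_plan.n_blocks]]:
                ok = False
            slot_ok.append(ok)
        ok_slots = [i for i, ok in enumerate(slot_ok) if ok]
        if len(ok_slots) < 1:
            raise SimulationError("no insertion slots available")
        targets = np.linspace(0, len(ok_slots) - 1, num=len(floating))
        assigned: dict[int, list[Token]] = {}
        for tok, t in zip(floating, targets):
            assigned.setdefault(ok_slots[int(round(t))], []).append(tok)
        for i, g in enumerate(genes):
            for tok in assigned.get(i, []):
                out.append(tok)
            if g in fixed_before:
                spec = fixed_before[g]
                out.append(("orf", spec.label))
                out.append(("gap", spec.context[1]))
            out.append(("gene", g))
        elements = out

    tokens: list[Token] = []
    prev_was_gap = False
    for tok in elements:
        if tok[0] == "gap":
            tokens.append(tok)
            prev_was_gap = True
            continue
        if not prev_was_gap:
            # spacer between elements; cluster-internal spacers are special
            if tok[0] == "gene" and tok[1] in cluster_genes:
                tokens.append(("cspacer", cluster_genes[tok[1]]))
            elif (
                tok[0] == "gene"
                and tok[1] in [c[2] for c in CLUSTERS[: config.mosaic_plan.n_blocks]]
            ):
                # spacer before the right junction gene closes the cluster
                idx = [c[2] for c in CLUSTERS].index(tok[1])
                tokens.append(("cspacer", idx))
            else:
                tokens.append(("spacer",))
        prev_was_gap = False
        tokens.append(tok)
    tokens.append(("spacer",))
    return tokens


def _assemble(
    genome_id: str,
    tokens: list[Token],
    element_seqs: dict[tuple, str],
    rng: np.random.Generator,
    target_len: int,
    config: SimConfig,
    cluster_spacer_lens: dict[int, list[int]] | None = None,
) -> tuple[str, dict[tuple, tuple[int, int]]]:
    """Concatenate elements and sterilized spacers; returns sequence and the
    genome interval of every element token."""
    elem_total = sum(
        len(element_seqs[tok]) for tok in tokens if tok[0] in ("gene", "orf", "repeat")
    )
    fixed_total = sum(tok[1] for tok in tokens if tok[0] == "gap")
    cluster_iters = {}
    cluster_total = 0
    if cluster_spacer_lens is None:
        cluster_spacer_lens = {}
    counts: dict[int, int] = {}
    for tok in tokens:
        if tok[0] == "cspacer":
            counts[tok[1]] = counts.get(tok[1], 0) + 1
    for idx, n in counts.items():
        lens = cluster_spacer_lens.get(idx)
        if lens is None:
            lens = [config.min_spacer + 400] * n
        if len(lens) != n:
            raise SimulationError("cluster spacer allocation mismatch")
        cluster_iters[idx] = iter(lens)
        cluster_total += sum(lens)

    n_default = sum(1 for tok in tokens if tok[0] == "spacer")
    budget = target_len - elem_total - fixed_total - cluster_total
    if budget < n_default * config.min_spacer:
        raise SimulationError(
            f"{genome_id}: infeasible packing — elements need "
            f"{elem_total + fixed_total + cluster_total + n_default * config.min_spacer} bp, "
            f"target is {target_len} bp"
        )
    extra = rng.multinomial(budget - n_default * config.min_spacer, [1.0 / n_default] * n_default)
    default_lens = iter(config.min_spacer + extra)

    parts: list[str] = []
    positions: dict[tuple, tuple[int, int]] = {}
    pos = 0

    def add_spacer(length: int) -> None:
        nonlocal pos
        if length < 30:
            raise SimulationError(f"spacer of {length} bp too short for cassettes")
        filler = _sterilize(
            _rand_seq(rng, length - 2 * len(STOP_CASSETTE), config.backbone_gc), rng
        )
        # a TG-initial filler would complete an ATG with the cassette's
        # terminal A; pin the first base instead
        filler = "C" + filler[1:]
        s = STOP_CASSETTE + filler + STOP_CASSETTE
        parts.append(s)
        pos += len(s)

    for tok in tokens:
        kind = tok[0]
        if kind == "spacer":
            add_spacer(int(next(default_lens)))
        elif kind == "gap":
            add_spacer(tok[1])
        elif kind == "cspacer":
            add_spacer(int(next(cluster_iters[tok[1]])))
        else:
            seq = element_seqs[tok]
            positions[tok] = (pos, pos + len(seq))
            parts.append(seq)
            pos += len(seq)
    return "".join(parts), positions


def _gene_annotation(
    gene: str, interval: tuple[int, int], exons: tuple[int, ...] | None, intron: int
) -> FeatureAnnotation:
    start, end = interval
    strand = GENE_TABLE[gene][1]
    if exons is None:
        segments = [(start, end, strand)]
    else:
        e1, e2 = exons
        segments = [(start, start + e1, strand), (start + e1 + intron, end, strand)]
        if strand == "-":
            segments = segments[::-1]
    return FeatureAnnotation(gene_name=gene, feature_type="CDS", segments=segments)


def simulate_trio(config: SimConfig | None = None) -> SimResult:
    """Generate the donor / maintainer / cms trio plus its truth table.

    The same seed always produces byte-identical genomes.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    # 1. recipient (= maintainer) gene alleles
    recipient_cds: dict[str, str] = {}
    for gene, (length, _) in GENE_TABLE.items():
        recipient_cds[gene] = _make_cds(rng, length)

    # 2. donor alleles: shared-gene SNPs + private SNPs + in-frame indel
    donor_cds = dict(recipient_cds)
    snps: list[PlantedSnp] = []
    used: dict[str, set[int]] = {}
    for spec, scope in [(s, "cms_vs_maintainer") for s in config.snp_plan] + [
        (s, "donor_private") for s in config.donor_private_snp_plan
    ]:
        if spec.gene in RECIPIENT_ONLY_GENES:
            raise SimulationError(f"cannot plant SNP in donor-absent gene {spec.gene}")
        donor_cds[spec.gene], rec = _plant_snp(
            rng, donor_cds[spec.gene], spec, used.setdefault(spec.gene, set())
        )
        rec.scope = scope
        snps.append(rec)

    indels: list[PlantedIndel] = []
    donor_rps3_exons = RPS3_EXONS
    for gene, length in config.indel_plan:
        if length % 3 != 0:
            raise SimulationError("indel plan must be in-frame (multiple of 3)")
        cds = donor_cds[gene]
        # insert after a codon boundary two-thirds into the CDS
        at = 3 * (2 * (len(cds) // 3) // 3)
        insert = _filler_codons(rng, length // 3)
        donor_cds[gene] = cds[:at] + insert + cds[at:]
        indels.append(
            PlantedIndel(gene=gene, cds_position=at + 1, length=length, aa_length=length // 3)
        )
        if gene == "rps3":
            donor_rps3_exons = (RPS3_EXONS[0], RPS3_EXONS[1] + length)

    # 3. genomic element sequences (gene placement respects strand; rps3
    #    carries its intron)
    rps3_intron_seq = _rand_seq(rng, RPS3_INTRON, config.backbone_gc)

    def gene_element(gene: str, cds: str, exons: tuple[int, int] | None) -> str:
        strand = GENE_TABLE[gene][1]
        if exons is not None:
            e1, _ = exons
            genomic = cds[:e1] + rps3_intron_seq + cds[e1:]
        else:
            genomic = cds
        return reverse_complement(genomic) if strand == "-" else genomic

    recipient_elems: dict[tuple, str] = {}
    donor_elems: dict[tuple, str] = {}
    for gene in GENE_ORDER:
        exons = RPS3_EXONS if gene == "rps3" else None
        recipient_elems[("gene", gene)] = gene_element(gene, recipient_cds[gene], exons)
        d_exons = donor_rps3_exons if gene == "rps3" else None
        donor_elems[("gene", gene)] = gene_element(gene, donor_cds[gene], d_exons)

    orfs: list[PlantedOrf] = []
    for spec in config.specific_orf_plan:
        nt = _make_orf(rng, spec, recipient_cds)
        donor_elems[("orf", spec.label)] = (
            reverse_complement(nt) if spec.strand == "-" else nt
        )
        orfs.append(
            PlantedOrf(
                label=spec.label,
                expected_name="",
                protein_length=spec.protein_length,
                nt_length=len(nt),
                tm_stretches=spec.tm_stretches,
                strand=spec.strand,
                chimera=spec.chimera,
                context=spec.context,
                sequence=nt,
            )
        )

    repeats: list[PlantedRepeat] = []
    for i, (length, orient) in enumerate(config.repeat_plan):
        label = _repeat_label(i, length, orient)
        unit = _sterilize(_rand_seq(rng, length, config.backbone_gc), rng)
        # fixed terminal bases rule out ATG formation across the copy
        # boundary on either strand (C cannot start one, G cannot end one)
        unit = "C" + unit[1:-1] + "G"
        # distinct guard bases around the two copies stop maximal-exact
        # extension at exactly the planted repeat length
        core_b = reverse_complement(unit) if orient == "inverted" else unit
        donor_elems[("repeat", label, 0)] = "A" + unit + "A"
        donor_elems[("repeat", label, 1)] = "C" + core_b + "C"
        repeats.append(PlantedRepeat(label=label, length=length, orientation=orient))

    # 4. assemble the donor, then the recipient with cluster spacers sized to
    #    realize the configured donor fraction of the mosaic
    donor_tokens = _layout_tokens(config, "donor")
    donor_seq, donor_pos = _assemble(
        "donor", donor_tokens, donor_elems, rng, config.genome_length_donor, config
    )

    def mid(positions: dict, gene: str) -> int:
        s, e = positions[("gene", gene)]
        return (s + e) // 2

    active_clusters = CLUSTERS[: config.mosaic_plan.n_blocks]
    donor_spans = [
        mid(donor_pos, ge) - mid(donor_pos, gs) for gs, _, ge in active_clusters
    ]
    f = config.mosaic_plan.donor_fraction
    recip_span_total = (1 - f) / f * (len(donor_seq) - sum(donor_spans))
    cluster_spacer_lens: dict[int, list[int]] = {}
    for idx, (gs, interior, ge) in enumerate(active_clusters):
        target_span = recip_span_total * donor_spans[idx] / sum(donor_spans)
        interior_names = list(interior)
        gene_bp = (
            len(recipient_elems[("gene", gs)]) // 2
            + len(recipient_elems[("gene", ge)]) // 2
            + sum(len(recipient_elems[("gene", g)]) for g in interior_names)
        )
        n_slots = len(interior_names) + 1
        per_slot = max(60, int((target_span - gene_bp) / n_slots))
        cluster_spacer_lens[idx] = [per_slot] * n_slots

    recipient_tokens = _layout_tokens(config, "recipient")
    recipient_seq, recipient_pos = _assemble(
        "maintainer",
        recipient_tokens,
        recipient_elems,
        rng,
        config.genome_length_recipient,
        config,
        cluster_spacer_lens=cluster_spacer_lens,
    )

    # 5. splice the cms mosaic at the midpoints of the junction genes
    pieces: list[tuple[str, int, int]] = []  # (source, start, end)
    cursor = 0
    for gs, _, ge in active_clusters:
        pieces.append(("donor", cursor, mid(donor_pos, gs)))
        pieces.append(("recipient", mid(recipient_pos, gs), mid(recipient_pos, ge)))
        cursor = mid(donor_pos, ge)
    pieces.append(("donor", cursor, len(donor_seq)))

    cms_parts: list[str] = []
    offsets: list[tuple[str, int, int, int]] = []  # (source, start, end, cms_start)
    cms_pos = 0
    recipient_intervals: list[tuple[int, int]] = []
    for source, s, e in pieces:
        seq = (donor_seq if source == "donor" else recipient_seq)[s:e]
        offsets.append((source, s, e, cms_pos))
        if source == "recipient":
            recipient_intervals.append((cms_pos, cms_pos + len(seq)))
        cms_parts.append(seq)
        cms_pos += len(seq)
    cms_seq = "".join(cms_parts)

    def to_cms(source: str, iv: tuple[int, int]) -> tuple[int, int] | None:
        for src, s, e, off in offsets:
            if src == source and s <= iv[0] and iv[0] < e:
                return (iv[0] - s + off, iv[1] - s + off)
        return None

    # 6. truth-table coordinates
    for orf in orfs:
        div = donor_pos[("orf", orf.label)]
        civ = to_cms("donor", div)
        if civ is None:
            raise SimulationError(f"ORF {orf.label} lost in mosaic splicing")
        orf.donor_interval = div
        orf.cms_interval = civ
    for rep in repeats:
        a = donor_pos[("repeat", rep.label, 0)]
        b = donor_pos[("repeat", rep.label, 1)]
        ca, cb = to_cms("donor", a), to_cms("donor", b)
        if ca is None or cb is None:
            raise SimulationError(f"repeat {rep.label} lost in mosaic splicing")
        # +1 skips the guard base in front of the planted unit
        rep.donor_positions = (a[0] + 1, b[0] + 1)
        rep.cms_positions = (ca[0] + 1, cb[0] + 1)

    # expected screen names (orf{protein_length}, a/b on inventory ties):
    # assign from an actual ORF call on the finished cms genome, which also
    # verifies every planted ORF is callable at the screen's default floor
    from .orf_screen import find_orfs as _find_orfs

    orfs_sorted = sorted(orfs, key=lambda o: o.cms_interval[0])
    called = {
        (rec.start, rec.strand): rec.orf_id
        for rec in _find_orfs(
            CircularGenome("cms_tmp", cms_seq, True), min_protein_length=101
        )
    }
    for o in orfs_sorted:
        key = (o.cms_interval[0], o.strand)
        if key not in called:
            raise SimulationError(f"planted ORF {o.label} not recovered by the caller")
        o.expected_name = called[key]

    # 7. per-genome gene annotations
    annotations: dict[str, list[FeatureAnnotation]] = {"donor": [], "maintainer": [], "cms": []}
    for gene in GENE_ORDER:
        exons_d = donor_rps3_exons if gene == "rps3" else None
        exons_r = RPS3_EXONS if gene == "rps3" else None
        if ("gene", gene) in donor_pos:
            annotations["donor"].append(
                _gene_annotation(gene, donor_pos[("gene", gene)], exons_d, RPS3_INTRON)
            )
        annotations["maintainer"].append(
            _gene_annotation(gene, recipient_pos[("gene", gene)], exons_r, RPS3_INTRON)
        )
        # cms carries the donor allele in donor blocks, the recipient allele
        # in recipient blocks
        civ = None
        exons_c = exons_d
        if ("gene", gene) in donor_pos:
            civ = to_cms("donor", donor_pos[("gene", gene)])
        if civ is None:
            civ = to_cms("recipient", recipient_pos[("gene", gene)])
            exons_c = exons_r
        if civ is None:
            raise SimulationError(f"gene {gene} lost in mosaic splicing")
        annotations["cms"].append(_gene_annotation(gene, civ, exons_c, RPS3_INTRON))

    genomes = GenomeSet(
        genomes={
            "donor": CircularGenome("donor_mito", donor_seq, True, "synthetic donor parent"),
            "maintainer": CircularGenome(
                "maintainer_mito", recipient_seq, True, "synthetic recipient/maintainer"
            ),
            "cms": CircularGenome("cms_mito", cms_seq, True, "synthetic CMS mosaic"),
        }
    )
    recip_total = sum(e - s for s, e in recipient_intervals)
    truth = TruthTable(
        seed=config.seed,
        orfs=orfs_sorted,
        snps=snps,
        indels=indels,
        repeats=repeats,
        annotations=annotations,
        recipient_only_genes=RECIPIENT_ONLY_GENES,
        donor_fraction_config=f,
        donor_fraction_actual=round(1 - recip_total / len(cms_seq), 4),
        recipient_block_intervals_cms=recipient_intervals,
    )
    return SimResult(genomes=genomes, annotations=annotations, truth=truth)


def simulate_divergent_copy(
    length: int = 153_449,
    n_snps: int = 60,
    n_gaps: int = 50,
    gc: float = 0.37,
    seed: int = 0,
) -> tuple[CircularGenome, CircularGenome, dict[str, int]]:
    """A chloroplast-style pair: one genome plus a copy carrying ``n_snps``
    substitutions and ``n_gaps`` short (1-5 bp) indels, well separated so
    each planted event is one alignment event."""
    rng = np.random.default_rng(seed)
    base = _rand_seq(rng, length, gc)
    step = (length - 400) // (n_snps + n_gaps)
    if step < 40:
        raise SimulationError("genome too short for the requested variant load")
    slots = np.arange(200, 200 + step * (n_snps + n_gaps), step)
    slots = rng.permutation(slots)
    snp_sites = np.sort(slots[:n_snps])
    gap_sites = np.sort(slots[n_snps : n_snps + n_gaps])

    chars = list(base)
    for p in snp_sites:
        ref = chars[p]
        chars[p] = rng.choice([b for b in "ACGT" if b != ref])
    gap_lengths = [1 + (i % 5) for i in range(n_gaps)]
    edits = sorted(zip(gap_sites.tolist(), gap_lengths), reverse=True)
    for i, (p, glen) in enumerate(edits):
        if i % 2 == 0:  # deletion
            del chars[p : p + glen]
        else:  # insertion
            chars[p:p] = list(_rand_seq(rng, glen, gc))
    derived = "".join(chars)
    a = CircularGenome("cp_a", base, True, "synthetic chloroplast")
    b = CircularGenome("cp_b", derived, True, "synthetic chloroplast variant copy")
    return a, b, {"snps": n_snps, "gaps": n_gaps}


def write_fixture_bundle(config: SimConfig, outdir: str | Path) -> Path:
    """Write FASTA + GFF3 + truth TSVs for a simulated trio.

    The pipeline only ever reads the FASTA/GFF3 files; the truth TSVs exist
    for scoring and can be deleted without affecting any run.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_trio(config)
    for role in ("donor", "maintainer", "cms"):
        genome = result.genomes[role]
        write_genome(genome, outdir / f"{role}.fasta", "fasta")
        write_gff3(genome, result.annotations[role], outdir / f"{role}.gff3")
    write_genome(
        result.genomes["maintainer"],
        outdir / "maintainer.gb",
        "genbank",
        annotations=result.annotations["maintainer"],
    )
    truth = result.truth
    pd.DataFrame(
        [
            {
                "label": o.label,
                "expected_name": o.expected_name,
                "protein_length": o.protein_length,
                "nt_length": o.nt_length,
                "tm_stretches": o.tm_stretches,
                "strand": o.strand,
                "chimera_gene": o.chimera.core_gene if o.chimera else "",
                "chimera_fragment": o.chimera.fragment_length if o.chimera else 0,
                "cms_start": o.cms_interval[0],
                "cms_end": o.cms_interval[1],
            }
            for o in truth.orfs
        ]
    ).to_csv(outdir / "truth_orfs.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(s) for s in truth.snps]).to_csv(
        outdir / "truth_snps.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(r) for r in truth.repeats]).to_csv(
        outdir / "truth_repeats.tsv", sep="\t", index=False
    )
    (outdir / "truth_summary.json").write_text(
        json.dumps(
            {
                "seed": truth.seed,
                "donor_fraction_actual": truth.donor_fraction_actual,
                "n_specific_orfs": len(truth.orfs),
                "n_candidates": len(truth.candidate_names()),
                "indels": [dataclasses.asdict(i) for i in truth.indels],
            },
            indent=2,
        )
    )
    return outdir
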