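"""Genome containers, circular-coordinate arithmetic and composition summaries.

Organelle genomes (plant mitochondria and chloroplasts) assemble as circular
molecules; every downstream stage therefore needs slicing and feature
coordinates that wrap across the origin.  Internally all coordinates are
0-based half-open; reports use 1-based inclusive (GenBank convention).

Sequences are restricted to the alphabet {A, C, G, T, N}.  Other IUPAC
ambiguity codes are rejected at parse time so that downstream classifiers
(codon translation, transition/transversion calls) stay total.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "ORF")


class GenomeError(ValueError):
    """Raised for malformed genomes, annotations or coordinates."""


@dataclass
class CircularGenome:
    """A named circular (or linear) nucleotide sequence.

    Parameters
    ----------
    id : str
        Unique label, e.g. an accession.
    sequence : str
        Upper-case nucleotides over {A, C, G, T, N}.
    circular : bool
        Whether coordinate arithmetic wraps across the origin.
    source : str
        Free-text provenance (accession, simulator tag, ...).
    """

    id: str
    sequence: str
    circular: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise GenomeError(
                f"genome {self.id!r}: invalid characters {sorted(bad)}; "
                "alphabet is A/C/G/T/N"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Extract ``[start, end)``, wrapping across the origin if circular.

        ``end`` may exceed the genome length (the slice wraps); the returned
        string always has length ``end - start``.
        """
        n = len(self.sequence)
        if not 0 <= start < n:
            raise GenomeError(f"slice start {start} outside [0, {n})")
        if end < start:
            raise GenomeError(f"slice end {end} < start {start}")
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise GenomeError(
                f"genome {self.id!r} is linear; slice end {end} exceeds length {n}"
            )
        if end - start > n:
            raise GenomeError(f"slice longer than genome ({end - start} > {n})")
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class FeatureAnnotation:
    """One annotated feature: possibly multi-exon, possibly origin-spanning.

    ``segments`` are ``(start, end, strand)`` triples in 0-based half-open
    forward-strand genome coordinates, ordered 5'->3' on the coding strand.
    Reverse-strand features store forward coordinates with strand ``'-'``;
    extraction reverse-complements.
    """

    gene_name: str
    feature_type: str
    segments: list[tuple[int, int, str]]
    product: str | None = None

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise GenomeError(
                f"feature {self.gene_name!r}: unknown type {self.feature_type!r}"
            )
        if not self.segments:
            raise GenomeError(f"feature {self.gene_name!r}: no segments")
        for start, end, strand in self.segments:
            if strand not in "+-":
                raise GenomeError(f"feature {self.gene_name!r}: bad strand {strand!r}")
            if end <= start:
                raise GenomeError(
                    f"feature {self.gene_name!r}: empty segment ({start}, {end})"
                )

    @property
    def strand(self) -> str:
        return self.segments[0][2]

    @property
    def start(self) -> int:
        """Leftmost genome coordinate of the feature footprint."""
        return min(s for s, _, _ in self.segments)

    @property
    def end(self) -> int:
        """Rightmost genome coordinate (exclusive) of the footprint."""
        return max(e for _, e, _ in self.segments)

    def extract(self, genome: CircularGenome) -> str:
        """Exon-joined sequence on the coding strand."""
        parts = [genome.slice(s, e) for s, e, _ in self.segments]
        if self.strand == "-":
            # segments are ordered 5'->3' on the coding strand already
            return "".join(reverse_complement(p) for p in parts)
        return "".join(parts)


@dataclass
class GenomeSet:
    """Genomes keyed by role (cms / maintainer / donor / ...)."""

    genomes: dict[str, CircularGenome] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genomes:
            raise GenomeError("GenomeSet requires at least one genome")

    def __getitem__(self, role: str) -> CircularGenome:
        return self.genomes[role]

    def roles(self) -> list[str]:
        return list(self.genomes)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise GenomeError(f"reverse_complement: invalid characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def circular_slice(genome: CircularGenome, start: int, end: int) -> str:
    """Functional form of :meth:`CircularGenome.slice`."""
    return genome.slice(start, end)


def gc_content(genome: CircularGenome | str) -> float:
    """G+C percentage, N excluded from numerator and denominator.

    Rounded half-up to 2 decimals, the precision organelle papers print.
    """
    seq = genome.sequence if isinstance(genome, CircularGenome) else genome
    counts = collections.Counter(seq)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise GenomeError("gc_content undefined: sequence is all N")
    pct = Decimal(100 * (counts["G"] + counts["C"])) / Decimal(denom)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _features_from_record(record: SeqRecord) -> list[FeatureAnnotation]:
    out: list[FeatureAnnotation] = []
    for feat in record.features:
        if feat.type not in FEATURE_TYPES:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or quals.get("label") or [feat.type])[0]
        product = (quals.get("product") or [None])[0]
        segments = []
        for part in feat.location.parts:
            strand = "-" if part.strand == -1 else "+"
            segments.append((int(part.start), int(part.end), strand))
        if feat.location.strand == -1:
            # Biopython lists parts in genome order; coding order for a
            # reverse-strand join is the reverse.
            segments = segments[::-1]
        out.append(
            FeatureAnnotation(
                gene_name=str(name), feature_type=feat.type, segments=segments,
                product=product,
            )
        )
    return out


def read_genome(
    path: str | Path, format: str = "fasta", circular: bool = True
) -> tuple[CircularGenome, list[FeatureAnnotation]]:
    """Read a genome (first record) from FASTA or a GenBank flat file.

    Returns ``(genome, annotations)``; the annotation list is empty for FASTA.
    Sequences are upper-cased and U is mapped to T.  Characters outside
    {A,C,G,T,N} raise :class:`GenomeError`.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("fasta", "genbank", "gb"):
        raise GenomeError(f"unsupported format {format!r}")
    fmt = "genbank" if fmt in ("genbank", "gb") else "fasta"
    try:
        record = next(SeqIO.parse(str(path), fmt))
    except StopIteration:
        raise GenomeError(f"{path}: no records found")
    except ValueError as exc:
        raise GenomeError(f"{path}: parse error: {exc}") from exc
    seq = str(record.seq).upper().replace("U", "T")
    if fmt == "genbank":
        circular = record.annotations.get("topology", "circular") == "circular"
    genome = CircularGenome(
        id=record.id, sequence=seq, circular=circular, source=str(path)
    )
    annotations = _features_from_record(record) if fmt == "genbank" else []
    return genome, annotations


def read_genomes(path: str | Path, format: str = "fasta") -> list[CircularGenome]:
    """All records of a (multi-)FASTA as genomes."""
    out = []
    for record in SeqIO.parse(str(path), format):
        seq = str(record.seq).upper().replace("U", "T")
        out.append(CircularGenome(id=record.id, sequence=seq, source=str(path)))
    return out


def write_genome(
    genome: CircularGenome,
    path: str | Path,
    format: str = "fasta",
    annotations: Iterable[FeatureAnnotation] = (),
) -> None:
    """Write FASTA or an annotated GenBank flat file (lossless round-trip)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description=genome.source)
    fmt = "genbank" if format.lower() in ("genbank", "gb") else "fasta"
    if fmt == "genbank":
        record.annotations["molecule_type"] = "DNA"
        record.annotations["topology"] = "circular" if genome.circular else "linear"
        for ann in annotations:
            segs = ann.segments
            if ann.strand == "-":
                segs = segs[::-1]
            locs = [
                SimpleLocation(s, e, -1 if strand == "-" else 1)
                for s, e, strand in segs
            ]
            location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
            quals = {"gene": [ann.gene_name]}
            if ann.product:
                quals["product"] = [ann.product]
            record.features.append(
                SeqFeature(location, type=ann.feature_type, qualifiers=quals)
            )
    SeqIO.write([record], str(path), fmt)


def write_gff3(
    genome: CircularGenome,
    annotations: Iterable[FeatureAnnotation],
    path: str | Path,
    source: str = "cms-scan",
) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {len(genome)}"]
    for i, ann in enumerate(sorted(annotations, key=lambda a: a.start), start=1):
        for s, e, strand in ann.segments:
            lines.append(
                "\t".join(
                    [
                        genome.id,
                        source,
                        ann.feature_type,
                        str(s + 1),
                        str(e),
                        ".",
                        strand,
                        ".",
                        f"ID={ann.gene_name}.{i};Name={ann.gene_name}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def annotation_summary(
    genome: CircularGenome, annotations: Iterable[FeatureAnnotation]
) -> dict[str, int]:
    """Feature counts by type plus total genome length and GC.

    Duplicated genes (e.g. chloroplast IR copies) count once per feature
    record, matching how deposited feature tables enumerate them; genes
    appearing more than once are additionally reported as ``duplicated``.
    """
    counts = {t: 0 for t in FEATURE_TYPES}
    names = collections.Counter()
    for ann in annotations:
        counts[ann.feature_type] += 1
        names[(ann.feature_type, ann.gene_name)] += 1
    counts["duplicated"] = sum(1 for n in names.values() if n > 1)
    counts["length_bp"] = len(genome)
    counts["gc_percent"] = gc_content(genome)
    return counts
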