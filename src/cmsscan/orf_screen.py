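"""ORF calling on circular genomes and CMS-specificity screening.

An ORF runs from an ATG to the first in-frame stop (standard genetic code;
plant mitochondria use it).  For each (stop, frame) only the longest
ATG-initiated ORF is kept, so nested starts never double-count.  Circular
genomes are scanned on the doubled sequence so that origin-spanning ORFs
are found, and duplicates are collapsed by their stop position modulo the
genome length.

The specificity screen mirrors the sterility-gene hunt: every ORF called in
the sterile (CMS) mitogenome is searched against the fertile maintainer
genome; ORFs with no qualifying hit are "CMS-specific" candidates.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

from .align_core import infix_search
from .genome_io import CircularGenome, FeatureAnnotation, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = dict(zip(_CODONS, _AA))


def translate(nt: str) -> str:
    """Standard-code conceptual translation; incomplete/ambiguous codons -> X."""
    return "".join(
        CODON_TABLE.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3)
    )


@dataclass
class OrfRecord:
    """A called open reading frame.

    ``start``/``end`` are half-open forward-strand genome coordinates of the
    footprint; ``end`` may exceed the genome length for origin-spanning ORFs
    (interpret modulo length).  ``sequence`` is the coding-strand nucleotide
    sequence including the stop codon; ``protein`` excludes the stop.
    """

    orf_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    nt_length: int
    sequence: str
    protein: str
    protein_length: int

    def __post_init__(self) -> None:
        assert self.nt_length % 3 == 0
        assert self.nt_length == 3 * (self.protein_length + 1)
        assert self.sequence[:3] == "ATG"
        assert self.sequence[-3:] in STOP_CODONS
        assert "*" not in self.protein


@dataclass
class PresenceCall:
    orf_id: str
    present_in: str
    coverage: float
    identity: float
    verdict: str  # "present" | "absent"


def _scan_strand(seq: str, min_nt: int) -> list[tuple[int, int]]:
    """(start, end) of maximal ATG->stop ORFs on one strand of ``seq``."""
    out = []
    n = len(seq)
    for frame in range(3):
        start = -1  # first ATG since the last stop, -1 if none
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start >= 0 and pos + 3 - start >= min_nt:
                    out.append((start, pos + 3))
                start = -1
            elif codon == "ATG" and start < 0:
                start = pos
    return out


def find_orfs(
    genome: CircularGenome, min_protein_length: int = 101
) -> list[OrfRecord]:
    """Call ORFs with conceptual translation >= ``min_protein_length`` aa.

    Both strands are scanned; for circular genomes the doubled sequence is
    scanned and ORFs longer than the genome are discarded.  ORFs are named
    ``orf{protein_length}`` (a/b/... suffixes on ties) in genome order.
    """
    L = len(genome)
    min_nt = 3 * (min_protein_length + 1)
    fwd = genome.sequence * 2 if genome.circular else genome.sequence
    scan_len = len(fwd)
    # key (strand, canonical stop position) -> best candidate
    best: dict[tuple[str, int], tuple[int, int, int]] = {}

    def _consider(strand: str, fp_start: int, nt_length: int, stop_key: int) -> None:
        if nt_length > L:
            return
        key = (strand, stop_key % L)
        cur = best.get(key)
        if cur is None or nt_length > cur[2]:
            best[key] = (fp_start % L, nt_length, nt_length)

    for s, e in _scan_strand(fwd, min_nt):
        _consider("+", s, e - s, e)
    rc = reverse_complement(fwd)
    for s, e in _scan_strand(rc, min_nt):
        # map revcomp-scan coordinates back to forward footprint
        fp_start = scan_len - e
        _consider("-", fp_start, e - s, fp_start)

    records = []
    for (strand, _), (start, nt_length, _) in best.items():
        end = start + nt_length
        nt = genome.slice(start, end) if end > L else genome.sequence[start:end]
        if strand == "-":
            nt = reverse_complement(nt)
        protein = translate(nt[:-3])
        records.append(
            OrfRecord(
                orf_id="",
                genome_id=genome.id,
                start=start,
                end=end,
                strand=strand,
                nt_length=nt_length,
                sequence=nt,
                protein=protein,
                protein_length=len(protein),
            )
        )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    _assign_names(records)
    return records


def _assign_names(records: list[OrfRecord]) -> None:
    by_len: dict[int, list[OrfRecord]] = {}
    for rec in records:
        by_len.setdefault(rec.protein_length, []).append(rec)
    for plen, group in by_len.items():
        if len(group) == 1:
            group[0].orf_id = f"orf{plen}"
        else:
            for rec, suffix in zip(group, string.ascii_lowercase):
                rec.orf_id = f"orf{plen}{suffix}"


def call_presence(
    orf: OrfRecord,
    target: CircularGenome,
    coverage_min: float = 0.90,
    identity_min: float = 95.0,
) -> PresenceCall:
    """Search the ORF nucleotide sequence against a target genome.

    Both strands are searched (the target is doubled when circular so
    origin-spanning placements are found).  ``coverage`` is the fraction of
    ORF bases aligned to a target base in the best placement; ``verdict`` is
    ``present`` iff coverage and identity clear their thresholds.
    """
    query = orf.sequence
    ref = target.sequence
    if target.circular:
        ref = ref + ref[: min(len(ref), 2 * len(query))]
    hits = [infix_search(query, ref), infix_search(query, reverse_complement(ref))]
    hit = max(hits, key=lambda h: (h.matches, h.score))
    coverage = (hit.matches + hit.mismatches) / len(query)
    identity = hit.identity
    verdict = "present" if coverage >= coverage_min and identity >= identity_min else "absent"
    return PresenceCall(
        orf_id=orf.orf_id,
        present_in=target.id,
        coverage=round(coverage, 4),
        identity=round(identity, 2),
        verdict=verdict,
    )


@dataclass
class OrfScreenParams:
    min_protein_length: int = 101
    coverage_min: float = 0.90
    identity_min: float = 95.0


def specific_orfs(
    cms: CircularGenome,
    maintainer: CircularGenome,
    params: OrfScreenParams | None = None,
) -> list[OrfRecord]:
    """ORFs of the CMS genome with verdict=absent in the maintainer,
    in genome-position order."""
    params = params or OrfScreenParams()
    out = []
    for orf in find_orfs(cms, params.min_protein_length):
        call = call_presence(orf, maintainer, params.coverage_min, params.identity_min)
        if call.verdict == "absent":
            out.append(orf)
    return out


def orfs_to_annotations(orfs: list[OrfRecord], genome_length: int) -> list[FeatureAnnotation]:
    """ORF records as ORF-typed feature annotations (wrapping split in two)."""
    anns = []
    for orf in orfs:
        if orf.end <= genome_length:
            segs = [(orf.start, orf.end, orf.strand)]
        else:
            segs = [
                (orf.start, genome_length, orf.strand),
                (0, orf.end - genome_length, orf.strand),
            ]
            if orf.strand == "-":
                segs = segs[::-1]
        anns.append(FeatureAnnotation(orf.orf_id, "ORF", segs))
    return anns
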