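"""Pairwise alignment engines and identity metrics.

Two engines sit behind one result type:

* affine-gap Smith-Waterman / Needleman-Wunsch (``local_align`` /
  ``global_align``) via Bio.Align.PairwiseAligner, used at gene scale
  (chimera detection, CDS comparison, distances);
* unit-cost infix search (``infix_search``) via edlib, used when a short
  query is located inside a whole organelle genome.

Identity is always ``matches / alignment columns`` with gap columns in the
denominator, so adding gaps can only lower identity.  The default
nucleotide scheme (+2/-3, gap open -5, extend -2, BLASTN-like, where a gap
of length k costs open + k*extend) emulates the megablast-style scoring
organelle comparisons are usually run with.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scores; a gap of length k scores ``gap_open + k*gap_extend``."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise AlignmentError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("penalties must be <= 0")


#: protein-level default (identity scoring; adequate for p-distances and
#: difference counts between close homologs)
PROTEIN_SCHEME = ScoringScheme(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)


@dataclass
class AlignmentResult:
    score: float
    aligned_length: int
    matches: int
    mismatches: int
    gap_columns: int
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    strand: str = "+"
    cigar: str = ""

    @property
    def identity(self) -> float:
        """Percent identity over alignment columns (gaps count against)."""
        if self.aligned_length == 0:
            return 0.0
        return 100.0 * self.matches / self.aligned_length

    def __post_init__(self) -> None:
        assert self.matches + self.mismatches + self.gap_columns == self.aligned_length


def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # PairwiseAligner's open score already includes the first gap column.
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _cigar(alignment) -> str:
    ops = []
    qa, ra = alignment[0], alignment[1]  # aligned strings with dashes
    for q, r in zip(qa, ra):
        if q == "-":
            op = "D"
        elif r == "-":
            op = "I"
        elif q == r:
            op = "="
        else:
            op = "X"
        if ops and ops[-1][1] == op:
            ops[-1][0] += 1
        else:
            ops.append([1, op])
    return "".join(f"{n}{op}" for n, op in ops)


def _result_from(alignment, strand: str = "+") -> AlignmentResult:
    counts = alignment.counts()
    matches = counts.identities
    mismatches = counts.mismatches
    gaps = counts.gaps
    blocks_q, blocks_r = alignment.aligned
    if len(blocks_q):
        q_iv = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
        r_iv = (int(blocks_r[0][0]), int(blocks_r[-1][1]))
    else:  # degenerate: all-gap alignment
        q_iv = (0, 0)
        r_iv = (0, 0)
    return AlignmentResult(
        score=float(alignment.score),
        aligned_length=matches + mismatches + gaps,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        query_interval=q_iv,
        ref_interval=r_iv,
        strand=strand,
        cigar=_cigar(alignment),
    )


def local_align(
    query: str, ref: str, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal affine-gap Smith-Waterman local alignment.

    The engine's alignment enumeration order is deterministic; the first
    optimal alignment is reported.
    """
    if not query or not ref:
        raise AlignmentError("local_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    alignments = _aligner(scheme, "local").align(query.upper(), ref.upper())
    try:
        return _result_from(alignments[0])
    except IndexError:
        # no positive-scoring local alignment exists: the empty alignment
        return AlignmentResult(0.0, 0, 0, 0, 0, (0, 0), (0, 0))


def local_align_all(
    query: str,
    ref: str,
    scheme: ScoringScheme | None = None,
    min_score: float = 20.0,
) -> list[AlignmentResult]:
    """Greedy non-overlapping local hits: best hit, then recurse on the
    query prefix/suffix outside it.  Sorted by query start."""
    scheme = scheme or ScoringScheme()
    hits: list[AlignmentResult] = []

    def _recurse(q: str, offset: int) -> None:
        if len(q) < 4:
            return
        hit = local_align(q, ref, scheme)
        if hit.score < min_score or hit.matches == 0:
            return
        qs, qe = hit.query_interval
        hit.query_interval = (qs + offset, qe + offset)
        hits.append(hit)
        _recurse(q[:qs], offset)
        _recurse(q[qe:], offset + qe)

    _recurse(query.upper(), 0)
    return sorted(hits, key=lambda h: h.query_interval[0])


def global_align(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """End-to-end affine-gap Needleman-Wunsch (end gaps penalized)."""
    if not a or not b:
        raise AlignmentError("global_align requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    alignments = _aligner(scheme, "global").align(a.upper(), b.upper())
    return _result_from(alignments[0])


def infix_search(query: str, ref: str) -> AlignmentResult:
    """Best placement of the whole ``query`` inside ``ref`` under unit edit
    costs (edlib HW mode).  Fast enough for ORF-vs-genome searches."""
    if not query or not ref:
        raise AlignmentError("infix_search requires non-empty sequences")
    res = edlib.align(query.upper(), ref.upper(), mode="HW", task="path")
    loc = res["locations"][0]
    cigar = res["cigar"] or ""
    matches = mismatches = gaps = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
        elif ch == "X":
            mismatches += n
        else:  # I / D
            gaps += n
    return AlignmentResult(
        score=-float(res["editDistance"]),
        aligned_length=matches + mismatches + gaps,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        query_interval=(0, len(query)),
        ref_interval=(int(loc[0]), int(loc[1]) + 1),
        cigar=cigar,
    )


def edit_align_path(a: str, b: str) -> str:
    """Global unit-cost alignment path (extended CIGAR) between two long,
    near-identical sequences.  Used to close gaps between synteny anchors."""
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    return res["cigar"] or ""


def percent_identity(
    a: str, b: str, level: str = "nucleotide"
) -> tuple[float, int]:
    """Global-alignment identity (1 decimal) and difference count.

    Differences = mismatch columns + gap columns.  ``level`` selects the
    default scoring scheme (nucleotide or protein).
    """
    if not a or not b:
        raise AlignmentError("percent_identity requires non-empty sequences")
    scheme = PROTEIN_SCHEME if level == "protein" else ScoringScheme()
    res = global_align(a, b, scheme)
    identity = round(100.0 * res.matches / res.aligned_length, 1)
    return identity, res.mismatches + res.gap_columns
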