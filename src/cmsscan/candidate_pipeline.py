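"""Evidence integration: from specific ORFs to ranked CMS candidates.

Plant sterility genes are, almost without exception, novel mitochondrial
ORFs that (i) are absent from the fertile maintainer, (ii) encode at least
one membrane-spanning segment, and (iii) are chimeric — they embed a
fragment of a core mitochondrial gene (atp8, cox1, ...).  This module
scores each specific ORF on those axes plus genomic context (nearest
functional gene) and parental origin, and tiers the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import ScoringScheme, local_align
from .genome_io import CircularGenome, FeatureAnnotation, reverse_complement
from .orf_screen import OrfRecord
from .tm_predict import TmResult


class PipelineError(ValueError):
    pass


@dataclass
class ChimeraHit:
    orf_id: str
    core_gene: str
    fragment_length: int  # aligned columns of the local hit
    identity: float
    orf_interval: tuple[int, int]
    gene_interval: tuple[int, int]
    strand: str = "+"


@dataclass
class NearestGene:
    gene_name: str
    distance: int  # intergenic gap in bp, 0 if overlapping
    relative_position: str  # the ORF lies upstream | downstream of the gene


@dataclass
class CandidateReport:
    orf_id: str
    specific: bool
    tm_count: int
    chimera: list[ChimeraHit] = field(default_factory=list)
    nearest_gene: NearestGene | None = None
    origin: str = "novel"
    rank_tier: str = "excluded"  # candidate | supporting | excluded


def _identity_core(res) -> tuple[int, int, float, tuple[int, int], tuple[int, int]]:
    """Trim a local hit to its maximal-identity core.

    Smith-Waterman under a relatedness scheme may drag low-identity flanks
    into a hit when the two sequences share base composition.  Rescoring
    the alignment columns with match +1 / mismatch or gap -2 and taking the
    maximum-scoring contiguous run (Kadane) keeps exactly the high-identity
    fragment.  Returns (columns, matches, identity, q_interval, r_interval)
    in local (alignment-start-relative) coordinates.
    """
    cols: list[tuple[str, int, int]] = []  # (op, q_advance, r_advance)
    num = ""
    for ch in res.cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        adv = {"=": (1, 1), "X": (1, 1), "I": (1, 0), "D": (0, 1)}[ch]
        cols.extend([(ch, *adv)] * n)
    best = (0.0, 0, 0)  # score, start, end
    score, start = 0.0, 0
    for i, (op, _, _) in enumerate(cols):
        score += 1.0 if op == "=" else -2.0
        if score <= 0:
            score, start = 0.0, i + 1
        elif score > best[0]:
            best = (score, start, i + 1)
    _, s, e = best
    q_off = sum(c[1] for c in cols[:s])
    r_off = sum(c[2] for c in cols[:s])
    q_len = sum(c[1] for c in cols[s:e])
    r_len = sum(c[2] for c in cols[s:e])
    matches = sum(1 for c in cols[s:e] if c[0] == "=")
    n_cols = e - s
    identity = 100.0 * matches / n_cols if n_cols else 0.0
    return n_cols, matches, identity, (q_off, q_off + q_len), (r_off, r_off + r_len)


def detect_chimera(
    orf: OrfRecord,
    core_genes: dict[str, str],
    min_fragment: int = 100,
    min_identity: float = 90.0,
    scheme: ScoringScheme | None = None,
) -> list[ChimeraHit]:
    """Best qualifying local hit of the ORF against each core gene CDS.

    Both gene strands are searched.  An ORF whose best hit covers >= 80% of
    the ORF at >= 95% identity is a displaced copy of the core gene itself,
    not a chimera, and yields no hits.
    """
    if not core_genes:
        raise PipelineError("core gene set is empty")
    scheme = scheme or ScoringScheme()
    hits: list[ChimeraHit] = []
    best_cover = 0.0
    best_cover_identity = 0.0
    for gene, cds in core_genes.items():
        candidates = []
        for strand, target in (("+", cds), ("-", reverse_complement(cds))):
            res = local_align(orf.sequence, target, scheme)
            if res.aligned_length == 0:
                continue
            gi = res.ref_interval
            if strand == "-":
                gi = (len(cds) - gi[1], len(cds) - gi[0])
            candidates.append((res, gi, strand))
        if not candidates:
            continue
        res, gi, strand = max(candidates, key=lambda c: (c[0].score, c[0].matches))
        cover = (res.query_interval[1] - res.query_interval[0]) / orf.nt_length
        if cover > best_cover:
            best_cover = cover
            best_cover_identity = res.identity
        n_cols, _, identity, q_core, r_core = _identity_core(res)
        if n_cols >= min_fragment and identity >= min_identity:
            q_iv = (res.query_interval[0] + q_core[0], res.query_interval[0] + q_core[1])
            if strand == "+":
                g_iv = (res.ref_interval[0] + r_core[0], res.ref_interval[0] + r_core[1])
            else:
                g_iv = (gi[1] - r_core[1], gi[1] - r_core[0])
            hits.append(
                ChimeraHit(
                    orf_id=orf.orf_id,
                    core_gene=gene,
                    fragment_length=n_cols,
                    identity=round(identity, 2),
                    orf_interval=q_iv,
                    gene_interval=g_iv,
                    strand=strand,
                )
            )
    if best_cover >= 0.80 and best_cover_identity >= 95.0:
        return []  # a relocated core-gene copy, not a chimeric novel ORF
    hits.sort(key=lambda h: (-h.identity * h.fragment_length, h.core_gene))
    return hits


def _circular_gap(a_start: int, a_end: int, b_start: int, b_end: int, L: int) -> tuple[int, str]:
    """Signed circular gap between two footprints on a circle of length L.

    Returns (gap, side) where side is 'right' if b lies clockwise of a's
    end, 'left' if counter-clockwise of a's start; gap 0 on overlap.
    """
    len_a, len_b = a_end - a_start, b_end - b_start
    right = (b_start - a_end) % L
    left = (a_start - b_end) % L
    # for disjoint arcs the two gaps and both spans tile the circle exactly
    if len_a + len_b >= L or right + left != L - len_a - len_b:
        return 0, "overlap"
    if right <= left:
        return right, "right"
    return left, "left"


def genomic_context(
    orf: OrfRecord,
    annotations: list[FeatureAnnotation],
    genome_length: int,
) -> NearestGene | None:
    """Nearest annotated gene and the intergenic distance to it.

    Distances are measured on the circle between feature footprints.
    ``relative_position`` says where the ORF sits relative to the gene
    along the ORF's own strand: an ORF whose 3' end precedes the gene is
    "upstream" of it.  Ties break toward the upstream neighbor.  Returns
    None when the annotation list is empty.
    """
    genes = [a for a in annotations if a.feature_type in ("CDS", "tRNA", "rRNA")]
    if not genes:
        return None
    best: tuple[int, int, str, str] | None = None  # (distance, tie_rank, side, name)
    for ann in genes:
        gap, side = _circular_gap(orf.start, orf.end, ann.start, ann.end, genome_length)
        if side == "overlap":
            gap = 0
            rel = "overlapping"
        else:
            # a gene to the genome-right of a + strand ORF has the ORF
            # upstream of it
            rel = "upstream" if (side == "right") == (orf.strand == "+") else "downstream"
        tie_rank = 0 if rel == "upstream" else 1
        key = (gap, tie_rank, ann.gene_name)
        if best is None or key < (best[0], best[1], best[3]):
            best = (gap, tie_rank, rel, ann.gene_name)
    return NearestGene(gene_name=best[3], distance=best[0], relative_position=best[2])


def assign_origin(
    orf: OrfRecord,
    donor: CircularGenome,
    recipient: CircularGenome,
    min_split: int = 20,
) -> str:
    """Parental origin of an ORF by exact full-length search.

    ``donor_identical`` / ``recipient_identical``: the full ORF occurs
    verbatim (either strand, across the origin) in that parent —
    checked donor first, mirroring the screen's direction of interest.
    ``recombinant``: the ORF splits into a donor prefix and recipient
    suffix (or vice versa), each at least ``min_split`` nt.
    ``novel``: none of the above.
    """

    def searchable(g: CircularGenome) -> str:
        s = g.sequence + (g.sequence[: len(orf.sequence)] if g.circular else "")
        return s + "#" + reverse_complement(s)

    d_seq, r_seq = searchable(donor), searchable(recipient)
    seq = orf.sequence
    if seq in d_seq:
        return "donor_identical"
    if seq in r_seq:
        return "recipient_identical"

    def longest_prefix_in(hay: str) -> int:
        lo, hi = 0, len(seq)
        while lo < hi:  # binary search: prefix containment is monotone
            mid = (lo + hi + 1) // 2
            if seq[:mid] in hay:
                lo = mid
            else:
                hi = mid - 1
        return lo

    def longest_suffix_in(hay: str) -> int:
        lo, hi = 0, len(seq)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if seq[-mid:] in hay:
                lo = mid
            else:
                hi = mid - 1
        return lo

    for first, second in ((d_seq, r_seq), (r_seq, d_seq)):
        p = longest_prefix_in(first)
        s = longest_suffix_in(second)
        if p >= min_split and s >= min_split and p + s >= len(seq):
            return "recombinant"
    return "novel"


def rank_candidates(
    specific: list[OrfRecord],
    tm: dict[str, TmResult],
    chimera: dict[str, list[ChimeraHit]],
    context: dict[str, NearestGene | None] | None = None,
    origin: dict[str, str] | None = None,
) -> list[CandidateReport]:
    """Deterministic tiering of specific ORFs.

    candidate:  specific AND tm_count >= 1 AND chimeric;
    supporting: specific AND (tm_count >= 1 OR chimeric);
    excluded:   everything else.
    Candidates sort by (best chimera identity x fragment length, tm_count)
    descending.
    """
    context = context or {}
    origin = origin or {}
    for key_map, label in ((tm, "tm"), (chimera, "chimera")):
        missing = {o.orf_id for o in specific} - set(key_map)
        if missing:
            raise PipelineError(f"{label} results missing for ORFs: {sorted(missing)}")
    reports = []
    for orf in specific:
        tm_count = tm[orf.orf_id].count
        hits = chimera[orf.orf_id]
        if tm_count >= 1 and hits:
            tier = "candidate"
        elif tm_count >= 1 or hits:
            tier = "supporting"
        else:
            tier = "excluded"
        reports.append(
            CandidateReport(
                orf_id=orf.orf_id,
                specific=True,
                tm_count=tm_count,
                chimera=hits,
                nearest_gene=context.get(orf.orf_id),
                origin=origin.get(orf.orf_id, "novel"),
                rank_tier=tier,
            )
        )

    def sort_key(rep: CandidateReport):
        tier_rank = {"candidate": 0, "supporting": 1, "excluded": 2}[rep.rank_tier]
        chim = max((h.identity * h.fragment_length for h in rep.chimera), default=0.0)
        return (tier_rank, -chim, -rep.tm_count, rep.orf_id)

    reports.sort(key=sort_key)
    return reports
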