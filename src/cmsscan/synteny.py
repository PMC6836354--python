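"""Collinearity blocks between two organelle genomes.

A self-contained anchor-and-chain aligner: maximal unique k-mer matches on
both strands are chained when collinear and close, inter-anchor gaps are
closed with unit-cost global alignment, and each chain is reported as a
block with per-column statistics.  Coverage is the fraction of the *query*
genome inside blocks; identity is match columns over all block columns.

This trades the generality of a whole-genome aligner for determinism and
zero external binaries, which is enough for megabase-free organelle work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import edit_align_path
from .genome_io import CircularGenome, reverse_complement


@dataclass(frozen=True)
class Anchor:
    """Maximal unique k-mer match.

    ``r`` is the forward-strand footprint start on the reference; for a
    ``-`` anchor the query segment matches the reverse complement of
    ``ref[r:r+length]``.
    """

    q: int
    r: int
    strand: str
    length: int


@dataclass
class SyntenyBlock:
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    strand: str
    length: int
    matches: int = 0
    mismatches: int = 0
    gap_columns: int = 0
    gap_runs: list[int] = field(default_factory=list)

    @property
    def identity(self) -> float:
        cols = self.matches + self.mismatches + self.gap_columns
        return 100.0 * self.matches / cols if cols else 0.0


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
        pos[kmer] = i
    return {kmer: p for kmer, p in pos.items() if counts[kmer] == 1}


def _merge_diagonal(matches: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Collapse (q, r) seed matches into maximal runs along each diagonal."""
    out: list[tuple[int, int, int]] = []
    by_diag: dict[int, list[int]] = {}
    for q, r in matches:
        by_diag.setdefault(q - r, []).append(q)
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q == prev + 1:
                prev = q
                continue
            out.append((start, start - diag, prev - start + k))
            start = prev = q
        out.append((start, start - diag, prev - start + k))
    return out


def anchor_map(query: CircularGenome, ref: CircularGenome, k: int = 31) -> list[Anchor]:
    """All maximal matches of k-mers unique in both genomes, both strands."""
    q_seq, r_seq = query.sequence, ref.sequence
    q_unique = _unique_kmer_positions(q_seq, k)
    r_unique = _unique_kmer_positions(r_seq, k)
    rc_ref = reverse_complement(r_seq)
    rc_unique = _unique_kmer_positions(rc_ref, k)

    fwd = [(qp, r_unique[kmer]) for kmer, qp in q_unique.items() if kmer in r_unique]
    rev = [(qp, rc_unique[kmer]) for kmer, qp in q_unique.items() if kmer in rc_unique]

    anchors = [Anchor(q, r, "+", ln) for q, r, ln in _merge_diagonal(fwd, k)]
    L = len(r_seq)
    for q, r_scan, ln in _merge_diagonal(rev, k):
        anchors.append(Anchor(q, L - r_scan - ln, "-", ln))
    anchors.sort(key=lambda a: (a.q, a.r))
    return anchors


def _gap_stats(q_seg: str, r_seg: str) -> tuple[int, int, int, list[int]]:
    """(matches, mismatches, gap_columns, gap_runs) of a closed gap."""
    if not q_seg and not r_seg:
        return 0, 0, 0, []
    if not q_seg or not r_seg:
        n = len(q_seg) + len(r_seg)
        return 0, 0, n, [n]
    matches = mismatches = gap_cols = 0
    runs: list[int] = []
    num = ""
    for ch in edit_align_path(q_seg, r_seg):
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
        elif ch == "X":
            mismatches += n
        else:
            gap_cols += n
            runs.append(n)
    return matches, mismatches, gap_cols, runs


def chain_blocks(
    anchors: list[Anchor],
    query: CircularGenome,
    ref: CircularGenome,
    max_gap: int = 2000,
    min_block: int = 500,
    gap_identity_floor: float = 70.0,
    max_unbalanced: int = 200,
) -> tuple[list[SyntenyBlock], dict[str, float]]:
    """Chain collinear anchors into blocks and summarize coverage/identity.

    Anchors sorted by query position are appended to the current chain when
    they keep the strand, advance monotonically on both genomes and leave
    gaps of at most ``max_gap`` on each; otherwise a new chain starts.
    Inter-anchor gaps are closed with unit-cost global alignment so every
    block carries exact column statistics.  A gap that does not actually
    align — closed identity below ``gap_identity_floor`` over a substantial
    gap, or a size imbalance beyond ``max_unbalanced`` bp — splits the block
    instead (the unaligned stretch counts as uncovered, the way a union of
    local alignment hits would).  Blocks shorter than ``min_block`` on the
    query are dropped.
    """
    L_ref = len(ref)
    rc_ref = reverse_complement(ref.sequence)

    def scan_start(a: Anchor) -> int:
        return a.r if a.strand == "+" else L_ref - a.r - a.length

    chains: list[list[Anchor]] = []
    for a in sorted(anchors, key=lambda x: (x.q, x.r)):
        placed = False
        if chains:
            chain = chains[-1]
            prev = chain[-1]
            if a.strand == prev.strand:
                q_gap = a.q - (prev.q + prev.length)
                r_gap = scan_start(a) - (scan_start(prev) + prev.length)
                # around an indel the flanking maximal runs may overlap by
                # a few bases; tolerate bounded overlap (trimmed later)
                if -62 <= q_gap <= max_gap and -62 <= r_gap <= max_gap:
                    chain.append(a)
                    placed = True
        if not placed:
            chains.append([a])

    blocks: list[SyntenyBlock] = []

    def finalize(run: list[Anchor], stats: tuple[int, int, int, list[int]]) -> None:
        first, last = run[0], run[-1]
        q_iv = (first.q, last.q + last.length)
        if last.strand == "+":
            r_iv = (first.r, last.r + last.length)
        else:
            r_iv = (last.r, first.r + first.length)
        block = SyntenyBlock(
            query_interval=q_iv,
            ref_interval=r_iv,
            strand=first.strand,
            length=q_iv[1] - q_iv[0],
            matches=stats[0] + sum(a.length for a in run),
            mismatches=stats[1],
            gap_columns=stats[2],
            gap_runs=stats[3],
        )
        if block.length >= min_block:
            blocks.append(block)

    for chain in chains:
        ref_scan = ref.sequence if chain[0].strand == "+" else rc_ref
        run: list[Anchor] = [chain[0]]
        stats = (0, 0, 0, [])
        for a in chain[1:]:
            prev = run[-1]
            # trim any overlap with the previous anchor so gaps are clean
            trim = max(
                0,
                (prev.q + prev.length) - a.q,
                (scan_start(prev) + prev.length) - scan_start(a),
            )
            if trim >= a.length:
                continue
            if trim:
                a = Anchor(
                    q=a.q + trim,
                    r=a.r + trim if a.strand == "+" else a.r,
                    strand=a.strand,
                    length=a.length - trim,
                )
            q_seg = query.sequence[prev.q + prev.length : a.q]
            r_seg = ref_scan[scan_start(prev) + prev.length : scan_start(a)]
            split = abs(len(q_seg) - len(r_seg)) > max_unbalanced
            gap = (0, 0, 0, [])
            if not split:
                gap = _gap_stats(q_seg, r_seg)
                cols = gap[0] + gap[1] + gap[2]
                if (
                    min(len(q_seg), len(r_seg)) >= 50
                    and cols
                    and 100.0 * gap[0] / cols < gap_identity_floor
                ):
                    split = True
            if split:
                finalize(run, stats)
                run = [a]
                stats = (0, 0, 0, [])
            else:
                run.append(a)
                stats = (
                    stats[0] + gap[0],
                    stats[1] + gap[1],
                    stats[2] + gap[2],
                    stats[3] + gap[3],
                )
        finalize(run, stats)

    covered = _interval_union_length([b.query_interval for b in blocks])
    total_cols = sum(b.matches + b.mismatches + b.gap_columns for b in blocks)
    total_matches = sum(b.matches for b in blocks)
    summary = {
        "coverage": round(100.0 * covered / len(query), 2),
        "identity": round(100.0 * total_matches / total_cols, 2) if total_cols else 0.0,
        "n_blocks": float(len(blocks)),
    }
    return blocks, summary


def _interval_union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
    return total


def compare_genomes(
    query: CircularGenome,
    ref: CircularGenome,
    k: int = 31,
    max_gap: int = 2000,
    min_block: int = 500,
) -> tuple[list[SyntenyBlock], dict[str, float]]:
    """Convenience wrapper: anchors + chaining in one call."""
    return chain_blocks(
        anchor_map(query, ref, k=k), query, ref, max_gap=max_gap, min_block=min_block
    )
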