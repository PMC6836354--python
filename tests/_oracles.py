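"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python dynamic
programming for affine-gap alignment, a quadratic longest-common-prefix
scan for repeats, and a dictionary hash-join for k-mer anchors.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def _gap_cost(scheme):
    # a gap of length k scores gap_open + k*gap_extend
    return scheme.gap_open + scheme.gap_extend, scheme.gap_extend


def nw_affine_score(a: str, b: str, scheme) -> float:
    """Global (end-to-end, end gaps penalized) affine-gap score."""
    open_cost, ext = _gap_cost(scheme)
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_cost + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0][j] = open_cost + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + ext)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + ext)
    return max(M[n][m], X[n][m], Y[n][m])


def sw_affine_score(a: str, b: str, scheme) -> float:
    """Local affine-gap score (Smith-Waterman)."""
    open_cost, ext = _gap_cost(scheme)
    n, m = len(a), len(b)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            M[i][j] = max(
                0.0,
                max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s,
            )
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + ext)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + ext)
            best = max(best, M[i][j])
    return best


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _lcp_matrix(s: str, t: str) -> np.ndarray:
    """lcp[i, j] = length of the common prefix of s[i:] and t[j:]."""
    n, m = len(s), len(t)
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    lcp = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(n - 1, -1, -1):
        eq = sa[i] == ta
        lcp[i, :-1] = np.where(eq, lcp[i + 1, 1:] + 1, 0)
    return lcp


def brute_force_repeats(seq: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal repeated pairs >= min_len on a linear sequence, as
    (length, pos_a, pos_b, orientation), via the quadratic LCP scan."""
    out: set[tuple[int, int, int, str]] = set()
    n = len(seq)
    lcp = _lcp_matrix(seq, seq)
    for i in range(n):
        for j in range(i + 1, n):
            ln = int(lcp[i, j])
            if ln < min_len:
                continue
            if i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                continue  # not left-maximal
            out.add((ln, i, j, "direct"))
    rc = _revcomp(seq)
    lcp_rc = _lcp_matrix(seq, rc)
    for i in range(n):
        for jr in range(n):
            ln = int(lcp_rc[i, jr])
            if ln < min_len:
                continue
            if i > 0 and jr > 0 and seq[i - 1] == rc[jr - 1]:
                continue
            j = n - jr - ln  # forward start of the inverted copy
            a, b = (i, j) if i < j else (j, i)
            if a == b:
                continue
            out.add((ln, a, b, "inverted"))
    return out


def hash_join_anchors(q: str, r: str, k: int) -> set[tuple[int, int, str]]:
    """Unique-in-both k-mer matches (seed level, unmerged), both strands."""

    def unique(s: str) -> dict[str, int]:
        seen: dict[str, list[int]] = {}
        for i in range(len(s) - k + 1):
            seen.setdefault(s[i : i + k], []).append(i)
        return {km: p[0] for km, p in seen.items() if len(p) == 1}

    qu, ru = unique(q), unique(r)
    rc = _revcomp(r)
    rcu = unique(rc)
    out: set[tuple[int, int, str]] = set()
    for km, qp in qu.items():
        if km in ru:
            out.add((qp, ru[km], "+"))
        if km in rcu:
            out.add((qp, len(r) - rcu[km] - k, "-"))
    return out


def tree_path_distances(tree) -> dict[frozenset, float]:
    """Leaf-pair path lengths of a PhyloTree (sum of branch lengths)."""

    dists: dict[frozenset, float] = {}

    def walk(node, depths: dict[str, float]):
        if node.is_leaf():
            return {node.name: node.branch_length or 0.0}
        below: dict[str, float] = {}
        for child in node.children:
            sub = walk(child, depths)
            for la, da in sub.items():
                for lb, db in below.items():
                    dists[frozenset((la, lb))] = da + db
            below.update(sub)
        bl = node.branch_length or 0.0
        return {leaf: d + bl for leaf, d in below.items()}

    walk(tree.root, {})
    return dists
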