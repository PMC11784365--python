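"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the local-alignment
oracle is a hand-written Smith-Waterman dynamic program (vectorised over
antidiagonals for speed, with full traceback), and the clustering oracle
precomputes the complete all-pairs similarity matrix before applying the
greedy rule.
"""

from __future__ import annotations

import numpy as np

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def sw_align(seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = -1.0,
             gap: float = -2.0):
    """Smith-Waterman local alignment with linear gaps.

    Returns ``(identity, coverage_short, score)``: identity = matches /
    alignment columns of one best local alignment, coverage_short = aligned
    span on the shorter sequence / its length, score = the (unique) optimal
    local alignment score.  Where several co-optimal alignments exist the
    traceback prefers diagonal, then up, then left moves; identity and
    coverage are therefore tied to that alignment choice, the score is not.
    """
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return 0.0, 0.0, 0.0
    H = np.zeros((m + 1, n + 1))
    sub = np.where(a[:, None] == b[None, :], match, mismatch)
    # antidiagonal sweep: cells (i, j) with i + j = d
    for d in range(2, m + n + 1):
        i_lo = max(1, d - n)
        i_hi = min(m, d - 1)
        if i_lo > i_hi:
            continue
        i = np.arange(i_lo, i_hi + 1)
        j = d - i
        diag = H[i - 1, j - 1] + sub[i - 1, j - 1]
        up = H[i - 1, j] + gap
        left = H[i, j - 1] + gap
        H[i, j] = np.maximum(0.0, np.maximum(diag, np.maximum(up, left)))
    best = H.max()
    if best <= 0:
        return 0.0, 0.0, 0.0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    end_i, end_j = i, j
    matches = columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = sub[i - 1, j - 1]
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += int(a[i - 1] == b[j - 1])
            columns += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    span_a, span_b = end_i - i, end_j - j
    short_len = min(m, n)
    span_short = span_a if m <= n else span_b
    return matches / columns, span_short / short_len, float(best)


def greedy_cluster_oracle(genes, identity_threshold: float = 0.95,
                          coverage_short: float = 0.9):
    """All-pairs-then-greedy clustering oracle.

    Computes the full pairwise (identity, coverage) matrix with
    :func:`sw_align` up front, then applies the greedy rule: genes sorted by
    length descending (gene_id ties), each joins the first cluster whose
    representative it matches, else founds one.  Returns a list of
    (representative_id, [member_ids]) tuples.
    """
    order = sorted(genes, key=lambda g: (-g.length, g.gene_id))
    pair = {}
    for x in range(len(order)):
        for y in range(x + 1, len(order)):
            pair[(order[x].gene_id, order[y].gene_id)] = sw_align(
                order[x].sequence, order[y].sequence
            )[:2]
    clusters = []
    for g in order:
        placed = False
        for rep, members in clusters:
            ident, cov = pair[(rep.gene_id, g.gene_id)]
            if ident >= identity_threshold and cov >= coverage_short:
                members.append(g.gene_id)
                placed = True
                break
        if not placed:
            clusters.append((g, [g.gene_id]))
    return [(rep.gene_id, members) for rep, members in clusters]


def spearman_oracle(x, y):
    """Rank-then-Pearson by explicit mid-ranking (no scipy ranking)."""
    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
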