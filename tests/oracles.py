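"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: full-matrix local
Smith-Waterman (Gotoh) for the seed-and-extend engine, exhaustive loss-subset
enumeration for Dollo parsimony, and a per-base interval classifier.
"""
from __future__ import annotations

import itertools

import numpy as np

NEG = -(10**9)


def sw_local_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2) -> int:
    """Optimal local alignment score, affine gaps (gap of k costs open + k*extend).

    Full-matrix DP, row-vectorized; no seeding, no pruning.
    """
    n, m = len(a), len(b)
    ac = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bc = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    go, ge = gap_open, gap_extend
    H_prev = np.zeros(m + 1, dtype=np.int64)
    F_prev = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    j_arr = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(bc == ac[i - 1], match, mismatch)
        F = np.maximum(H_prev + go + ge, F_prev + ge)
        H0 = np.zeros(m + 1, dtype=np.int64)
        H0[1:] = np.maximum(H_prev[:-1] + sub, 0)
        H0 = np.maximum(H0, F)
        H0[0] = 0
        # E by prefix cummax (two-pass affine trick)
        C = H0 - ge * j_arr
        E = np.full(m + 1, NEG, dtype=np.int64)
        E[1:] = go + ge * j_arr[1:] + np.maximum.accumulate(C)[:-1]
        H = np.maximum(H0, E)
        best = max(best, int(H.max()))
        H_prev, F_prev = H, F
    return best


def sw_local_align(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """(score, longest exact-match run in one optimal local alignment).

    Full-matrix Gotoh with traceback; used to verify both the optimum and the
    precondition that the optimal alignment contains a shared exact w-mer.
    """
    n, m = len(a), len(b)
    au, bu = a.upper(), b.upper()
    ac = np.frombuffer(au.encode(), dtype=np.uint8)
    bc = np.frombuffer(bu.encode(), dtype=np.uint8)
    go, ge = gap_open, gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    j_arr = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(bc == ac[i - 1], match, mismatch)
        F[i] = np.maximum(H[i - 1] + go + ge, F[i - 1] + ge)
        H0 = np.zeros(m + 1, dtype=np.int64)
        H0[1:] = np.maximum(H[i - 1, :-1] + sub, 0)
        H0 = np.maximum(H0, F[i])
        H0[0] = 0
        C = H0 - ge * j_arr
        E[i, 1:] = go + ge * j_arr[1:] + np.maximum.accumulate(C)[:-1]
        H[i] = np.maximum(H0, E[i])
    best = int(H.max())
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    run = longest = 0
    state = "H"
    while H[i, j] != 0 or state != "H":
        if state == "H":
            if E[i, j] == H[i, j]:
                state = "E"
                continue
            if F[i, j] == H[i, j]:
                state = "F"
                continue
            if au[i - 1] == bu[j - 1]:
                run += 1
                longest = max(longest, run)
            else:
                run = 0
            i, j = i - 1, j - 1
        elif state == "E":
            run = 0
            if E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            run = 0
            if F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    return best, longest


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

def rooted_trees(leaves: list[str]):
    """All rooted binary trees (nested tuples) on the given labeled leaves."""
    if not leaves:
        return
    if len(leaves) == 1:
        yield leaves[0]
        return
    for t in rooted_trees(leaves[:-1]):
        yield from _insert_everywhere(t, leaves[-1])


def _insert_everywhere(t, leaf):
    yield (t, leaf)
    if isinstance(t, tuple):
        left, right = t
        for sub in _insert_everywhere(left, leaf):
            yield (sub, right)
        for sub in _insert_everywhere(right, leaf):
            yield (left, sub)


def tuple_to_newick(t) -> str:
    def rec(x):
        if isinstance(x, tuple):
            return "(" + ",".join(rec(c) for c in x) + "):1"
        return f"{x}:1"

    inner = rec(t)
    return inner.rsplit(":", 1)[0] + ";"


def _paths_and_nodes(t, leaves):
    """Per-leaf root-path bitmasks over preorder node indices (root included)."""
    masks = {leaf: 0 for leaf in leaves}
    counter = itertools.count()

    def walk(node, path_bits):
        idx = next(counter)
        bits = path_bits | (1 << idx)
        if isinstance(node, tuple):
            for child in node:
                walk(child, bits)
        else:
            masks[node] = bits

    walk(t, 0)
    return masks, next(counter)


def dollo_min_losses(t, leaves: list[str]) -> dict[int, int]:
    """pattern_id -> minimum number of losses, by exhaustive subset search.

    Nodes (including the root, whose stem is the branch into the whole clade)
    are enumerated; a loss subset explains a pattern iff every absent leaf has
    >= 1 loss on its root path and every present leaf has none.  pattern_id
    bit i set = leaf i absent.
    """
    masks, n_nodes = _paths_and_nodes(t, leaves)
    n_leaves = len(leaves)
    subsets = np.arange(1 << n_nodes, dtype=np.int64)
    pattern = np.zeros(len(subsets), dtype=np.int64)
    for i, leaf in enumerate(leaves):
        absent = (subsets & masks[leaf]) != 0
        pattern |= absent.astype(np.int64) << i
    losses = np.zeros(len(subsets), dtype=np.int64)
    for bit in range(n_nodes):
        losses += (subsets >> bit) & 1
    out = np.full(1 << n_leaves, 1 << 30, dtype=np.int64)
    np.minimum.at(out, pattern, losses)
    return {int(p): int(v) for p, v in enumerate(out)}


def dollo_min_loss_branches(t, leaves: list[str]) -> tuple[dict[int, int], np.ndarray]:
    """As dollo_min_losses, plus per-branch loss totals over all patterns.

    Dollo's minimum placement (losses on the stems of maximal absent clades)
    is unique, so per pattern the first minimum-popcount explaining subset is
    the placement; the second return value sums its bits over every pattern,
    indexed by preorder node number.
    """
    masks, n_nodes = _paths_and_nodes(t, leaves)
    n_leaves = len(leaves)
    subsets = np.arange(1 << n_nodes, dtype=np.int64)
    pattern = np.zeros(len(subsets), dtype=np.int64)
    for i, leaf in enumerate(leaves):
        absent = (subsets & masks[leaf]) != 0
        pattern |= absent.astype(np.int64) << i
    losses = np.zeros(len(subsets), dtype=np.int64)
    for bit in range(n_nodes):
        losses += (subsets >> bit) & 1
    order = np.argsort(losses, kind="stable")
    _, first = np.unique(pattern[order], return_index=True)
    chosen = subsets[order][first]  # unique minimal subset per pattern id
    per_pattern = {int(p): int(losses[order][i]) for p, i in zip(np.unique(pattern[order]), first)}
    branch_totals = np.zeros(n_nodes, dtype=np.int64)
    for s in chosen:
        for bit in range(n_nodes):
            if (s >> bit) & 1:
                branch_totals[bit] += 1
    return per_pattern, branch_totals


def classify_per_base(start: int, end: int, features) -> str:
    """Per-base brute-force location classifier over a FeatureTable.

    Mirrors the precedence UTR > intron > intergenic with base-resolution
    bookkeeping: any base in a UTR feature -> UTR (larger overlap side wins,
    ties 5'); else contained in a gene span with no exon base -> intron;
    else intergenic.
    """
    from linecns.genome_io import GenomicInterval

    utr5 = utr3 = 0
    any_exon = False
    for pos in range(start, end):
        iv = GenomicInterval("chr1", pos, pos + 1)
        types = {f.type for f in features.overlapping(iv)}
        if "five_prime_UTR" in types:
            utr5 += 1
        if "three_prime_UTR" in types:
            utr3 += 1
        if "exon" in types:
            any_exon = True
    if utr5 or utr3:
        return "5'-UTR" if utr5 >= utr3 else "3'-UTR"
    whole = GenomicInterval("chr1", start, end)
    genes = features.overlapping(whole, ("gene",))
    inside = any(g.interval.start <= start and end <= g.interval.end for g in genes)
    if inside and not any_exon:
        return "intron"
    return "intergenic"
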