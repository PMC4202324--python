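"""Phylogenetic reconstruction from concatenated CNS alignments.

Per-element multiple alignments are built by deterministic center-star
alignment, concatenated, converted to Kimura two-parameter (K2P) distances
with pairwise deletion of gapped columns, and fed to neighbor-joining with
column-bootstrap support.  K2P separates the transition proportion P from the
transversion proportion Q:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from skbio import TreeNode

from .homology_search import ScoringScheme


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the K2P-correctable range."""


@dataclass
class MultipleAlignment:
    """Species -> gapped sequence, all rows the same length."""

    rows: dict[str, str]
    source_cns_ids: list[str] = field(default_factory=list)
    low_confidence: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.rows.items():
                fh.write(f">{name}\n{seq}\n")


def _pairwise_global(a: str, b: str, scheme: ScoringScheme) -> tuple[str, str]:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=scheme.match,
        mismatch_score=scheme.mismatch,
        open_gap_score=scheme.gap_open + scheme.gap_extend,
        extend_gap_score=scheme.gap_extend,
    )
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def _identity(a: str, b: str) -> float:
    cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not cols:
        return 0.0
    return sum(1 for x, y in cols if x == y) / len(cols)


def align_cns(
    sequences: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    cns_id: str | None = None,
) -> MultipleAlignment:
    """Deterministic center-star multiple alignment.

    The center is the sequence maximizing mean pairwise identity (ties to the
    first species in input order); all others are merged against it under
    "once a gap, always a gap".  Alignments with all-pairs identity below 40%
    are flagged low-confidence but still returned.
    """
    scheme = scheme or ScoringScheme()
    names = list(sequences)
    if len(names) < 2:
        raise ValueError("need >= 2 sequences")
    for n in names:
        if len(sequences[n]) < 10:
            raise ValueError(f"sequence {n!r} shorter than 10 bp")

    pair_aln: dict[tuple[str, str], tuple[str, str]] = {}
    ident: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(names, 2):
        ga, gb = _pairwise_global(sequences[a], sequences[b], scheme)
        pair_aln[(a, b)] = (ga, gb)
        ident[(a, b)] = ident[(b, a)] = _identity(ga, gb)
    mean_ident = {
        n: float(np.mean([ident[(n, m)] for m in names if m != n])) for n in names
    }
    center = max(names, key=lambda n: (mean_ident[n], -names.index(n)))
    low_confidence = max(ident[k] for k in ident) < 0.40 if ident else False

    center_seq = sequences[center]
    others = [n for n in names if n != center]
    # per pair: number of inserted columns before each center position (and after last)
    inserts = {n: np.zeros(len(center_seq) + 1, dtype=int) for n in others}
    paths = {}
    for n in others:
        key = (center, n) if (center, n) in pair_aln else (n, center)
        gc, gn = pair_aln[key] if key[0] == center else pair_aln[key][::-1]
        pos = 0
        ins = inserts[n]
        cols = []
        for cc, nc in zip(gc, gn):
            if cc == "-":
                ins[pos] += 1
            else:
                pos += 1
            cols.append((cc, nc))
        paths[n] = cols
    master = np.zeros(len(center_seq) + 1, dtype=int)
    for n in others:
        master = np.maximum(master, inserts[n])

    def render(cols, own_ins) -> str:
        out = []
        pos = 0
        pending: list[str] = []
        i = 0
        # walk the pairwise columns; at each center residue flush pending
        # insertions padded to the master count
        for cc, nc in cols:
            if cc == "-":
                pending.append(nc)
            else:
                out.append(pending_str(pending, master[pos]))
                pending = []
                out.append(nc)
                pos += 1
        out.append(pending_str(pending, master[pos]))
        return "".join(out)

    def pending_str(pending: list[str], width: int) -> str:
        return "".join(pending) + "-" * (width - len(pending))

    rows = {}
    center_cols = []
    pos = 0
    for pos in range(len(center_seq) + 1):
        center_cols.append("-" * master[pos])
        if pos < len(center_seq):
            center_cols.append(center_seq[pos])
    rows[center] = "".join(center_cols)
    for n in others:
        rows[n] = render(paths[n], inserts[n])
    ordered = {n: rows[n] for n in names}
    return MultipleAlignment(
        ordered,
        source_cns_ids=[cns_id] if cns_id else [],
        low_confidence=low_confidence,
    )


def concatenate(alignments: Sequence[MultipleAlignment]) -> MultipleAlignment:
    """Concatenate alignments over the same species set."""
    species = list(alignments[0].rows)
    for a in alignments:
        if list(a.rows) != species:
            raise ValueError("alignments cover different species sets")
    rows = {s: "".join(a.rows[s] for a in alignments) for s in species}
    ids = [i for a in alignments for i in a.source_cns_ids]
    return MultipleAlignment(rows, source_cns_ids=ids)


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_distance(row_i: str, row_j: str) -> tuple[float, float, float]:
    """(P, Q, d): transition/transversion proportions over ungapped shared
    columns and the K2P distance.  Raises SaturationError when the log
    arguments are non-positive."""
    pairs = [
        (a.upper(), b.upper())
        for a, b in zip(row_i, row_j)
        if a != "-" and b != "-" and a.upper() in "ACGT" and b.upper() in "ACGT"
    ]
    if not pairs:
        raise ValueError("no ungapped shared columns")
    n = len(pairs)
    ts = sum(1 for p in pairs if p in _TRANSITIONS)
    tv = sum(1 for a, b in pairs if a != b and (a, b) not in _TRANSITIONS)
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P saturation: P={P:.3f}, Q={Q:.3f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return P, Q, d


@dataclass
class DistanceMatrix:
    species: list[str]
    d: np.ndarray
    P: np.ndarray | None = None
    Q: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.species)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")


def _codes_matrix(alignment: MultipleAlignment) -> tuple[list[str], np.ndarray]:
    trans = {"A": 0, "C": 1, "G": 2, "T": 3}
    species = list(alignment.rows)
    mat = np.array(
        [[trans.get(c.upper(), 4) for c in alignment.rows[s]] for s in species],
        dtype=np.uint8,
    )
    return species, mat


def _k2p_from_codes(mat: np.ndarray, saturation_cap: float | None = None) -> np.ndarray:
    """Pairwise K2P over a codes matrix (4 = gap/ambiguous, pairwise deletion)."""
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            ok = (a < 4) & (b < 4)
            tot = int(ok.sum())
            if tot == 0:
                raise ValueError("no ungapped shared columns")
            diff = ok & (a != b)
            ts = int((diff & ((a ^ b) == 2)).sum())  # A<->G, C<->T differ in bit 1
            tv = int(diff.sum()) - ts
            P, Q = ts / tot, tv / tot
            w1, w2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                if saturation_cap is None:
                    raise SaturationError(f"K2P saturation between rows {i} and {j}")
                dij = saturation_cap
            else:
                dij = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            d[i, j] = d[j, i] = dij
    return d


def distance_matrix(
    alignment: MultipleAlignment, saturation_cap: float | None = None
) -> DistanceMatrix:
    species, mat = _codes_matrix(alignment)
    return DistanceMatrix(species, _k2p_from_codes(mat, saturation_cap))


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining; ties in the Q-criterion break to the
    lowest taxon-index pair; negative branch lengths clamp to 0."""
    n = len(dm.species)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.species]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                key = (q[ai, aj], ai, aj)
                if best is None or key < best:
                    best = key
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = float(li), float(lj)
        parent.extend([ni, nj_])
        # distances to the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        new_idx = d.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [new_idx]
    # join the last three with the three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = float(max(length, 0.0))
        root.append(nodes[idx])
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits as frozensets of the smaller (or lexicographically
    first, on ties) side's taxa."""
    taxa = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = min((side, other), key=lambda s: (len(s), sorted(s)))
        splits.add(pick)
    return splits


def bootstrap_support(
    alignment: MultipleAlignment,
    B: int = 1000,
    seed: int = 0,
    saturation_cap: float = 10.0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Column bootstrap of the NJ tree.

    Returns the full-data NJ tree with internal nodes labelled by the
    percentage of replicate trees containing the corresponding split, plus
    the split -> support mapping.  Saturated replicate distances are capped
    at ``saturation_cap`` rather than aborting a replicate.
    """
    species, mat = _codes_matrix(alignment)
    if len(species) < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    ncol = mat.shape[1]
    if ncol < 4:
        raise ValueError("alignment shorter than 4 columns")
    full = nj_tree(DistanceMatrix(species, _k2p_from_codes(mat, saturation_cap)))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(full)}
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        rep = mat[:, cols]
        rep_tree = nj_tree(DistanceMatrix(species, _k2p_from_codes(rep, saturation_cap)))
        rep_splits = tree_splits(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / B for s, c in counts.items()}
    labelled = full.copy()
    taxa = frozenset(species)
    for node in labelled.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = min((side, other), key=lambda s: (len(s), sorted(s)))
        if pick in support:
            node.name = f"{support[pick]:g}"
    return labelled, support
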