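"""Self-contained nucleotide seed-and-extend local aligner.

The engine mirrors the behaviour of an ungapped-statistics blastn run: exact
unmasked w-mer seeds, gapped X-drop extension with affine gap costs, and
Karlin-Altschul e-values E = K*m*n*exp(-lambda*S).  Lambda and K are solved
from the scoring scheme and background base frequencies (ungapped theory; the
same constants are reused for gapped scores, a stated approximation).  Soft
masking semantics: seeds never start in masked (lowercase/N) bases, extension
may cross them, scoring every masked column as a mismatch.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .genome_io import GenomicInterval, SpeciesGenome, reverse_complement

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_MASKED = np.zeros(256, dtype=bool)
for b in "acgtnN":
    _MASKED[ord(b)] = True

_NEG = -(10**9)


def encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes 0..4, masked flags) for a nucleotide string."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw], _MASKED[raw]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus the Karlin-Altschul constants.

    A gap of length k costs gap_open + k * gap_extend (both <= 0).
    ``lam`` (lambda) and ``karlin_k`` (K) are solved by
    :func:`solve_karlin_params`; ``base_freqs`` are the background frequencies
    of A, C, G, T used in that solution.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float | None = None
    karlin_k: float | None = None
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ScoringError("match must be > 0 and mismatch < 0")
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise ScoringError("gap_open must be <= 0 and gap_extend < 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ScoringError("base_freqs must sum to 1")

    def calibrated(self) -> "ScoringScheme":
        if self.lam is not None and self.karlin_k is not None:
            return self
        lam, k = solve_karlin_params(self.match, self.mismatch, self.base_freqs)
        return replace(self, lam=lam, karlin_k=k)


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 11
    x_drop: int = 30
    evalue_cutoff: float = 0.001
    both_strands: bool = True
    max_hits_per_query: int | None = None
    min_length: int = 15
    max_extension: int = 3000

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")


@dataclass(frozen=True)
class LocalAlignment:
    """One pairwise local alignment; strand is subject relative to query.

    When strand is '-', the aligned strings are given with the query reverse
    complemented (the orientation in which the two sequences align).
    """

    query_interval: GenomicInterval
    subject_interval: GenomicInterval
    strand: str
    score: int
    evalue: float
    identity_pct: float
    aligned_query: str
    aligned_subject: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def mismatches(self) -> int:
        return sum(
            1 for a, b in zip(self.aligned_query, self.aligned_subject)
            if a != "-" and b != "-" and a.upper() != b.upper()
        )

    @property
    def gap_opens(self) -> int:
        opens = 0
        prev = None
        for a, b in zip(self.aligned_query, self.aligned_subject):
            cur = "q" if a == "-" else ("s" if b == "-" else None)
            if cur and cur != prev:
                opens += 1
            prev = cur
        return opens


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def _score_distribution(
    match: int, mismatch: int, base_freqs: Sequence[float]
) -> dict[int, float]:
    p = np.asarray(base_freqs, dtype=float)
    p_match = float(np.sum(p * p))
    return {match: p_match, mismatch: 1.0 - p_match}


def solve_karlin_params(
    match: int,
    mismatch: int,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Solve the ungapped Karlin-Altschul parameters (lambda, K).

    Lambda is the unique positive root of sum_ij p_i p_j exp(lambda*s(i,j)) = 1.
    K follows the lattice-case series: with
    sigma = sum_{j>=1} (1/j) * ( P(S_j >= 0) + E[exp(lambda*S_j); S_j < 0] ),
    K = delta * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*delta))), where
    H = lambda * E[S_1 * exp(lambda*S_1)] and delta is the score-lattice span.
    For the blastn-like +1/-2 uniform scheme this reproduces the published
    ungapped constants lambda = 1.33, K = 0.621, H = 1.12.
    """
    dist = _score_distribution(match, mismatch, base_freqs)
    scores = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[s] for s in scores])
    expected = float(np.sum(scores * probs))
    if expected >= 0:
        raise ScoringError("invalid scoring scheme: expected per-position score >= 0")
    if scores.max() <= 0:
        raise ScoringError("invalid scoring scheme: no positive score attainable")

    def f(lam: float) -> float:
        return float(np.sum(probs * np.exp(lam * scores))) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover
            raise ScoringError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=tol))

    delta = int(np.gcd.reduce(np.abs(scores)))
    h = lam * float(np.sum(scores * probs * np.exp(lam * scores)))

    # sigma series over the j-fold convolutions of the step distribution
    lo_s = int(scores.min())
    step = np.zeros(int(scores.max()) - lo_s + 1)
    for s, pr in dist.items():
        step[s - lo_s] = pr
    cur = step.copy()
    cur_lo = lo_s
    sigma = 0.0
    for j in range(1, 2000):
        vals = np.arange(cur_lo, cur_lo + len(cur))
        neg = vals < 0
        term = float(np.sum(cur[~neg])) + float(np.sum(cur[neg] * np.exp(lam * vals[neg])))
        sigma += term / j
        if term < 1e-8:
            break
        cur = np.convolve(cur, step)
        cur_lo += lo_s
    k = delta * lam * math.exp(-2.0 * sigma) / (h * (1.0 - math.exp(-lam * delta)))
    return lam, k


def evalue(score: float, m: int, n: int, lam: float, karlin_k: float) -> float:
    """Expected number of chance alignments scoring >= score: K*m*n*exp(-lambda*S)."""
    return karlin_k * m * n * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# X-drop extension (anchored, affine gaps, adaptive window)
# ---------------------------------------------------------------------------

def _extend_dir(
    qc: np.ndarray, qm: np.ndarray, sc: np.ndarray, sm: np.ndarray,
    qpos: int, spos: int, direction: int,
    scheme: ScoringScheme, x_drop: int, max_ext: int,
) -> tuple[int, int, int]:
    """Best anchored extension from (qpos, spos) moving by ``direction``.

    Returns (score, query bases consumed, subject bases consumed) of the best
    alignment of a query run starting at qpos against a subject run starting
    at spos.  Cells whose score falls more than x_drop below the running best
    are abandoned (window trimmed to the surviving range).
    """
    if direction > 0:
        qv = qc[qpos:] if 0 <= qpos <= len(qc) else qc[:0]
        qmv = qm[qpos:] if 0 <= qpos <= len(qm) else qm[:0]
        sv = sc[spos:] if 0 <= spos <= len(sc) else sc[:0]
        smv = sm[spos:] if 0 <= spos <= len(sm) else sm[:0]
    else:
        qv = qc[qpos::-1] if qpos >= 0 else qc[:0]
        qmv = qm[qpos::-1] if qpos >= 0 else qm[:0]
        sv = sc[spos::-1] if spos >= 0 else sc[:0]
        smv = sm[spos::-1] if spos >= 0 else sm[:0]

    nq = min(len(qv), max_ext)
    ns = min(len(sv), max_ext)
    if nq == 0 or ns == 0:
        return 0, 0, 0

    match, mismatch = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend
    best, best_i, best_j = 0, 0, 0

    jlo, jhi = 0, 0  # inclusive subject-consumed window of previous row
    H_prev = np.array([0], dtype=np.int64)
    F_prev = np.array([_NEG], dtype=np.int64)
    for i in range(1, nq + 1):
        new_lo, new_hi = jlo, min(jhi + 1, ns)
        width = new_hi - new_lo + 1
        j_arr = np.arange(new_lo, new_hi + 1)

        # align previous-row arrays to the new window
        pad_hi = new_hi - jhi  # 0 or 1
        Hp = np.full(width, _NEG, dtype=np.int64)
        Fp = np.full(width, _NEG, dtype=np.int64)
        Hp[: width - pad_hi] = H_prev[new_lo - jlo :]
        Fp[: width - pad_hi] = F_prev[new_lo - jlo :]
        Hp_diag = np.full(width, _NEG, dtype=np.int64)  # H_prev[j-1]
        src_lo = max(new_lo - 1, jlo)
        Hp_diag[src_lo - new_lo + 1 :] = H_prev[src_lo - jlo : new_hi - jlo]

        F_row = np.maximum(Hp + go + ge, Fp + ge)

        s_idx = j_arr - 1
        valid_s = s_idx >= 0
        s_take = np.clip(s_idx, 0, ns - 1)
        q_code, q_mask = int(qv[i - 1]), bool(qmv[i - 1])
        if q_mask or q_code > 3:
            sub = np.full(width, mismatch, dtype=np.int64)
        else:
            eq = (sv[s_take] == q_code) & ~smv[s_take]
            sub = np.where(eq, match, mismatch)
        diag = np.where(valid_s, Hp_diag + sub, _NEG)

        H0 = np.maximum(diag, F_row)
        # E by prefix cummax: E[j] = go + ge*j + max_{k<j}(H0[k] - ge*k)
        C = H0 - ge * j_arr
        cm = np.maximum.accumulate(C)
        E_row = np.full(width, _NEG, dtype=np.int64)
        if width > 1:
            E_row[1:] = go + ge * j_arr[1:] + cm[:-1]
        H_row = np.maximum(H0, E_row)

        row_best = int(H_row.max())
        if row_best > best:
            best = row_best
            best_i = i
            best_j = int(j_arr[int(np.argmax(H_row))])

        alive = np.maximum(H_row, F_row) >= best - x_drop
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        jlo = int(j_arr[idx[0]])
        jhi = int(j_arr[idx[-1]])
        H_prev = H_row[idx[0] : idx[-1] + 1]
        F_prev = F_row[idx[0] : idx[-1] + 1]
        if jlo == ns and jhi == ns and i >= nq:
            break
    return best, best_i, best_j


# ---------------------------------------------------------------------------
# Banded global alignment with traceback (for the final gapped strings)
# ---------------------------------------------------------------------------

def _banded_global(qs: str, ss: str, scheme: ScoringScheme, extra_band: int = 34):
    """Global affine-gap alignment of two segments; returns gapped strings and score.

    Band-indexed Gotoh DP: cell (i, j) lives at t = j - i + B where
    B = |len(qs) - len(ss)| + extra_band.
    """
    n, m = len(qs), len(ss)
    if n == 0 or m == 0:
        return "-" * m + qs, ss + "-" * n, 0  # degenerate; not used on real hits
    B = abs(n - m) + extra_band
    W = 2 * B + 1
    go, ge = scheme.gap_open, scheme.gap_extend
    match, mismatch = scheme.match, scheme.mismatch
    qc, qm_ = encode(qs)
    sc, sm_ = encode(ss)
    pad_len = max(n, m) + 2 * B + 2
    s_pad_code = np.full(pad_len, 255, dtype=np.int16)
    s_pad_code[B + 1 : B + 1 + m] = sc
    s_pad_mask = np.ones(pad_len, dtype=bool)
    s_pad_mask[B + 1 : B + 1 + m] = sm_

    H = np.full((n + 1, W), _NEG, dtype=np.int64)
    E = np.full((n + 1, W), _NEG, dtype=np.int64)
    F = np.full((n + 1, W), _NEG, dtype=np.int64)
    t_arr = np.arange(W)
    H[0, B] = 0
    top = np.arange(1, min(m, B) + 1)
    E[0, B + top] = go + ge * top
    H[0, B + top] = E[0, B + top]

    for i in range(1, n + 1):
        j_arr = i - B + t_arr
        valid = (j_arr >= 0) & (j_arr <= m)
        Hp = H[i - 1]
        Fp = F[i - 1]
        Hp_up = np.concatenate((Hp[1:], [_NEG]))
        Fp_up = np.concatenate((Fp[1:], [_NEG]))
        F_row = np.maximum(Hp_up + go + ge, Fp_up + ge)

        sw = s_pad_code[i : i + W]
        swm = s_pad_mask[i : i + W]
        q_code, q_mask = int(qc[i - 1]), bool(qm_[i - 1])
        if q_mask or q_code > 3:
            sub = np.full(W, mismatch, dtype=np.int64)
        else:
            sub = np.where((sw == q_code) & ~swm, match, mismatch)
        H0 = np.maximum(Hp + sub, F_row)
        C = H0 - ge * t_arr
        cm = np.maximum.accumulate(C)
        E_row = np.full(W, _NEG, dtype=np.int64)
        E_row[1:] = go + ge * t_arr[1:] + cm[:-1]
        H_row = np.maximum(H0, E_row)
        H_row[~valid] = _NEG
        E_row[~valid] = _NEG
        F_row[~valid] = _NEG
        H[i] = H_row
        E[i] = E_row
        F[i] = F_row

    t_end = m - n + B
    score = int(H[n, t_end])
    # traceback
    aq: list[str] = []
    as_: list[str] = []
    i, t = n, t_end
    state = "H"
    while True:
        j = i - B + t
        if i == 0 and j == 0:
            break
        if state == "H":
            if j > 0 and H[i, t] == E[i, t]:
                state = "E"
                continue
            if i > 0 and H[i, t] == F[i, t]:
                state = "F"
                continue
            aq.append(qs[i - 1])
            as_.append(ss[j - 1])
            i -= 1  # diagonal: same t
        elif state == "E":
            aq.append("-")
            as_.append(ss[j - 1])
            if j > 1 and E[i, t] == E[i, t - 1] + ge:
                t -= 1
            else:
                t -= 1
                state = "H"
        else:  # F
            aq.append(qs[i - 1])
            as_.append("-")
            if i > 1 and F[i, t] == F[i - 1, t + 1] + ge:
                i -= 1
                t += 1
            else:
                i -= 1
                t += 1
                state = "H"
    return "".join(reversed(aq)), "".join(reversed(as_)), score


def _identity_pct(aq: str, as_: str) -> float:
    matches = sum(
        1 for a, b in zip(aq, as_)
        if a != "-" and b != "-" and a.upper() == b.upper() and a.upper() in "ACGT"
    )
    return 100.0 * matches / len(aq)


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_positions(codes: np.ndarray, masked: np.ndarray, w: int) -> dict[int, list[int]]:
    """Start positions of every unmasked exact w-mer, keyed by 2-bit packed int."""
    index: dict[int, list[int]] = {}
    n = len(codes)
    if n < w:
        return index
    kmer = 0
    run = 0
    mask_bits = (1 << (2 * w)) - 1
    cl = codes.tolist()
    ml = masked.tolist()
    for i in range(n):
        c = cl[i]
        if c > 3 or ml[i]:
            run = 0
            kmer = 0
            continue
        kmer = ((kmer << 2) | c) & mask_bits
        run += 1
        if run >= w:
            index.setdefault(kmer, []).append(i - w + 1)
    return index


def _iter_query_kmers(codes: np.ndarray, masked: np.ndarray, w: int):
    n = len(codes)
    kmer = 0
    run = 0
    mask_bits = (1 << (2 * w)) - 1
    cl = codes.tolist()
    ml = masked.tolist()
    for i in range(n):
        c = cl[i]
        if c > 3 or ml[i]:
            run = 0
            kmer = 0
            continue
        kmer = ((kmer << 2) | c) & mask_bits
        run += 1
        if run >= w:
            yield i - w + 1, kmer


class _AcceptedIndex:
    """Containment index: skip seeds lying inside an already-extended alignment."""

    def __init__(self) -> None:
        self._by_diag: dict[int, list[tuple[int, int, int, int]]] = {}

    def add(self, qs: int, qe: int, ss: int, se: int) -> None:
        rec = (qs, qe, ss, se)
        for d in range(ss - qe, se - qs + 1):
            self._by_diag.setdefault(d, []).append(rec)

    def contains(self, qpos: int, spos: int, w: int) -> bool:
        for qs, qe, ss, se in self._by_diag.get(spos - qpos, ()):
            if qs <= qpos and qpos + w <= qe and ss <= spos and spos + w <= se:
                return True
        return False


def seed_extend_search(
    query: SpeciesGenome | Mapping[str, str],
    subject: SpeciesGenome,
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
) -> list[LocalAlignment]:
    """Find all local alignments with E <= cutoff seeded by a shared exact
    unmasked w-mer (on either strand when ``params.both_strands``).

    ``query`` may be a SpeciesGenome or a plain mapping of sequence id ->
    sequence (e.g. candidate CNS sequences).  In the e-value, m is the
    individual query length and n the total subject length.  Hits are sorted
    by ascending E, ties broken by higher score, then query (chromosome,
    start).
    """
    params = params or SearchParams()
    scheme = (scheme or ScoringScheme()).calibrated()
    w = params.word_size

    if isinstance(query, SpeciesGenome):
        queries = {c: query.chromosomes[c] for c in query.nuclear_ids}
    else:
        queries = dict(query)
    subject_chroms = {c: subject.chromosomes[c] for c in subject.nuclear_ids}
    n_total = sum(len(s) for s in subject_chroms.values())
    if not queries or n_total == 0:
        return []

    sub_idx = {}
    for cid, seq in subject_chroms.items():
        sc, sm = encode(seq)
        sub_idx[cid] = (sc, sm, _kmer_positions(sc, sm, w))

    hits: list[LocalAlignment] = []
    strands = ("+", "-") if params.both_strands else ("+",)
    for qid, qseq in queries.items():
        qlen = len(qseq)
        per_query: list[LocalAlignment] = []
        for strand in strands:
            oriented = qseq if strand == "+" else reverse_complement(qseq)
            qc, qm = encode(oriented)
            for scid, (sc, sm, index) in sub_idx.items():
                accepted = _AcceptedIndex()
                seen: set[tuple[int, int, int, int]] = set()
                for qpos, kmer in _iter_query_kmers(qc, qm, w):
                    positions = index.get(kmer)
                    if not positions:
                        continue
                    for spos in positions:
                        if accepted.contains(qpos, spos, w):
                            continue
                        r_score, ri, rj = _extend_dir(
                            qc, qm, sc, sm, qpos + w, spos + w, 1,
                            scheme, params.x_drop, params.max_extension,
                        )
                        l_score, li, lj = _extend_dir(
                            qc, qm, sc, sm, qpos - 1, spos - 1, -1,
                            scheme, params.x_drop, params.max_extension,
                        )
                        score = w * scheme.match + l_score + r_score
                        q0, q1 = qpos - li, qpos + w + ri
                        s0, s1 = spos - lj, spos + w + rj
                        accepted.add(q0, q1, s0, s1)
                        e = evalue(score, qlen, n_total, scheme.lam, scheme.karlin_k)
                        if e > params.evalue_cutoff or q1 - q0 < params.min_length:
                            continue
                        key = (q0, q1, s0, s1)
                        if key in seen:
                            continue
                        seen.add(key)
                        aq, as_, _ = _banded_global(
                            oriented[q0:q1], subject_chroms[scid][s0:s1], scheme
                        )
                        if strand == "+":
                            q_iv = GenomicInterval(qid, q0, q1, "+")
                        else:
                            q_iv = GenomicInterval(qid, qlen - q1, qlen - q0, "+")
                        per_query.append(
                            LocalAlignment(
                                query_interval=q_iv,
                                subject_interval=GenomicInterval(scid, s0, s1, "+"),
                                strand=strand,
                                score=score,
                                evalue=e,
                                identity_pct=_identity_pct(aq, as_),
                                aligned_query=aq,
                                aligned_subject=as_,
                            )
                        )
        uniq: dict[tuple, LocalAlignment] = {}
        for h in per_query:
            key = (h.query_interval, h.subject_interval, h.strand)
            if key not in uniq or h.score > uniq[key].score:
                uniq[key] = h
        per_query = sorted(
            uniq.values(),
            key=lambda h: (h.evalue, -h.score, h.query_interval.chrom, h.query_interval.start),
        )
        if params.max_hits_per_query is not None:
            per_query = per_query[: params.max_hits_per_query]
        hits.extend(per_query)
    hits.sort(key=lambda h: (h.evalue, -h.score, h.query_interval.chrom, h.query_interval.start))
    return hits


def write_hits_table(hits: Iterable[LocalAlignment], path) -> None:
    """Tabular output mirroring BLAST outfmt 6 (1-based inclusive) plus strand."""
    with open(path, "w") as fh:
        for h in hits:
            q, s = h.query_interval, h.subject_interval
            fh.write(
                "\t".join(
                    [
                        q.chrom, s.chrom, f"{h.identity_pct:.2f}", str(h.n_columns),
                        str(h.mismatches), str(h.gap_opens),
                        str(q.start + 1), str(q.end), str(s.start + 1), str(s.end),
                        f"{h.evalue:.3g}", str(h.score), h.strand,
                    ]
                )
                + "\n"
            )


def organellar_filter(
    genome: SpeciesGenome,
    organellar: SpeciesGenome | Mapping[str, str] | None = None,
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
) -> SpeciesGenome:
    """Hard-mask (to N) nuclear regions with a significant hit to organellar DNA.

    Organellar sequences come from ``organellar`` or, if omitted, from the
    genome's own ``organellar_ids``.  With no organellar input the genome is
    returned unchanged.
    """
    params = params or SearchParams()
    if organellar is None:
        organellar = {c: genome.chromosomes[c] for c in genome.organellar_ids}
    elif isinstance(organellar, SpeciesGenome):
        organellar = dict(organellar.chromosomes)
    else:
        organellar = dict(organellar)
    if not organellar:
        return genome

    nuclear = genome.drop_organellar()
    hits = seed_extend_search(organellar, nuclear, params, scheme)
    masked_chroms = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
                     for c, s in nuclear.chromosomes.items()}
    n_masked = 0
    for h in hits:
        s = h.subject_interval
        span = masked_chroms[s.chrom][s.start : s.end]
        n_masked += int(np.sum(span != ord("N")))
        span[:] = ord("N")
    logger.info("organellar filter masked %d bases in %s", n_masked, genome.species_id)
    return SpeciesGenome(
        genome.species_id,
        {c: arr.tobytes().decode() for c, arr in masked_chroms.items()},
    )
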