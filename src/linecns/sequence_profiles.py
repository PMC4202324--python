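"""Sequence-level characterization of CNS sets: A+T border profiles,
nucleosome-occupancy profiles with matched controls, methylation overlap, and
recombination-hotspot overlap.

The nucleosome model is pluggable: any callable mapping a nucleotide string to
per-base occupancy probabilities in [0, 1] may be supplied.  The built-in
stand-in (:func:`gc_logistic_model`) is a logistic function of windowed G+C
with a ~10.25-bp A/T-dinucleotide periodicity bonus — a deliberately simple
sequence-preference heuristic standing behind the same averaging/controls/test
logic used for any real model.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import FeatureTable, GenomicInterval, SpeciesGenome, overlaps
from .synthetic_data import sample_noncoding_intervals

logger = logging.getLogger(__name__)

_AT = frozenset("ATat")
_GC = frozenset("GCgc")


def at_fraction(seq: str) -> float:
    return sum(1 for b in seq if b in _AT) / len(seq)


def _windowed_at(seq: str, window: int, step: int) -> np.ndarray:
    isat = np.frombuffer(seq.encode(), dtype=np.uint8)
    isat = np.isin(isat, np.frombuffer(b"ATat", dtype=np.uint8)).astype(float)
    kernel = np.ones(window) / window
    full = np.convolve(isat, kernel, mode="valid")
    return full[::step]


@dataclass
class WindowProfile:
    """Composite moving-window A+T profile around a CNS set.

    ``positions`` are window-start offsets: negative values in the 5' flank
    (relative to CNS start), 0.. within the center span, and positive values
    offset from the CNS end in the 3' flank.  ``t``/``p`` compare flank vs
    center window values (Welch); ``t_cns``/``p_cns`` give the per-CNS-means
    variant.
    """

    positions: np.ndarray
    at: np.ndarray
    segment: np.ndarray  # 'L', 'C', 'R' per position
    n_cns: int
    n_excluded: int
    flank_mean: float
    center_mean: float
    t: float
    p: float
    t_cns: float
    p_cns: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "at_fraction": self.at, "segment": self.segment}
        )


def at_profile(
    cns_set: Sequence[GenomicInterval],
    genome: SpeciesGenome,
    features: FeatureTable,
    flank: int = 1000,
    center: int = 20,
    window: int = 10,
    step: int = 1,
) -> WindowProfile:
    """Moving-window A+T around CNSs: ``flank`` bp each side plus a ``center``
    bp span on the CNS midpoint, averaged over the set.

    CNSs whose flanks intersect coding sequence (or run past a chromosome
    end) are excluded, with the count logged.  The headline Welch t compares
    flank vs center window values of the averaged profile; the per-CNS-means
    variant is reported alongside (``t_cns``/``p_cns``).
    """
    left_profiles, center_profiles, right_profiles = [], [], []
    flank_means, center_means = [], []
    n_excluded = 0
    for iv in cns_set:
        mid = (iv.start + iv.end) // 2
        c0, c1 = mid - center // 2, mid + (center + 1) // 2
        lo, hi = iv.start - flank, iv.end + flank
        if lo < 0 or hi > genome.length(iv.chrom) or c0 < 0:
            n_excluded += 1
            continue
        span = GenomicInterval(iv.chrom, lo, hi)
        if features.overlapping(span, ("CDS",)):
            n_excluded += 1
            continue
        chrom_seq = genome.chromosomes[iv.chrom]
        left = chrom_seq[lo : iv.start]
        middle = chrom_seq[c0:c1]
        right = chrom_seq[iv.end : hi]
        left_profiles.append(_windowed_at(left, window, step))
        center_profiles.append(_windowed_at(middle, window, step))
        right_profiles.append(_windowed_at(right, window, step))
        flank_means.append(at_fraction(left + right))
        center_means.append(at_fraction(middle))
    n_cns = len(flank_means)
    if n_cns == 0:
        raise ValueError("no CNSs left after flank/coding exclusion")

    left_avg = np.mean(left_profiles, axis=0)
    center_avg = np.mean(center_profiles, axis=0)
    right_avg = np.mean(right_profiles, axis=0)
    at = np.concatenate([left_avg, center_avg, right_avg])
    positions = np.concatenate(
        [
            np.arange(-flank, -flank + len(left_avg) * step, step),
            np.arange(0, len(center_avg) * step, step),
            np.arange(1, 1 + len(right_avg) * step, step),
        ]
    )
    segment = np.array(
        ["L"] * len(left_avg) + ["C"] * len(center_avg) + ["R"] * len(right_avg)
    )

    flank_vals = np.concatenate([left_avg, right_avg])
    t, p = stats.ttest_ind(flank_vals, center_avg, equal_var=False)
    t_cns, p_cns = stats.ttest_ind(flank_means, center_means, equal_var=False)
    logger.info(
        "at_profile: %d CNSs used, %d excluded (coding flank or edge)", n_cns, n_excluded
    )
    return WindowProfile(
        positions=positions,
        at=at,
        segment=segment,
        n_cns=n_cns,
        n_excluded=n_excluded,
        flank_mean=float(np.mean(flank_means)),
        center_mean=float(np.mean(center_means)),
        t=float(t),
        p=float(p),
        t_cns=float(t_cns),
        p_cns=float(p_cns),
    )


# ---------------------------------------------------------------------------
# Nucleosome occupancy
# ---------------------------------------------------------------------------

def constant_model(p: float = 0.5) -> Callable[[str], np.ndarray]:
    def model(seq: str) -> np.ndarray:
        return np.full(len(seq), p)

    return model


def gc_logistic_model(
    window: int = 147,
    gc_weight: float = 8.0,
    period_weight: float = 1.5,
    gc_center: float = 0.5,
    period: float = 10.25,
) -> Callable[[str], np.ndarray]:
    """Stand-in sequence-preference model: logistic of windowed G+C content
    plus a phased A/T-dinucleotide (AA/TT/TA/AT) periodicity bonus at ~10.25
    bp, the period of DNA wrapped on the histone octamer."""

    def model(seq: str) -> np.ndarray:
        n = len(seq)
        raw = np.frombuffer(seq.encode(), dtype=np.uint8)
        gc = np.isin(raw, np.frombuffer(b"GCgc", dtype=np.uint8)).astype(float)
        at = np.isin(raw, np.frombuffer(b"ATat", dtype=np.uint8)).astype(float)
        ww = np.zeros(n)
        ww[:-1] = at[:-1] * at[1:]  # weak-weak dinucleotide starts
        kernel = np.ones(window) / window
        pad = window // 2
        gc_pad = np.pad(gc, pad, mode="edge")
        gc_win = np.convolve(gc_pad, kernel, mode="valid")[:n]
        phase = np.cos(2.0 * math.pi * np.arange(window) / period)
        phase -= phase.mean()
        ww_pad = np.pad(ww, pad, mode="edge")
        per = np.convolve(ww_pad, phase[::-1] / window, mode="valid")[:n]
        x = gc_weight * (gc_win - gc_center) + period_weight * per
        return 1.0 / (1.0 + np.exp(-x))

    return model


@dataclass
class OccupancyProfile:
    positions: np.ndarray
    cns: np.ndarray
    control_matched: np.ndarray
    control_unmatched: np.ndarray
    n_cns: int
    t: float
    p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "cns": self.cns,
                "control_matched": self.control_matched,
                "control_unmatched": self.control_unmatched,
            }
        )


def occupancy_profile(
    cns_set: Sequence[GenomicInterval],
    genome: SpeciesGenome,
    features: FeatureTable,
    model: Callable[[str], np.ndarray],
    span: int = 4000,
    at_tolerance: float = 0.01,
    center_window: int = 147,
    seed: int = 0,
    max_tries: int = 10_000,
) -> OccupancyProfile:
    """Mean per-position occupancy over ``span`` bases each side of the CNS
    centers, with two noncoding controls: one matched in length and A+T
    content (within ``at_tolerance``), one without composition preference.

    The Welch t compares per-element mean occupancy over the central
    ``center_window`` bases between the CNS set and the matched control.
    """
    if not cns_set:
        raise ValueError("empty CNS set")
    usable: list[GenomicInterval] = []
    extracts: list[str] = []
    for iv in cns_set:
        mid = (iv.start + iv.end) // 2
        lo, hi = mid - span, mid + span
        if lo < 0 or hi > genome.length(iv.chrom):
            continue
        usable.append(iv)
        extracts.append(genome.chromosomes[iv.chrom][lo:hi])
    if not usable:
        raise ValueError("no CNS has full flanking span inside its chromosome")

    def occupancy_tracks(seqs: list[str]) -> np.ndarray:
        tracks = []
        for s in seqs:
            occ = np.asarray(model(s), dtype=float)
            if len(occ) != len(s):
                raise ValueError("model output length != input length")
            if occ.min() < 0 or occ.max() > 1:
                raise ValueError("model output outside [0, 1]")
            tracks.append(occ)
        return np.vstack(tracks)

    lengths = [iv.length for iv in usable]
    rng = np.random.default_rng(seed)
    matched = sample_noncoding_intervals(
        genome, features, lengths,
        at_match=[at_fraction(genome.sequence(iv)) for iv in usable],
        at_tolerance=at_tolerance, rng=rng, pad=span, max_tries=max_tries,
    )
    unmatched = sample_noncoding_intervals(
        genome, features, lengths, rng=rng, pad=span, max_tries=max_tries,
    )

    def extract(ivs: Sequence[GenomicInterval]) -> list[str]:
        out = []
        for iv in ivs:
            mid = (iv.start + iv.end) // 2
            out.append(genome.chromosomes[iv.chrom][mid - span : mid + span])
        return out

    cns_tracks = occupancy_tracks(extracts)
    matched_tracks = occupancy_tracks(extract(matched))
    unmatched_tracks = occupancy_tracks(extract(unmatched))

    c0 = span - center_window // 2
    c1 = span + (center_window + 1) // 2
    a = cns_tracks[:, c0:c1].mean(axis=1)
    b = matched_tracks[:, c0:c1].mean(axis=1)
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0  # degenerate (e.g. constant model): no difference
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return OccupancyProfile(
        positions=np.arange(-span, span),
        cns=cns_tracks.mean(axis=0),
        control_matched=matched_tracks.mean(axis=0),
        control_unmatched=unmatched_tracks.mean(axis=0),
        n_cns=len(usable),
        t=float(t),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# Methylation and hotspots
# ---------------------------------------------------------------------------

@dataclass
class MethylationResult:
    k_cns: int
    n_cns: int
    k_rand: int
    n_rand: int
    z: float
    p: float
    testable: bool


def methylation_overlap(
    cns_set: Sequence[GenomicInterval],
    calls: pd.DataFrame,
    genome: SpeciesGenome,
    features: FeatureTable,
    n_random_sets: int = 27,
    seed: int = 0,
) -> MethylationResult:
    """Two-proportion z-test of methylation presence in CNSs vs length-matched
    random noncoding intervals (``n_random_sets`` sets of |cns_set| each).

    An interval counts methylated iff >= 1 call (any context, either strand)
    lies within it.  z uses the pooled-proportion form; when the pooled
    proportion is degenerate (0 or 1) the comparison is not testable and z/p
    are NaN.
    """
    if not cns_set:
        raise ValueError("empty CNS set")
    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in calls.groupby("chrom")
    }

    def methylated(iv: GenomicInterval) -> bool:
        pos = pos_by_chrom.get(iv.chrom)
        if pos is None:
            return False
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        return hi > lo

    k_cns = sum(methylated(iv) for iv in cns_set)
    n_cns = len(cns_set)

    rng = np.random.default_rng(seed)
    lengths = [iv.length for iv in cns_set]
    k_rand = 0
    n_rand = 0
    for _ in range(n_random_sets):
        sample = sample_noncoding_intervals(genome, features, lengths, rng=rng)
        k_rand += sum(methylated(iv) for iv in sample)
        n_rand += len(sample)

    return two_proportion_z(k_cns, n_cns, k_rand, n_rand)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> MethylationResult:
    """Pooled two-proportion z: (p1-p2) / sqrt(pbar(1-pbar)(1/n1+1/n2))."""
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return MethylationResult(x1, n1, x2, n2, float("nan"), float("nan"), False)
    p1, p2 = x1 / n1, x2 / n2
    z = (p1 - p2) / math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.norm.sf(abs(z))
    return MethylationResult(x1, n1, x2, n2, z, p, True)


def hotspot_overlap(
    cns_set: Sequence[GenomicInterval],
    hotspot_intervals: Sequence[GenomicInterval],
) -> tuple[int, list[GenomicInterval]]:
    """Count of CNSs overlapping (>= 1 bp) any recombination hotspot."""
    hot_by_chrom: dict[str, list[GenomicInterval]] = {}
    for h in hotspot_intervals:
        hot_by_chrom.setdefault(h.chrom, []).append(h)
    overlapping = [
        iv
        for iv in cns_set
        if any(overlaps(iv, h) for h in hot_by_chrom.get(iv.chrom, ()))
    ]
    return len(overlapping), overlapping
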