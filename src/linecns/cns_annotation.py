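"""CNS characterization against the reference annotation: genomic location
classes, likely target genes, synteny of target genes, and term enrichment.

Location classes follow the reference-genome bookkeeping used for plant CNSs:
a CNS overlapping an annotated UTR is a UTR CNS (5' vs 3' resolved by larger
overlap, ties to 5'), otherwise a CNS inside a gene span that touches no exon
is intronic, and everything else is intergenic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import FeatureTable, GenomicInterval

CATEGORIES = ("intergenic", "intron", "UTR", "5'-UTR", "3'-UTR")


def _overlap_len(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def classify_location(cns: GenomicInterval, features: FeatureTable) -> str:
    """Classify a CNS as 5'-UTR, 3'-UTR, intron or intergenic.

    Precedence: UTR > intron > intergenic.  A CNS overlapping both UTR types
    is assigned the one with the larger overlap (ties to 5').
    """
    if cns.chrom not in features.chromosomes():
        raise ValueError(f"chromosome {cns.chrom!r} absent from annotation")
    utr5 = features.overlapping(cns, ("five_prime_UTR",))
    utr3 = features.overlapping(cns, ("three_prime_UTR",))
    if utr5 or utr3:
        o5 = max((_overlap_len(cns, f.interval) for f in utr5), default=0)
        o3 = max((_overlap_len(cns, f.interval) for f in utr3), default=0)
        return "5'-UTR" if o5 >= o3 else "3'-UTR"
    genes = features.overlapping(cns, ("gene",))
    inside = any(
        g.interval.start <= cns.start and cns.end <= g.interval.end for g in genes
    )
    if inside and not features.overlapping(cns, ("exon",)):
        return "intron"
    return "intergenic"


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LocationSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    genome_composition: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            rows.append(
                {
                    "category": cat,
                    "count": self.counts.get(cat, 0),
                    "percent": self.percentages.get(cat, 0.0),
                    "genome_percent": self.genome_composition.get(cat, float("nan")),
                    "z": self.z.get(cat, float("nan")),
                    "p": self.p.get(cat, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def location_summary(
    counts: Mapping[str, int],
    genome_composition: Mapping[str, float],
) -> LocationSummary:
    """Percentages (one decimal, round-half-up) and per-category one-proportion
    z-tests of the observed location counts against genome composition.

    ``counts`` uses keys among {intergenic, intron, UTR, 5'-UTR, 3'-UTR}; the
    UTR count defaults to 5' + 3' when absent.  ``genome_composition`` gives
    expected percentages; intergenic + intron + UTR must total ~100 (+-0.5).
    """
    counts = dict(counts)
    for key in counts:
        if key not in CATEGORIES:
            raise ValueError(f"unknown category {key!r}")
        if counts[key] < 0:
            raise ValueError("counts must be >= 0")
    if "UTR" not in counts:
        counts["UTR"] = counts.get("5'-UTR", 0) + counts.get("3'-UTR", 0)
    total = counts.get("intergenic", 0) + counts.get("intron", 0) + counts["UTR"]
    if total <= 0:
        raise ValueError("total count must be > 0")
    comp_total = (
        genome_composition.get("intergenic", 0)
        + genome_composition.get("intron", 0)
        + genome_composition.get("UTR",
            genome_composition.get("5'-UTR", 0) + genome_composition.get("3'-UTR", 0))
    )
    if abs(comp_total - 100.0) > 0.5:
        raise ValueError(f"genome composition sums to {comp_total}, expected ~100")

    percentages = {}
    z = {}
    p = {}
    for cat in CATEGORIES:
        if cat not in counts:
            continue
        phat = counts[cat] / total
        percentages[cat] = _round_half_up(100.0 * phat)
        if cat in genome_composition:
            p0 = genome_composition[cat] / 100.0
            se = math.sqrt(p0 * (1.0 - p0) / total)
            z[cat] = (phat - p0) / se
            p[cat] = 2.0 * stats.norm.sf(abs(z[cat]))
    return LocationSummary(
        counts=counts,
        percentages=percentages,
        genome_composition=dict(genome_composition),
        z=z,
        p=p,
        total=total,
    )


@dataclass(frozen=True)
class TargetAssignment:
    cns_id: str
    gene_id: str | None
    relation: str  # inside-UTR, inside-intron, nearest-upstream, nearest-downstream, none
    distance: int
    secondary_gene_id: str | None = None


def nearest_gene(
    cns: GenomicInterval, features: FeatureTable, cns_id: str = "cns"
) -> TargetAssignment:
    """The likely target gene: the gene a CNS resides in (UTR or intron), else
    the closest gene edge-to-edge; exact ties report both genes, primary the
    lexicographically smaller id."""
    loc = classify_location(cns, features)
    if loc in ("5'-UTR", "3'-UTR", "intron"):
        kinds = ("five_prime_UTR", "three_prime_UTR") if loc != "intron" else ("gene",)
        host = features.overlapping(cns, kinds)
        gene_id = sorted(f.gene_id for f in host)[0]
        relation = "inside-intron" if loc == "intron" else "inside-UTR"
        return TargetAssignment(cns_id, gene_id, relation, 0)

    genes = [f for f in features.genes() if f.interval.chrom == cns.chrom]
    if not genes:
        return TargetAssignment(cns_id, None, "none", -1)
    with_d = sorted(
        ((cns.distance(g.interval), g) for g in genes), key=lambda t: (t[0], t[1].gene_id)
    )
    d, g = with_d[0]
    if d == 0:
        # overlapping a gene span without being inside UTR/intron (e.g. exon edge)
        return TargetAssignment(cns_id, g.gene_id, "nearest-upstream", 0)
    secondary = None
    if len(with_d) > 1 and with_d[1][0] == d:
        secondary = with_d[1][1].gene_id
    if g.interval.start >= cns.end:  # gene lies 3'-ward of the CNS in + coordinates
        relation = "nearest-upstream" if g.interval.strand != "-" else "nearest-downstream"
    else:
        relation = "nearest-downstream" if g.interval.strand != "-" else "nearest-upstream"
    return TargetAssignment(cns_id, g.gene_id, relation, d, secondary)


def synteny_check(
    assignment: TargetAssignment,
    ortholog_map: Mapping[str, str],
    subject_cns_interval: GenomicInterval,
    subject_features: FeatureTable,
    range_bp: int = 5000,
) -> bool | str:
    """True iff the ortholog of the target gene lies within ``range_bp``
    (edge-to-edge, inclusive) of the CNS's subject-genome interval.

    Returns "unknown" when the target gene is absent from the ortholog map.
    """
    if assignment.gene_id is None or assignment.gene_id not in ortholog_map:
        return "unknown"
    ortholog = ortholog_map[assignment.gene_id]
    candidates = [f for f in subject_features.genes() if f.gene_id == ortholog]
    if not candidates:
        return "unknown"
    best = min(
        (
            f.interval.distance(subject_cns_interval)
            for f in candidates
            if f.interval.chrom == subject_cns_interval.chrom
        ),
        default=None,
    )
    return best is not None and best <= range_bp


def term_enrichment(
    target_genes: Iterable[str],
    gene_to_terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms among target genes.

    For each term with K genes in the universe of size N, and k of the n
    target genes, p = P(X >= k) with X ~ Hypergeometric(N, K, n), then
    Benjamini-Hochberg across terms.  Returns a DataFrame sorted by ascending
    p with columns term, k, K, n, N, p, q.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = set(target_genes)
    if not targets <= universe:
        raise ValueError("target genes must be a subset of the universe")
    term_universe: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        if gene not in universe:
            continue
        for t in terms:
            term_universe.setdefault(t, set()).add(gene)
    N, n = len(universe), len(targets)
    rows = []
    for term, members in sorted(term_universe.items()):
        K = len(members)
        k = len(members & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return df
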