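"""Core CNS inference: filters, best-hit resolution, the chained common-CNS
search, lineage-specific calling by outgroup exclusion, all-pairs unions, and
ancestral-loss counting under Dollo parsimony.

The chained search follows the study design: the reference genome is searched
against the second species, hits overlapping coding sequence on either side
are dropped, overlapping hits are resolved to the lowest-e-value one, and the
surviving reference subsequences are carried forward as queries against each
further species in turn.  A candidate survives a step iff at least one
significant non-coding hit remains, and is trimmed to its best hit's aligned
query span, so the final coordinates are the conserved core on the reference.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genome_io import (
    FeatureTable,
    GenomicInterval,
    SpeciesGenome,
    merge_intervals,
    overlaps,
)
from .homology_search import (
    LocalAlignment,
    ScoringScheme,
    SearchParams,
    seed_extend_search,
)

logger = logging.getLogger(__name__)


@dataclass
class CnsRecord:
    """A candidate conserved element on the reference genome."""

    cns_id: str
    reference_species: str
    reference_interval: GenomicInterval
    support: dict[str, LocalAlignment] = field(default_factory=dict)
    lineage_label: str | None = None

    @property
    def length(self) -> int:
        return self.reference_interval.length

    @property
    def mean_identity_pct(self) -> float:
        if not self.support:
            return 100.0
        return float(np.mean([a.identity_pct for a in self.support.values()]))


# ---------------------------------------------------------------------------
# Filters and resolution
# ---------------------------------------------------------------------------

def noncoding_filter(
    hits: Sequence[LocalAlignment],
    query_features: FeatureTable,
    subject_features: FeatureTable,
    ncrna_intervals: Sequence[GenomicInterval] | None = None,
    exclude: str = "CDS",
) -> list[LocalAlignment]:
    """Drop hits overlapping coding sequence on either side, and (optionally)
    hits overlapping supplied ncRNA intervals on the query side.

    ``exclude`` may be "CDS" (coding regions only, the common-CNS rule) or
    "gene" (whole gene spans, the ancestral-loss rule).
    """
    types = ("CDS",) if exclude == "CDS" else ("gene",)
    kept: list[LocalAlignment] = []
    n_coding = n_ncrna = 0
    for h in hits:
        if query_features.overlapping(h.query_interval, types) or subject_features.overlapping(
            h.subject_interval, types
        ):
            n_coding += 1
            continue
        if ncrna_intervals is not None and any(
            overlaps(h.query_interval, iv) for iv in ncrna_intervals
        ):
            n_ncrna += 1
            continue
        kept.append(h)
    logger.info(
        "noncoding_filter: removed %d coding-overlap and %d ncRNA-overlap hits, kept %d",
        n_coding, n_ncrna, len(kept),
    )
    return kept


def best_hit_resolution(hits: Sequence[LocalAlignment]) -> list[LocalAlignment]:
    """Among hits overlapping on the query, retain only the lowest-e-value one.

    Greedy by ascending (E, -score, query chromosome, query start): a hit is
    accepted iff its query interval overlaps no previously accepted hit.
    """
    ordered = sorted(
        hits, key=lambda h: (h.evalue, -h.score, h.query_interval.chrom, h.query_interval.start)
    )
    accepted: list[LocalAlignment] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for h in ordered:
        iv = h.query_interval
        spans = occupied.setdefault(iv.chrom, [])
        if any(iv.start < e and s < iv.end for s, e in spans):
            continue
        spans.append((iv.start, iv.end))
        accepted.append(h)
    accepted.sort(key=lambda h: (h.query_interval.chrom, h.query_interval.start))
    return accepted


# ---------------------------------------------------------------------------
# Chained common-CNS search
# ---------------------------------------------------------------------------

def chained_common_search(
    ordered_species: Sequence[str],
    genomes: Mapping[str, SpeciesGenome],
    features: Mapping[str, FeatureTable],
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
    ncrna_intervals: Sequence[GenomicInterval] | None = None,
) -> list[CnsRecord]:
    """Chained search for elements conserved (and noncoding) in every listed
    species; the first species is the chain's query and reference.

    Returns one CnsRecord per surviving candidate, carrying the best
    supporting alignment found in each non-reference species.  Reference
    coordinates are the final trimmed conserved core.
    """
    params = params or SearchParams()
    if len(ordered_species) < 2:
        raise ValueError("chain needs at least two species")
    for sp in ordered_species:
        if sp not in features:
            raise ValueError(f"species {sp!r} has no annotation; coding filter impossible")
        if sp not in genomes:
            raise ValueError(f"species {sp!r} has no genome")

    ref = ordered_species[0]
    ref_genome = genomes[ref]
    ref_features = features[ref]

    # step 1: reference genome vs second species
    second = ordered_species[1]
    hits = seed_extend_search(ref_genome, genomes[second], params, scheme)
    hits = noncoding_filter(hits, ref_features, features[second], ncrna_intervals)
    hits = best_hit_resolution(hits)
    candidates: list[dict] = []
    for i, h in enumerate(hits):
        candidates.append(
            {"interval": h.query_interval, "support": {second: h}}
        )
    logger.info("chain step %s->%s: %d candidates", ref, second, len(candidates))

    for sp in ordered_species[2:]:
        if not candidates:
            break
        queries = {
            f"cand{i}": ref_genome.sequence(c["interval"]) for i, c in enumerate(candidates)
        }
        hits = seed_extend_search(queries, genomes[sp], params, scheme)
        # filter subject-side coding overlap; query side is already noncoding
        # on the reference but candidate-local coordinates must be lifted back
        lifted: dict[int, list[LocalAlignment]] = {}
        for h in hits:
            idx = int(h.query_interval.chrom[4:])
            base = candidates[idx]["interval"]
            q_iv = GenomicInterval(
                base.chrom,
                base.start + h.query_interval.start,
                base.start + h.query_interval.end,
                "+",
            )
            if ref_features.overlapping(q_iv, ("CDS",)):
                continue
            if features[sp].overlapping(h.subject_interval, ("CDS",)):
                continue
            if ncrna_intervals is not None and any(overlaps(q_iv, iv) for iv in ncrna_intervals):
                continue
            lifted.setdefault(idx, []).append(
                LocalAlignment(
                    query_interval=q_iv,
                    subject_interval=h.subject_interval,
                    strand=h.strand,
                    score=h.score,
                    evalue=h.evalue,
                    identity_pct=h.identity_pct,
                    aligned_query=h.aligned_query,
                    aligned_subject=h.aligned_subject,
                )
            )
        survivors: list[dict] = []
        for idx, cand in enumerate(candidates):
            if idx not in lifted:
                continue
            best = min(
                lifted[idx],
                key=lambda h: (h.evalue, -h.score, h.query_interval.start),
            )
            trimmed = best.query_interval
            if trimmed.length < params.min_length:
                continue
            # trim candidate to the supported span; clip earlier support
            cand["interval"] = trimmed
            cand["support"][sp] = best
            survivors.append(cand)
        candidates = survivors
        logger.info("chain step vs %s: %d candidates survive", sp, len(candidates))

    records = []
    for i, cand in enumerate(candidates):
        records.append(
            CnsRecord(
                cns_id=f"cns{i:05d}",
                reference_species=ref,
                reference_interval=cand["interval"],
                support=cand["support"],
            )
        )
    return records


def lineage_specific_filter(
    common_cns: Sequence[CnsRecord],
    reference_genome: SpeciesGenome,
    outgroup_genomes: Mapping[str, SpeciesGenome],
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
    lineage_label: str = "custom",
) -> list[CnsRecord]:
    """Retain CNSs with no significant hit (E <= cutoff, any genomic context)
    in *every* outgroup genome.

    An outgroup hit at exactly the cutoff counts as found (threshold
    inclusive).  Per-outgroup elimination counts are logged.
    """
    params = params or SearchParams()
    if not outgroup_genomes:
        raise ValueError("at least one outgroup is required")
    alive = {r.cns_id: r for r in common_cns}
    for og, genome in outgroup_genomes.items():
        if not alive:
            break
        queries = {
            cid: reference_genome.sequence(r.reference_interval) for cid, r in alive.items()
        }
        hits = seed_extend_search(queries, genome, params, scheme)
        found = {h.query_interval.chrom for h in hits if h.evalue <= params.evalue_cutoff}
        logger.info("outgroup %s eliminates %d of %d candidates", og, len(found), len(alive))
        alive = {cid: r for cid, r in alive.items() if cid not in found}
    out = []
    for r in common_cns:
        if r.cns_id in alive:
            r.lineage_label = lineage_label
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# All-pairs unions
# ---------------------------------------------------------------------------

def schedule_all_pairs(species: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered species pairs, in input order: C(n, 2) searches."""
    return list(itertools.combinations(species, 2))


def all_pairs_union(
    genomes: Mapping[str, SpeciesGenome],
    features: Mapping[str, FeatureTable],
    tree: TreeNode,
    params: SearchParams | None = None,
    scheme: ScoringScheme | None = None,
    reference: str | None = None,
) -> dict[str, dict]:
    """Run one noncoding search per unordered species pair and report, for each
    internal tree node, the merged union of CNS intervals from pairs inside
    that node's clade.

    Unions need a common coordinate system, so each node's union is taken on a
    per-node reference leaf (the global ``reference`` when it belongs to the
    clade, otherwise the clade's first leaf) over the pairs that involve that
    leaf as query.  Node keys are tree node names, or ``node<k>`` for unnamed
    internal nodes (k in preorder).
    """
    params = params or SearchParams()
    species = [t.name for t in tree.tips()]
    pairs = schedule_all_pairs(species)
    pair_hits: dict[tuple[str, str], list[LocalAlignment]] = {}
    for a, b in pairs:
        hits = seed_extend_search(genomes[a], genomes[b], params, scheme)
        hits = noncoding_filter(hits, features[a], features[b])
        pair_hits[(a, b)] = best_hit_resolution(hits)

    results: dict[str, dict] = {}
    for k, node in enumerate(tree.preorder(include_self=True)):
        if node.is_tip():
            continue
        clade = [t.name for t in node.tips()]
        node_ref = reference if reference in clade else clade[0]
        intervals = []
        n_pairs = 0
        for (a, b), hits in pair_hits.items():
            if a not in clade or b not in clade:
                continue
            n_pairs += 1
            if a == node_ref:
                intervals.extend(h.query_interval for h in hits)
            elif b == node_ref:
                intervals.extend(h.subject_interval for h in hits)
        merged = merge_intervals(intervals) if intervals else []
        name = node.name or f"node{k}"
        results[name] = {
            "reference": node_ref,
            "n_pairs_in_clade": n_pairs,
            "union_count": len(merged),
            "union_intervals": merged,
        }
    results["n_searches"] = len(pairs)
    return results


# ---------------------------------------------------------------------------
# Ancestral loss (Dollo parsimony)
# ---------------------------------------------------------------------------

def build_presence_matrix(
    superset: Sequence[GenomicInterval],
    hits_by_species: Mapping[str, Sequence[LocalAlignment]],
) -> pd.DataFrame:
    """Presence/absence of each ancestral (basal-reference) interval per species.

    ``superset`` should be the merged union of all species' query-side hits on
    the basal reference (see :func:`linecns.genome_io.merge_intervals`); a
    species is present in a row iff one of its hits overlaps that interval.
    """
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in superset]
    mat = pd.DataFrame(False, index=index, columns=list(hits_by_species))
    for sp, hits in hits_by_species.items():
        for h in hits:
            for i, iv in enumerate(superset):
                if overlaps(iv, h.query_interval):
                    mat.iloc[i, mat.columns.get_loc(sp)] = True
    return mat


def ancestral_loss(presence: pd.DataFrame, tree: TreeNode) -> TreeNode:
    """Assign minimum loss events per branch under Dollo parsimony.

    Each character (ancestral CNS) originates once at the root; a loss on a
    branch removes it from the entire clade below.  The minimum-loss
    assignment places one loss on the stem of each maximal all-absent clade.
    Returns a copy of the tree whose nodes carry ``loss_count`` attributes
    (the root's own count covers the all-absent pattern, a loss on the
    ingroup stem).
    """
    tree = tree.copy()
    tips = {t.name for t in tree.tips()}
    missing = set(presence.columns) - tips
    if missing:
        raise ValueError(f"species in matrix missing from tree: {sorted(missing)}")
    for node in tree.traverse(include_self=True):
        node.loss_count = 0

    cols = list(presence.columns)
    for _, row in presence.iterrows():
        present = {sp for sp, v in zip(cols, row.values) if v}
        # postorder: a clade is absent iff all its tips are absent
        absent: dict[int, bool] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                absent[id(node)] = node.name not in present
            else:
                absent[id(node)] = all(absent[id(c)] for c in node.children)
        for node in tree.traverse(include_self=True):
            if absent[id(node)] and (node.parent is None or not absent[id(node.parent)]):
                node.loss_count += 1
    return tree


def total_losses(tree: TreeNode) -> int:
    return sum(getattr(n, "loss_count", 0) for n in tree.traverse(include_self=True))


def loss_annotated_newick(tree: TreeNode) -> str:
    """Newick string with per-branch loss counts as node labels."""
    t = tree.copy()
    for node in t.traverse(include_self=True):
        count = getattr(node, "loss_count", 0)
        if node.is_tip():
            node.name = f"{node.name}_loss{count}"
        else:
            node.name = f"loss{count}"
    return str(t).strip()
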