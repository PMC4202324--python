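"""Synthetic multi-species genomes with planted conserved noncoding elements.

The generator evolves a block-structured ancestral genome down a user-supplied
species tree: alternating intergenic and gene blocks (5'UTR / CDS-intron
alternation / 3'UTR), with conserved elements planted inside intergenic
blocks.  Substitutions follow a Kimura two-parameter kernel (Jukes-Cantor at
the default transition/transversion ratio 0.5); planted elements evolve at a
scaled-down rate; elements assigned to a lineage are deleted on every branch
outside that lineage, and each deletion is recorded as a loss event.  Indels
occur only in intergenic background, so gene annotation and planted-element
coordinates stay exact.  All randomness flows from one master seed through
named substreams, so identical configurations give byte-identical output.

The default gene architecture (intergenic 3477 bp, introns 3 x 400 bp, UTRs
120 + 170 bp per gene) reproduces a noncoding-genome composition of about
70% intergenic / 24.2% intron / 5.8% UTR, the composition of the rice
noncoding genome; background base composition is A+T 0.56 (the rice genomic
average) and planted elements A+T 0.54.
"""
from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .genome_io import (
    Feature,
    FeatureTable,
    GenomicInterval,
    SpeciesGenome,
    merge_intervals,
    write_bed,
    write_fasta,
    write_gff3,
    write_methylation,
)

_BASES = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)


def _rng(seed: int, *names) -> np.random.Generator:
    tag = zlib.crc32("/".join(str(n) for n in names).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))


@dataclass
class CnsPlant:
    """A batch of planted conserved elements sharing a lineage assignment.

    ``lineage`` names a tree node (internal or leaf); the element is retained
    in exactly the leaves below it and deleted (one loss event per stem) on
    the branches hanging off the path from the root.  ``lineage=None`` plants
    the element in every species.
    """

    count: int
    lineage: str | None = None
    rate_scaling: float = 0.05
    length_log_mean: float = math.log(80.0)
    length_log_sigma: float = 0.45
    min_length: int = 40
    max_length: int = 400


@dataclass
class GeneModel:
    n_genes: int = 12
    utr5_len: int = 120
    utr3_len: int = 170
    cds_len: int = 300
    n_cds: int = 4
    intron_len: int = 400
    intergenic_len: int = 3477  # -> noncoding composition ~70 / 24.2 / 5.8


@dataclass
class SimulationConfig:
    tree_newick: str
    plants: list[CnsPlant]
    seed: int
    genes: GeneModel = field(default_factory=GeneModel)
    background_at: float = 0.56
    cns_at: float = 0.54
    ts_tv: float = 0.5  # 0.5 = Jukes-Cantor; larger exercises transition bias
    indel_rate: float = 0.002  # events per site per substitution unit
    indel_max: int = 10
    reference: str | None = None
    methylation_rates: dict[str, float] | None = None  # e.g. CG 0.24, CHG 0.10, CHH 0.03
    hotspot_count: int = 0
    hotspot_length: int = 2000

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["plants"] = [CnsPlant(**p) for p in raw.get("plants", [])]
        if "genes" in raw:
            raw["genes"] = GeneModel(**raw["genes"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted-element coordinates, retention flags and per-branch loss events."""

    elements: pd.DataFrame  # element_id, lineage, species, chrom, start, end, retained
    loss_counts: dict[str, int]  # tree node name -> deletions on its stem branch
    element_meta: pd.DataFrame  # element_id, lineage, length, rate_scaling

    def intervals(self, species: str, retained_only: bool = True) -> list[GenomicInterval]:
        sub = self.elements[self.elements["species"] == species]
        if retained_only:
            sub = sub[sub["retained"]]
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sub.itertuples(index=False)
        ]

    def presence_matrix(self) -> pd.DataFrame:
        return (
            self.elements.pivot_table(
                index="element_id", columns="species", values="retained", aggfunc="first"
            )
            .fillna(False)
            .astype(bool)
        )


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: TreeNode
    genomes: dict[str, SpeciesGenome]
    features: dict[str, FeatureTable]
    truth: GroundTruth
    methylation: pd.DataFrame | None = None
    hotspots: list[GenomicInterval] | None = None


# ---------------------------------------------------------------------------
# Evolution kernels
# ---------------------------------------------------------------------------

def _draw_seq(n: int, at: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _k2p_probs(d: float, ts_tv: float) -> tuple[float, float]:
    """(transition prob, per-transversion prob) after divergence d (subs/site)."""
    r = ts_tv
    alpha = d * r / (r + 1.0)
    beta = d / (2.0 * (r + 1.0))
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta) - 0.5 * math.exp(-2.0 * (alpha + beta))
    p_tv = 0.25 - 0.25 * math.exp(-4.0 * beta)
    return p_ts, p_tv


def _mutate(codes: np.ndarray, d: float, ts_tv: float, rng: np.random.Generator) -> np.ndarray:
    if d <= 0 or len(codes) == 0:
        return codes.copy()
    p_ts, p_tv = _k2p_probs(d, ts_tv)
    u = rng.random(len(codes))
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] ^= 2  # A<->G, C<->T
    out[tv1] ^= 1
    out[tv2] ^= 3
    return out


def _apply_indels(
    codes: np.ndarray, t: float, at: float, rate: float, max_len: int, rng: np.random.Generator
) -> np.ndarray:
    if t <= 0 or rate <= 0 or len(codes) == 0:
        return codes
    n_events = rng.poisson(rate * len(codes) * t)
    for _ in range(n_events):
        length = int(min(rng.geometric(0.35), max_len))
        pos = int(rng.integers(0, len(codes) + 1))
        if rng.random() < 0.5 and len(codes) > length + pos:
            codes = np.concatenate([codes[:pos], codes[pos + length :]])
        else:
            codes = np.concatenate([codes[:pos], _draw_seq(length, at, rng), codes[pos:]])
    return codes


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    block_id: int
    kind: str  # 'bg', 'element', 'gene_part'
    length: int
    rate_scale: float = 1.0
    role: str | None = None  # for gene parts: utr5, utr3, cds, intron
    gene_index: int | None = None
    strand: str = "+"
    element_id: str | None = None


def _named_tree(newick: str) -> TreeNode:
    tree = TreeNode.read(StringIO(newick))
    k = 0
    for node in tree.preorder(include_self=True):
        if not node.is_tip() and not node.name:
            node.name = f"nd{k}"
        k += 1
    return tree


def _element_losses(tree: TreeNode, lineage: str | None) -> tuple[set[str], list[str]]:
    """(retained leaves, loss-branch node names) for a lineage assignment."""
    leaves = [t.name for t in tree.tips()]
    if lineage is None:
        return set(leaves), []
    node = tree.find(lineage)
    retained = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
    path = list(node.ancestors())[::-1] + [node]  # root ... node
    losses = []
    for parent, on_path in zip(path[:-1], path[1:]):
        for child in parent.children:
            if child is not on_path:
                losses.append(child.name)
    return retained, losses


def _build_template(cfg: SimulationConfig, tree: TreeNode) -> tuple[list[_Block], dict]:
    g = cfg.genes
    n_slots = g.n_genes + 1

    # draw element lengths and lineage assignments
    elements = []
    for pi, plant in enumerate(cfg.plants):
        rng = _rng(cfg.seed, "lengths", pi)
        raw = np.exp(rng.normal(plant.length_log_mean, plant.length_log_sigma, plant.count))
        lengths = np.clip(np.round(raw).astype(int), plant.min_length, plant.max_length)
        for ei, length in enumerate(lengths):
            if length > g.intergenic_len:
                raise ValueError(
                    f"element of length {length} exceeds available intergenic space "
                    f"({g.intergenic_len})"
                )
            elements.append(
                {
                    "element_id": f"el_{pi}_{ei}",
                    "lineage": plant.lineage,
                    "length": int(length),
                    "rate_scaling": plant.rate_scaling,
                }
            )
    # round-robin elements over intergenic slots
    slots: list[list[dict]] = [[] for _ in range(n_slots)]
    for i, el in enumerate(elements):
        slots[i % n_slots].append(el)

    blocks: list[_Block] = []
    bid = 0

    def add(kind, length, **kw):
        nonlocal bid
        blocks.append(_Block(bid, kind, int(length), **kw))
        bid += 1

    for gi in range(g.n_genes + 1):
        in_slot = slots[gi]
        parts = len(in_slot) + 1
        part_len = g.intergenic_len // parts
        if part_len < 20:
            raise ValueError("too many elements for the intergenic space of one slot")
        rest = g.intergenic_len - part_len * parts
        for si, el in enumerate(in_slot):
            add("bg", part_len + (rest if si == 0 else 0))
            add(
                "element", el["length"],
                rate_scale=el["rate_scaling"], element_id=el["element_id"],
            )
        add("bg", part_len)
        if gi == g.n_genes:
            break
        strand = "+" if gi % 2 == 0 else "-"
        roles: list[tuple[str, int]] = [("utr5", g.utr5_len)]
        for ci in range(g.n_cds):
            roles.append(("cds", g.cds_len))
            if ci < g.n_cds - 1:
                roles.append(("intron", g.intron_len))
        roles.append(("utr3", g.utr3_len))
        if strand == "-":
            roles = roles[::-1]
        for role, length in roles:
            add("gene_part", length, role=role, gene_index=gi, strand=strand)

    meta = {
        "elements": elements,
        "retention": {
            el["element_id"]: _element_losses(tree, el["lineage"]) for el in elements
        },
    }
    return blocks, meta


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Generate genomes, annotations and ground truth for one configuration."""
    tree = _named_tree(cfg.tree_newick)
    blocks, meta = _build_template(cfg, tree)

    # ancestral sequences
    root_seqs = []
    for b in blocks:
        rng = _rng(cfg.seed, "root", b.block_id)
        at = cfg.cns_at if b.kind == "element" else cfg.background_at
        root_seqs.append(_draw_seq(b.length, at, rng))

    leaf_seqs: dict[str, list[np.ndarray]] = {}

    def descend(node: TreeNode, seqs: list[np.ndarray]) -> None:
        if node.is_tip():
            leaf_seqs[node.name] = seqs
            return
        for child in node.children:
            t = child.length or 0.0
            child_seqs = []
            for b, s in zip(blocks, seqs):
                rng = _rng(cfg.seed, "branch", child.name, b.block_id)
                s2 = _mutate(s, t * b.rate_scale, cfg.ts_tv, rng)
                if b.kind == "bg":
                    s2 = _apply_indels(
                        s2, t, cfg.background_at, cfg.indel_rate, cfg.indel_max, rng
                    )
                child_seqs.append(s2)
            descend(child, child_seqs)

    descend(tree, root_seqs)

    retention: dict[str, tuple[set[str], list[str]]] = meta["retention"]
    loss_counts: dict[str, int] = {}
    for el in meta["elements"]:
        for branch in retention[el["element_id"]][1]:
            loss_counts[branch] = loss_counts.get(branch, 0) + 1

    genomes: dict[str, SpeciesGenome] = {}
    features: dict[str, FeatureTable] = {}
    truth_rows = []
    for leaf in tree.tips():
        sp = leaf.name
        seqs = leaf_seqs[sp]
        chrom = "chr1"
        pieces = []
        offset = 0
        gene_parts: dict[int, list[tuple[str, int, int, str]]] = {}
        for b, s in zip(blocks, seqs):
            if b.kind == "element":
                retained = sp in retention[b.element_id][0]
                if not retained:
                    truth_rows.append(
                        {
                            "element_id": b.element_id, "species": sp, "chrom": chrom,
                            "start": -1, "end": -1, "retained": False,
                        }
                    )
                    continue
                truth_rows.append(
                    {
                        "element_id": b.element_id, "species": sp, "chrom": chrom,
                        "start": offset, "end": offset + len(s), "retained": True,
                    }
                )
            elif b.kind == "gene_part":
                gene_parts.setdefault(b.gene_index, []).append(
                    (b.role, offset, offset + len(s), b.strand)
                )
            pieces.append(s)
            offset += len(s)
        seq = _BASES[np.concatenate(pieces)].tobytes().decode()
        genomes[sp] = SpeciesGenome(sp, {chrom: seq})

        table = FeatureTable(sp)
        for gi, parts in gene_parts.items():
            gene_id = f"{sp}_g{gi}"
            strand = parts[0][3]
            start = min(p[1] for p in parts)
            end = max(p[2] for p in parts)
            table.add(Feature(GenomicInterval(chrom, start, end, strand), "gene", gene_id))
            exon_start = None
            prev_end = None
            for role, s0, s1, _ in parts + [("intron", end, end, strand)]:
                if role == "intron":
                    if exon_start is not None and prev_end > exon_start:
                        table.add(
                            Feature(GenomicInterval(chrom, exon_start, prev_end, strand),
                                    "exon", gene_id)
                        )
                    exon_start = None
                else:
                    if exon_start is None:
                        exon_start = s0
                    prev_end = s1
                    ftype = {"utr5": "five_prime_UTR", "utr3": "three_prime_UTR",
                             "cds": "CDS"}[role]
                    table.add(Feature(GenomicInterval(chrom, s0, s1, strand), ftype, gene_id))
        features[sp] = table

    meta_cols = ["element_id", "lineage", "length", "rate_scaling"]
    truth = GroundTruth(
        elements=pd.DataFrame(
            truth_rows,
            columns=["element_id", "species", "chrom", "start", "end", "retained"],
        ),
        loss_counts=loss_counts,
        element_meta=pd.DataFrame(meta["elements"], columns=meta_cols)[meta_cols],
    )

    reference = cfg.reference or [t.name for t in tree.tips()][0]
    methylation = None
    if cfg.methylation_rates:
        methylation = _simulate_methylation(
            genomes[reference], cfg.methylation_rates, _rng(cfg.seed, "methylation")
        )
    hotspots = None
    if cfg.hotspot_count > 0:
        avoid = truth.intervals(reference)
        hotspots = _simulate_hotspots(
            genomes[reference], features[reference], cfg.hotspot_count,
            cfg.hotspot_length, avoid, _rng(cfg.seed, "hotspots"),
        )
    return SimulationResult(cfg, tree, genomes, features, truth, methylation, hotspots)


def _simulate_methylation(
    genome: SpeciesGenome, rates: Mapping[str, float], rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for chrom, seq in genome.chromosomes.items():
        raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        is_c = raw == ord("C")
        is_g = raw == ord("G")
        n = len(raw)
        for strand, mask, partner in (("+", is_c, is_g), ("-", is_g, is_c)):
            pos = np.flatnonzero(mask)
            d = 1 if strand == "+" else -1
            p1 = pos + d
            p2 = pos + 2 * d
            ok1 = (p1 >= 0) & (p1 < n)
            ok2 = (p2 >= 0) & (p2 < n)
            nxt = np.where(ok1, partner[np.clip(p1, 0, n - 1)], False)
            nxt2 = np.where(ok2, partner[np.clip(p2, 0, n - 1)], False)
            context = np.where(nxt, "CG", np.where(nxt2, "CHG", "CHH"))
            for ctx in ("CG", "CHG", "CHH"):
                rate = rates.get(ctx, 0.0)
                if rate <= 0:
                    continue
                sub = pos[context == ctx]
                keep = sub[rng.random(len(sub)) < rate]
                for p in keep:
                    rows.append({"chrom": chrom, "pos": int(p), "strand": strand, "context": ctx})
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def _simulate_hotspots(
    genome: SpeciesGenome,
    features: FeatureTable,
    count: int,
    length: int,
    avoid: Sequence[GenomicInterval],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    tries = 0
    while len(out) < count and tries < 10_000:
        tries += 1
        candidates = sample_noncoding_intervals(genome, features, [length], rng=rng)
        iv = candidates[0]
        if any(iv.overlaps(a) for a in avoid):
            continue
        out.append(iv)
    return out


def sample_noncoding_intervals(
    genome: SpeciesGenome,
    features: FeatureTable,
    lengths: Sequence[int],
    at_match: float | Sequence[float] | None = None,
    at_tolerance: float = 0.01,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    pad: int = 0,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Sample intervals of the requested lengths uniformly from CDS-free space.

    ``at_match`` (a scalar, or one target per requested length) restricts each
    interval's A+T fraction to +- ``at_tolerance``; ``pad`` additionally keeps
    each interval at least that far from chromosome ends (so flanking spans
    can be extracted).  Raises when matching fails after ``max_tries`` draws
    for any element.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    cds = [f.interval for f in features.features if f.type == "CDS"]
    blocked = merge_intervals(cds) if cds else []
    runs: list[tuple[str, int, int]] = []
    for chrom in genome.nuclear_ids:
        clen = genome.length(chrom)
        prev = 0
        for iv in [b for b in blocked if b.chrom == chrom] + [GenomicInterval(chrom, clen, clen + 1)]:
            if iv.start > prev:
                runs.append((chrom, prev, min(iv.start, clen)))
            prev = max(prev, iv.end)
    if not runs:
        raise ValueError("no noncoding space available")

    targets: list[float | None]
    if at_match is None:
        targets = [None] * len(lengths)
    elif np.isscalar(at_match):
        targets = [float(at_match)] * len(lengths)
    else:
        targets = list(at_match)

    out = []
    for length, target in zip(lengths, targets):
        valid = []
        weights = []
        for chrom, r0, r1 in runs:
            clen = genome.length(chrom)
            lo = max(r0, pad)
            hi = min(r1 - length, clen - pad - length)
            if hi >= lo:
                valid.append((chrom, lo, hi))
                weights.append(hi - lo + 1)
        if not valid:
            raise ValueError(f"no noncoding run can host an interval of length {length}")
        weights = np.asarray(weights, dtype=float)
        weights /= weights.sum()
        placed = None
        for _ in range(max_tries):
            ri = rng.choice(len(valid), p=weights)
            chrom, lo, hi = valid[ri]
            start = int(rng.integers(lo, hi + 1))
            iv = GenomicInterval(chrom, start, start + length)
            if target is not None:
                seq = genome.sequence(iv)
                frac = sum(1 for b in seq if b in "ATat") / length
                if abs(frac - target) > at_tolerance:
                    continue
            placed = iv
            break
        if placed is None:
            raise ValueError(
                f"could not sample a noncoding interval of length {length} "
                f"matching A+T {target:.3f} +- {at_tolerance:.3f} after {max_tries} tries"
            )
        out.append(placed)
    return out


# ---------------------------------------------------------------------------
# Output and presets
# ---------------------------------------------------------------------------

def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Emit FASTA + GFF3 per species, ground-truth BED/JSON, and optional
    methylation/hotspot tracks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, genome in result.genomes.items():
        write_fasta(genome, outdir / f"{sp}.fasta")
        write_gff3(result.features[sp], outdir / f"{sp}.gff3")
        ivs = result.truth.intervals(sp)
        sub = result.truth.elements.query("species == @sp and retained")
        write_bed(ivs, outdir / f"{sp}.truth.bed", names=list(sub["element_id"]))
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "loss_counts": result.truth.loss_counts,
                "elements": result.truth.element_meta.to_dict(orient="records"),
            },
            fh,
            indent=2,
        )
    result.tree.write(str(outdir / "tree.nwk"))
    if result.methylation is not None:
        write_methylation(result.methylation, outdir / "methylation.tsv")
    if result.hotspots is not None:
        write_bed(result.hotspots, outdir / "hotspots.bed")


#: tree used by the discovery preset: a five-species ingroup chain (A..E) with
#: 0.25 substitutions/site per branch, and two outgroups splitting off deeper.
DISCOVERY_TREE = (
    "((((A:0.25,B:0.25)ab:0.25,C:0.25)abc:0.25,(D:0.25,E:0.25)de:0.25)ingroup:0.35,"
    "(O1:0.30,O2:0.30)outgroup:0.35)root;"
)


def preset_lineage_discovery(seed: int) -> SimulationConfig:
    """Study conditions for planted-element recovery: 5 ingroup species, 2
    outgroups, 50 ingroup-lineage elements (plus shared and outgroup-only
    elements), 0.25 subs/site branches, element rate scaling 0.05."""
    return SimulationConfig(
        tree_newick=DISCOVERY_TREE,
        plants=[
            CnsPlant(count=50, lineage="ingroup", rate_scaling=0.05),
            CnsPlant(count=15, lineage=None, rate_scaling=0.05),
            CnsPlant(count=10, lineage="outgroup", rate_scaling=0.05),
        ],
        genes=GeneModel(n_genes=16),
        seed=seed,
    )


def preset_at_border(seed: int, n_cns: int = 200) -> SimulationConfig:
    """Single-genome configuration for the A+T border profile: one element per
    intergenic slot so every element keeps 1000-bp coding-free flanks."""
    return SimulationConfig(
        tree_newick="(R:0.0)root;",
        plants=[CnsPlant(count=n_cns, lineage=None, rate_scaling=0.05)],
        genes=GeneModel(n_genes=n_cns),
        seed=seed,
    )
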