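"""Genomes, annotations and interval arithmetic.

All internal coordinates are 0-based half-open; GFF3 I/O converts to and from
the 1-based inclusive convention of that format, BED I/O is native 0-based
half-open.  Lowercase bases are preserved on input: they carry the soft-masking
state of the source genome (repeat-masked regions), which the homology search
honours when seeding.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
#: the feature types retained from GFF3 input
FEATURE_TYPES = ("gene", "exon", "CDS", "five_prime_UTR", "three_prime_UTR", "ncRNA")
METHYLATION_CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Raised for malformed input files or invalid coordinates."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome; strand '.' = unstranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GenomeIOError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def distance(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance; 0 when overlapping or abutting."""
        if self.chrom != other.chrom:
            raise GenomeIOError("distance undefined across chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 base (half-open; strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping *and abutting* intervals into a sorted disjoint set.

    Abutting intervals ([a,b), [b,c)) merge because the result represents
    covered sequence, not hit identity.  Strand is dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


@dataclass
class SpeciesGenome:
    """Nucleotide sequences of one species, keyed by chromosome id.

    ``organellar_ids`` flags chromosomes that are mitochondrial/chloroplast;
    those are excluded from nuclear CNS discovery.
    """

    species_id: str
    chromosomes: dict[str, str]
    organellar_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for cid, seq in self.chromosomes.items():
            if not seq:
                raise GenomeIOError(f"empty sequence for {cid}")
        unknown = self.organellar_ids - set(self.chromosomes)
        if unknown:
            raise GenomeIOError(f"organellar ids not in genome: {sorted(unknown)}")

    @property
    def nuclear_ids(self) -> list[str]:
        return [c for c in self.chromosomes if c not in self.organellar_ids]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def sequence(self, interval: GenomicInterval) -> str:
        seq = self.chromosomes[interval.chrom]
        if interval.end > len(seq):
            raise GenomeIOError(
                f"interval {interval} exceeds {interval.chrom} length {len(seq)}"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub

    def drop_organellar(self) -> "SpeciesGenome":
        return SpeciesGenome(
            self.species_id,
            {c: s for c, s in self.chromosomes.items() if c not in self.organellar_ids},
        )


def read_fasta(
    path: str | Path,
    species_id: str | None = None,
    organellar_ids: Iterable[str] = (),
) -> SpeciesGenome:
    """Read a (multi-)FASTA file, preserving case. Duplicate headers are rejected."""
    path = Path(path)
    chromosomes: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records")
    for rec in records:
        if rec.id in chromosomes:
            raise GenomeIOError(f"{path}: duplicate header {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise GenomeIOError(f"{path}: empty record {rec.id!r}")
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise GenomeIOError(f"{path}: record {rec.id!r} has invalid characters {sorted(bad)}")
        chromosomes[rec.id] = seq
    return SpeciesGenome(species_id or path.stem, chromosomes, set(organellar_ids))


def write_fasta(genome: SpeciesGenome | Mapping[str, str], path: str | Path, width: int = 70) -> None:
    chroms = genome.chromosomes if isinstance(genome, SpeciesGenome) else genome
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in chroms.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class Feature:
    interval: GenomicInterval
    type: str
    gene_id: str


class FeatureTable:
    """Typed, strand-aware annotation intervals for one species.

    Backed by per-chromosome interval trees so overlap queries run in
    O(log n + k).
    """

    def __init__(self, species_id: str, features: Iterable[Feature] = ()):
        self.species_id = species_id
        self.features: list[Feature] = []
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in features:
            self.add(f)

    def add(self, feature: Feature) -> None:
        if feature.type not in FEATURE_TYPES:
            raise GenomeIOError(f"unknown feature type {feature.type!r}")
        self.features.append(feature)
        iv = feature.interval
        self._trees[iv.chrom].addi(iv.start, iv.end, feature)

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(
        self, interval: GenomicInterval, types: Iterable[str] | None = None
    ) -> list[Feature]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(interval.start, interval.end)]
        if types is not None:
            wanted = set(types)
            hits = [f for f in hits if f.type in wanted]
        return sorted(hits, key=lambda f: (f.interval.start, f.interval.end, f.type, f.gene_id))

    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.type == "gene"]

    def validate_containment(self) -> None:
        """Check every sub-feature lies within its gene's span."""
        spans = {f.gene_id: f.interval for f in self.features if f.type == "gene"}
        for f in self.features:
            if f.type in ("gene", "ncRNA"):
                continue
            span = spans.get(f.gene_id)
            if span is None or not (
                span.chrom == f.interval.chrom
                and span.start <= f.interval.start
                and f.interval.end <= span.end
            ):
                raise GenomeIOError(
                    f"{f.type} {f.gene_id} at {f.interval} outside its gene span"
                )


def _gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path, species_id: str) -> FeatureTable:
    """Read GFF3 (1-based inclusive) into internal 0-based half-open features.

    Only the six recognized feature types are retained; other types are ignored
    and their count logged.  The gene id is taken from the ``gene_id`` or
    ``ID`` attribute for genes, and from ``gene_id`` or ``Parent`` for
    sub-features.
    """
    path = Path(path)
    table = FeatureTable(species_id)
    ignored: dict[str, int] = defaultdict(int)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype not in FEATURE_TYPES:
                ignored[ftype] += 1
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: bad coordinates") from exc
            if end1 < start1:
                raise GenomeIOError(f"{path}:{lineno}: end {end1} < start {start1}")
            if strand not in STRANDS:
                raise GenomeIOError(f"{path}:{lineno}: unknown strand {strand!r}")
            a = _gff3_attributes(attrs)
            if ftype in ("gene", "ncRNA"):
                gene_id = a.get("gene_id") or a.get("ID") or f"{ftype}:{lineno}"
            else:
                gene_id = a.get("gene_id") or a.get("Parent") or a.get("ID") or f"{ftype}:{lineno}"
            table.add(Feature(GenomicInterval(chrom, start1 - 1, end1, strand), ftype, gene_id))
    if ignored:
        logger.info(
            "%s: ignored %d features of unrecognized types (%s)",
            path,
            sum(ignored.values()),
            ", ".join(f"{t}:{n}" for t, n in sorted(ignored.items())),
        )
    return table


def write_gff3(table: FeatureTable, path: str | Path) -> None:
    """Write features back to GFF3 (1-based inclusive); round-trips coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table.features:
            iv = f.interval
            attr = f"ID={f.gene_id}" if f.type in ("gene", "ncRNA") else f"Parent={f.gene_id}"
            attr += f";gene_id={f.gene_id}"
            fh.write(
                "\t".join(
                    [iv.chrom, "linecns", f.type, str(iv.start + 1), str(iv.end),
                     ".", iv.strand, ".", attr]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (native 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise GenomeIOError(f"{path}: BED needs >= 3 columns")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if df.shape[1] >= 6 and row[5] in STRANDS else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a methylation-call table: chromosome, 1-based position, strand, context.

    Returns a DataFrame with columns chrom, pos (0-based), strand, context.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "pos", "strand", "context"])
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int) - 1
    if (df["pos"] < 0).any():
        raise GenomeIOError(f"{path}: positions must be 1-based and positive")
    bad = ~df["context"].isin(METHYLATION_CONTEXTS)
    if bad.any():
        raise GenomeIOError(f"{path}: invalid contexts {sorted(df.loc[bad, 'context'].unique())}")
    if (~df["strand"].isin(["+", "-"])).any():
        raise GenomeIOError(f"{path}: strand must be + or -")
    return df


def write_methylation(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out[["chrom", "pos", "strand", "context"]].to_csv(path, sep="\t", header=False, index=False)
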