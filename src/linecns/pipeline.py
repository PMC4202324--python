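"""End-to-end orchestration: load inputs, run the discovery stages in order,
and write a result bundle with a machine-readable summary.

Stage order: organellar filter -> chained common search -> (ncRNA filter,
applied inside the chain) -> lineage-specific filter -> annotation ->
profiles -> phylogeny, each toggleable from the configuration.  Every run
writes the resolved configuration next to its outputs and a MANIFEST noting
which stages completed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import genome_io
from .cns_annotation import classify_location, location_summary, nearest_gene
from .cns_discovery import CnsRecord, chained_common_search, lineage_specific_filter
from .genome_io import FeatureTable, GenomicInterval, SpeciesGenome, read_bed, write_bed
from .homology_search import ScoringScheme, SearchParams, organellar_filter
from .phylogeny import align_cns, bootstrap_support, concatenate
from .sequence_profiles import at_profile

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Resolved run configuration; see ``from_dict`` for the file schema."""

    chain: list[str]
    outgroups: list[str]
    fasta: dict[str, str]
    gff: dict[str, str]
    reference: str | None = None
    lineage_label: str = "custom"
    ncrna_bed: str | None = None
    organellar_fasta: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(
        default_factory=lambda: ["discover", "lineage", "annotate"]
    )
    search: dict[str, Any] = field(default_factory=dict)
    scoring: dict[str, Any] = field(default_factory=dict)
    genome_composition: dict[str, float] = field(
        default_factory=lambda: {"intergenic": 70.0, "intron": 24.2, "UTR": 5.8}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.chain) & set(self.outgroups):
            raise PipelineError("chain and outgroups must be disjoint")
        if self.reference is None:
            self.reference = self.chain[0] if self.chain else None
        if self.reference not in self.chain:
            raise PipelineError("reference must be part of the chain")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        return cls(**dict(raw))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def search_params(self) -> SearchParams:
        return SearchParams(**self.search)

    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(**self.scoring)


def _load_inputs(config: PipelineConfig):
    genomes: dict[str, SpeciesGenome] = {}
    features: dict[str, FeatureTable] = {}
    for sp in config.chain + config.outgroups:
        if sp not in config.fasta:
            raise PipelineError(f"no FASTA configured for species {sp!r}")
        genomes[sp] = genome_io.read_fasta(config.fasta[sp], species_id=sp)
    for sp in config.chain:
        if sp not in config.gff:
            raise PipelineError(f"missing annotation file for species {sp!r}")
        features[sp] = genome_io.read_gff3(config.gff[sp], sp)
    for sp in config.outgroups:
        if sp in config.gff:
            features[sp] = genome_io.read_gff3(config.gff[sp], sp)
    return genomes, features


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages; returns the summary dict (also written to
    ``summary.json``).  On stage failure, partial outputs are kept and the
    MANIFEST records the completion state before the error is re-raised."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)

    completed: list[str] = []
    summary: dict[str, Any] = {"stages": {}, "parameters": asdict(config)}

    def checkpoint(stage: str) -> None:
        completed.append(stage)
        with open(outdir / "MANIFEST", "w") as fh:
            fh.write("completed: " + ", ".join(completed) + "\n")

    params = config.search_params()
    scheme = config.scoring_scheme().calibrated()
    try:
        genomes, features = _load_inputs(config)
        checkpoint("load")

        if config.organellar_fasta:
            for sp, path in config.organellar_fasta.items():
                org = genome_io.read_fasta(path, species_id=f"{sp}_organellar")
                genomes[sp] = organellar_filter(genomes[sp], org, params, scheme)
            checkpoint("organellar_filter")

        ncrna = read_bed(config.ncrna_bed) if config.ncrna_bed else None

        common: list[CnsRecord] = chained_common_search(
            config.chain, genomes, features, params, scheme, ncrna_intervals=ncrna
        )
        summary["stages"]["common"] = {"n": len(common)}
        checkpoint("discover")

        records = common
        if "lineage" in config.stages and config.outgroups:
            records = lineage_specific_filter(
                common,
                genomes[config.reference],
                {og: genomes[og] for og in config.outgroups},
                params,
                scheme,
                lineage_label=config.lineage_label,
            )
            summary["stages"]["lineage_specific"] = {"n": len(records)}
            checkpoint("lineage")

        ref_genome = genomes[config.reference]
        intervals = [r.reference_interval for r in records]
        write_bed(
            intervals,
            outdir / "cns.bed",
            names=[r.cns_id for r in records],
            scores=[r.mean_identity_pct * 10 for r in records],
        )
        with open(outdir / "cns.fasta", "w") as fh:
            for r in records:
                fh.write(f">{r.cns_id}\n{ref_genome.sequence(r.reference_interval)}\n")
        with open(outdir / "cns_support.jsonl", "w") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {
                            "cns_id": r.cns_id,
                            "reference": r.reference_species,
                            "interval": [
                                r.reference_interval.chrom,
                                r.reference_interval.start,
                                r.reference_interval.end,
                            ],
                            "lineage": r.lineage_label,
                            "mean_identity_pct": round(r.mean_identity_pct, 2),
                            "support": {
                                sp: {
                                    "subject": [
                                        a.subject_interval.chrom,
                                        a.subject_interval.start,
                                        a.subject_interval.end,
                                    ],
                                    "strand": a.strand,
                                    "evalue": a.evalue,
                                    "score": a.score,
                                    "identity_pct": round(a.identity_pct, 2),
                                }
                                for sp, a in r.support.items()
                            },
                        }
                    )
                    + "\n"
                )

        if "annotate" in config.stages and records:
            ref_features = features[config.reference]
            counts: dict[str, int] = {}
            rows = []
            for r in records:
                cat = classify_location(r.reference_interval, ref_features)
                counts[cat] = counts.get(cat, 0) + 1
                tgt = nearest_gene(r.reference_interval, ref_features, r.cns_id)
                rows.append(
                    f"{r.cns_id}\t{cat}\t{tgt.gene_id}\t{tgt.relation}\t{tgt.distance}"
                )
            with open(outdir / "cns_targets.tsv", "w") as fh:
                fh.write("cns_id\tlocation\tgene_id\trelation\tdistance\n")
                fh.write("\n".join(rows) + "\n")
            summ = location_summary(counts, config.genome_composition)
            summ.to_frame().to_csv(outdir / "location_summary.tsv", sep="\t", index=False)
            summary["stages"]["annotate"] = {
                "counts": summ.counts,
                "percentages": summ.percentages,
            }
            checkpoint("annotate")

        if "profile" in config.stages and records:
            profile = at_profile(intervals, ref_genome, features[config.reference])
            profile.to_frame().to_csv(outdir / "at_profile.tsv", sep="\t", index=False)
            summary["stages"]["profile"] = {
                "n_cns": profile.n_cns,
                "flank_mean": profile.flank_mean,
                "center_mean": profile.center_mean,
                "t": profile.t,
                "p": profile.p,
            }
            checkpoint("profile")

        if "phylo" in config.stages and len(records) >= 1 and len(config.chain) >= 4:
            alignments = []
            for r in records:
                seqs = {config.reference: ref_genome.sequence(r.reference_interval)}
                for sp, a in r.support.items():
                    seqs[sp] = genomes[sp].sequence(a.subject_interval)
                try:
                    alignments.append(align_cns(seqs, scheme, cns_id=r.cns_id))
                except ValueError:
                    continue
            if alignments:
                concat = concatenate(alignments)
                concat.to_fasta(outdir / "cns_concat.fasta")
                tree, support = bootstrap_support(concat, B=1000, seed=config.seed)
                tree.write(str(outdir / "cns_tree.nwk"))
                summary["stages"]["phylo"] = {
                    "n_alignments": len(alignments),
                    "columns": concat.n_columns,
                    "min_support": min(support.values()) if support else None,
                }
                checkpoint("phylo")
    except Exception as exc:
        summary["error"] = str(exc)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        raise

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
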