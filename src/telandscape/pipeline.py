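"""End-to-end orchestration over one or many species.

Runs the stages census -> logfc -> coreset -> landscape -> overlap ->
tandem -> enrichment -> clustering -> tree, writing one TSV directory
per stage plus a machine-readable JSON run report.  Every stage is a
pure function of (inputs, config, seed); reruns with an identical
config are byte-identical apart from the report timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io_formats, overlap, quant, seqcompare, tandem
from .io_formats import ClassificationTable

logger = logging.getLogger(__name__)

DEFAULT_FOCUS = (
    "L2",
    "Rex-Babar",
    "RTE-BovB",
    "TcMar-Tc1",
    "hAT-Ac",
    "hAT-Charlie",
    "MIR",
    "Helitron",
    "IS3EU",
)

ALL_STAGES = (
    "census",
    "logfc",
    "coreset",
    "landscape",
    "overlap",
    "tandem",
    "enrichment",
    "clustering",
    "tree",
)


@dataclass
class SpeciesInput:
    species_id: str
    repeats: Path
    assembly_size: int
    genes: Path | None = None
    genome: Path | None = None


@dataclass
class RunConfig:
    species: list[SpeciesInput]
    classification: Path | None = None
    outdir: Path = Path("telandscape_out")
    reference_species: str | None = None  # fold-change reference (the expanded genome)
    stages: tuple[str, ...] = ALL_STAGES
    focus_superfamilies: tuple[str, ...] = DEFAULT_FOCUS
    identity_threshold: float = 0.70
    min_fragment_length: int = 1000
    flank: int = 500
    min_region: int = 500
    quantile_q: float = 0.99
    bootstrap_replicates: int = 100
    terms: Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        species = [
            SpeciesInput(
                species_id=entry["species_id"],
                repeats=Path(entry["repeats"]),
                assembly_size=int(entry["assembly_size"]),
                genes=Path(entry["genes"]) if entry.get("genes") else None,
                genome=Path(entry["genome"]) if entry.get("genome") else None,
            )
            for entry in doc["species"]
        ]
        kwargs = {}
        for key in (
            "reference_species",
            "identity_threshold",
            "min_fragment_length",
            "flank",
            "min_region",
            "quantile_q",
            "bootstrap_replicates",
            "seed",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        if "stages" in doc:
            kwargs["stages"] = tuple(doc["stages"])
        if "focus_superfamilies" in doc:
            kwargs["focus_superfamilies"] = tuple(doc["focus_superfamilies"])
        for key in ("classification", "terms", "outdir"):
            if doc.get(key):
                kwargs[key] = Path(doc[key])
        return cls(species=species, **kwargs)

    def validate(self) -> None:
        if not self.species:
            raise ValueError("config lists no species")
        for sp in self.species:
            if not Path(sp.repeats).exists():
                raise FileNotFoundError(f"{sp.species_id}: repeats file {sp.repeats} missing")
            for path in (sp.genes, sp.genome):
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(f"{sp.species_id}: input {path} missing")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report dict.

    Any stage failure aborts with the stage name; outputs of completed
    stages are retained and a FAILED marker file is written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {
            sp.species_id: {
                "repeats": str(sp.repeats),
                "checksum": _checksum(sp.repeats),
                "assembly_size": sp.assembly_size,
            }
            for sp in config.species
        },
        "stages": {},
    }
    classification = (
        ClassificationTable.from_tsv(config.classification) if config.classification else None
    )
    current_stage = "load"
    try:
        fragments = {
            sp.species_id: io_formats.read_repeatmasker_out(
                sp.repeats, sp.species_id, classification
            )
            for sp in config.species
        }
        censuses = {
            sp.species_id: quant.census(fragments[sp.species_id], sp.assembly_size)
            for sp in config.species
        }
        reference = config.reference_species or config.species[0].species_id

        if "census" in config.stages:
            current_stage = "census"
            stage_dir = outdir / "census"
            stage_dir.mkdir(exist_ok=True)
            table = quant.census_table(c for cs in censuses.values() for c in cs)
            table.to_csv(stage_dir / "census.tsv", sep="\t", index=False)
            report["stages"]["census"] = {"rows": len(table)}

        if "logfc" in config.stages and len(config.species) >= 2:
            current_stage = "logfc"
            stage_dir = outdir / "logfc"
            stage_dir.mkdir(exist_ok=True)
            table = quant.logfc_table(censuses, reference)
            table.to_csv(stage_dir / "logfc.tsv", sep="\t", index=False)
            report["stages"]["logfc"] = {"rows": len(table), "reference": reference}

        if "coreset" in config.stages and len(config.species) >= 2:
            current_stage = "coreset"
            stage_dir = outdir / "coreset"
            stage_dir.mkdir(exist_ok=True)
            partition = quant.core_partition(censuses)
            rows = [
                ("+".join(sorted(subset)), len(sfs), ";".join(sorted(sfs)))
                for subset, sfs in sorted(
                    partition.cells.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
                )
            ]
            io_formats.write_table(
                rows, stage_dir / "intersections.tsv", header=("species_subset", "n", "superfamilies")
            )
            report["stages"]["coreset"] = {
                "cells": len(partition.cells),
                "core_size": len(partition.core),
            }

        if "landscape" in config.stages:
            current_stage = "landscape"
            stage_dir = outdir / "landscape"
            stage_dir.mkdir(exist_ok=True)
            histograms = []
            for sp_id, frags in fragments.items():
                by_sf: dict[str, list] = {}
                for frag in frags:
                    if frag.te_order != "Other":
                        by_sf.setdefault(frag.superfamily, []).append(frag)
                for sf, sf_frags in sorted(by_sf.items()):
                    histograms.append(quant.divergence_landscape(sf_frags))
            table = quant.landscape_table(histograms)
            table.to_csv(stage_dir / "landscape.tsv", sep="\t", index=False)
            report["stages"]["landscape"] = {"rows": len(table)}

        overlaps_by_species: dict[str, dict] = {}
        if "overlap" in config.stages:
            current_stage = "overlap"
            stage_dir = outdir / "overlap"
            stage_dir.mkdir(exist_ok=True)
            rows = []
            for sp in config.species:
                if sp.genes is None:
                    continue
                genes = io_formats.read_gff3(sp.genes)
                seq_lengths = (
                    {k: len(v) for k, v in io_formats.read_fasta(sp.genome).items()}
                    if sp.genome
                    else {}
                )
                regions = [
                    overlap.build_subregions(
                        g, seq_lengths.get(g.seq_id, g.end + config.flank), flank=config.flank
                    )
                    for g in genes
                ]
                focus = [
                    sf
                    for sf in config.focus_superfamilies
                    if any(f.superfamily == sf for f in fragments[sp.species_id])
                ]
                sp_summaries = {}
                for sf in focus:
                    te_set = overlap.reduce_fragments(
                        f for f in fragments[sp.species_id] if f.superfamily == sf
                    )
                    summaries = overlap.overlap_summary(te_set, regions, superfamily=sf)
                    sp_summaries[sf] = (te_set, summaries)
                    for rec in summaries:
                        rows.append(
                            (
                                sp.species_id,
                                rec.gene_id,
                                sf,
                                rec.n_te_regions,
                                rec.overlap_bp,
                                round(rec.gene_fraction, 6),
                            )
                        )
                overlaps_by_species[sp.species_id] = {
                    "genes": genes,
                    "regions": regions,
                    "summaries": sp_summaries,
                }
            pd.DataFrame(
                rows,
                columns=["species", "gene_id", "superfamily", "n_te_regions", "overlap_bp", "gene_fraction"],
            ).to_csv(stage_dir / "gene_overlap.tsv", sep="\t", index=False)
            report["stages"]["overlap"] = {"rows": len(rows)}

        tandem_gene_stats: dict[str, dict[str, float]] = {}
        if "tandem" in config.stages:
            current_stage = "tandem"
            stage_dir = outdir / "tandem"
            stage_dir.mkdir(exist_ok=True)
            stat_rows = []
            for sp in config.species:
                if sp.genome is None or sp.species_id not in overlaps_by_species:
                    continue
                genome = io_formats.read_fasta(sp.genome)
                genes = overlaps_by_species[sp.species_id]["genes"]
                gene_ivs = [(g.seq_id, g.start, g.end) for g in genes]
                all_te = overlap.reduce_fragments(fragments[sp.species_id])
                gene_set = overlap.reduce_intervals(gene_ivs)
                # merged TE regions that intersect any gene
                te_gene: list[tuple[str, int, int]] = []
                for seq_id, ivs in all_te.intervals.items():
                    for s, e in ivs:
                        n, bp = overlap._overlap_with(gene_set.on(seq_id), (s, e))
                        if bp > 0:
                            te_gene.append((seq_id, s, e))
                te_gene_set = overlap.reduce_intervals(te_gene) if te_gene else overlap.IntervalSet({})
                stats = tandem.tandem_stats(
                    te_gene_set, genome, species_id=sp.species_id, min_region=config.min_region
                )
                stat_rows.append(
                    (
                        stats.species_id,
                        stats.n_te_regions_overlapping_genes,
                        stats.n_regions_gt_min,
                        stats.n_regions_gt_min_with_tandems,
                        stats.pct_gt_min,
                        stats.pct_with_tandems,
                    )
                )
                # per-gene tandem copy-number totals for enrichment
                per_gene: dict[str, float] = {}
                for seq_id, ivs in te_gene_set.intervals.items():
                    for s, e in ivs:
                        if e - s <= config.min_region:
                            continue
                        arrays = tandem.find_tandems(genome[seq_id][s:e], seq_id=seq_id)
                        if not arrays:
                            continue
                        copy_total = sum(a.copy_number for a in arrays)
                        for g in genes:
                            if g.seq_id == seq_id and min(g.end, e) > max(g.start, s):
                                per_gene[g.gene_id] = per_gene.get(g.gene_id, 0.0) + copy_total
                tandem_gene_stats[sp.species_id] = per_gene
            pd.DataFrame(
                stat_rows,
                columns=[
                    "species",
                    "n_te_regions_overlapping_genes",
                    "n_regions_gt_min",
                    "n_regions_gt_min_with_tandems",
                    "pct_gt_min",
                    "pct_with_tandems",
                ],
            ).to_csv(stage_dir / "tandem_stats.tsv", sep="\t", index=False)
            report["stages"]["tandem"] = {"rows": len(stat_rows)}

        if "enrichment" in config.stages and config.terms is not None and tandem_gene_stats:
            current_stage = "enrichment"
            stage_dir = outdir / "enrichment"
            stage_dir.mkdir(exist_ok=True)
            _, term_rows = io_formats.read_table(config.terms, header=False)
            term_map: dict[str, set[str]] = {}
            for row in term_rows:
                if len(row) >= 2:
                    term_map.setdefault(row[1], set()).add(row[0])
            n_rows = 0
            for sp_id, per_gene in tandem_gene_stats.items():
                if not per_gene:
                    continue
                background = {g.gene_id for g in overlaps_by_species[sp_id]["genes"]}
                unranked = tandem.enrich_unranked(set(per_gene), term_map, background)
                unranked.to_csv(stage_dir / f"{sp_id}_unranked.tsv", sep="\t", index=False)
                ranked = tandem.enrich_ranked(
                    per_gene, term_map, n_permutations=1000, seed=config.seed
                )
                ranked.to_csv(stage_dir / f"{sp_id}_ranked.tsv", sep="\t", index=False)
                n_rows += len(unranked) + len(ranked)
            report["stages"]["enrichment"] = {"rows": n_rows}

        clusters_by_sf: dict[str, list[seqcompare.Cluster]] = {}
        if "clustering" in config.stages:
            current_stage = "clustering"
            stage_dir = outdir / "clustering"
            stage_dir.mkdir(exist_ok=True)
            rows = []
            pool: dict[str, list[tuple[str, str]]] = {}
            for sp in config.species:
                if sp.genome is None:
                    continue
                genome = io_formats.read_fasta(sp.genome)
                for frag in fragments[sp.species_id]:
                    if (
                        frag.superfamily in config.focus_superfamilies
                        and frag.length > config.min_fragment_length
                    ):
                        seq = genome[frag.seq_id][frag.start : frag.end]
                        pool.setdefault(frag.superfamily, []).append(
                            (f"{sp.species_id}|{frag.fragment_id}", seq)
                        )
            for sf, items in sorted(pool.items()):
                clusters = seqcompare.greedy_cluster(
                    items,
                    identity_threshold=config.identity_threshold,
                    min_length=config.min_fragment_length,
                )
                clusters_by_sf[sf] = clusters
                for cluster in clusters:
                    rows.append(
                        (sf, cluster.centroid_id, len(cluster.centroid_seq), cluster.size, ";".join(cluster.members))
                    )
            io_formats.write_table(
                rows,
                stage_dir / "clusters.tsv",
                header=("superfamily", "centroid_id", "centroid_length", "n_members", "members"),
            )
            report["stages"]["clustering"] = {
                "clusters": sum(len(c) for c in clusters_by_sf.values())
            }

        if "tree" in config.stages and clusters_by_sf:
            current_stage = "tree"
            stage_dir = outdir / "tree"
            stage_dir.mkdir(exist_ok=True)
            n_trees = 0
            for sf, clusters in sorted(clusters_by_sf.items()):
                centroids = [(c.centroid_id, sf, c.centroid_seq) for c in clusters]
                kept = seqcompare.coverage_filter(centroids)
                if len(kept) < 3:
                    logger.info("tree: %s has %d centroids after filtering, skipped", sf, len(kept))
                    continue
                seqs = {cid: seq for cid, _, seq in kept}
                reference = max(seqs, key=lambda k: (len(seqs[k]), k))
                labels, columns = seqcompare.star_alignment(seqs, reference)
                matrix = seqcompare._k2p_matrix_from_columns(labels, columns)
                tree = seqcompare.nj_tree(
                    matrix,
                    alignment=(labels, columns),
                    bootstrap_replicates=config.bootstrap_replicates,
                    seed=config.seed,
                )
                io_formats.write_newick(tree, stage_dir / f"{sf}.nwk")
                n_trees += 1
            report["stages"]["tree"] = {"trees": n_trees}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current_stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {current_stage!r}: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
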