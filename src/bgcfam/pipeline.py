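"""End-to-end pipeline: read inputs, call clusters, census, similarity,
families, histograms, boundaries — and write the report bundle.

The pipeline is a pure function of (inputs, config): rerunning with the
same files and configuration produces byte-identical outputs.  A run
manifest echoes every parameter together with a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import call_clusters, census, nrps_pks_ratio, scan_pepm_motif
from .config import DEFAULT_CUTOFFS, MODEL_CLASS_MAP, read_model_table
from .families import (
    conservation_histogram,
    delineate_boundaries,
    group_families,
    write_boundaries_table,
    write_families_table,
)
from .io import (
    attach_proteins,
    newick_leaf_order,
    read_gene_table,
    read_hits,
    read_orthomcl_groups,
    read_protein_fasta,
)
from .model import SM_CLASSES
from .similarity import similarity_matrix, write_heatmap_table


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All knobs of one pipeline run; echoed into the run manifest."""

    input_dir: str
    output_dir: str
    window: int = 6
    join_rule: str = "hit_in_window"
    merge_overlapping_extensions: bool = True
    family_threshold: float = 0.5
    boundary_min_fraction: float = 0.8
    include_plasmids: bool = False
    genus_label: str = ""
    pepm_scan: bool = True
    tree_file: str | None = None
    model_table: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    genomes: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    censuses: list = field(default_factory=list)
    ratio: float | None = None
    matrix: object = None
    families: list = field(default_factory=list)
    histograms: dict = field(default_factory=dict)
    boundaries: list = field(default_factory=list)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage on the files in ``config.input_dir``.

    Expects ``<genome>.genes.tsv`` gene tables (optionally ``<genome>.faa``
    protein FASTA), ``groups.txt`` homolog groups, ``hits.tsv`` signature
    hits and optionally ``models.tsv`` overriding the bundled model/cutoff
    catalogue.  Writes clusters.tsv, census.tsv, similarity.tsv,
    families.tsv, boundaries.tsv and run_manifest.json to
    ``config.output_dir``.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult(config=config)

    # --- read ---------------------------------------------------------
    gene_tables = sorted(indir.glob("*.genes.tsv"))
    if not gene_tables:
        raise PipelineError("read", f"no *.genes.tsv gene tables in {indir}")
    genomes = []
    for path in gene_tables:
        genome = read_gene_table(
            path, format="tsv", include_plasmids=config.include_plasmids
        )
        faa = indir / f"{genome.genome_id}.faa"
        if faa.exists():
            attach_proteins(genome, read_protein_fasta(faa))
        genomes.append(genome)
    result.genomes = genomes

    groups_path = indir / "groups.txt"
    if not groups_path.exists():
        raise PipelineError("read", f"missing homolog groups file {groups_path}")
    hgs = read_orthomcl_groups(groups_path)

    hits_path = indir / "hits.tsv"
    if not hits_path.exists():
        raise PipelineError("read", f"missing hits file {hits_path} (--hits)")
    if config.model_table:
        mcm, cutoffs = read_model_table(config.model_table)
    elif (indir / "models.tsv").exists():
        mcm, cutoffs = read_model_table(indir / "models.tsv")
    else:
        mcm, cutoffs = dict(MODEL_CLASS_MAP), dict(DEFAULT_CUTOFFS)
    try:
        hits = read_hits(
            hits_path, genomes, format="tsv", model_class_map=mcm, cutoffs=cutoffs
        )
    except ValueError as exc:
        raise PipelineError("read", str(exc)) from exc

    # --- motif scan ---------------------------------------------------
    if config.pepm_scan:
        for genome in genomes:
            proteins = {
                g.locus_tag: g.protein_seq for g in genome.genes if g.protein_seq
            }
            pepm_hits = scan_pepm_motif(proteins, genome)
            known = {(h.locus_tag, h.sm_class) for h in hits}
            hits.extend(
                h
                for h in pepm_hits
                if (h.locus_tag, h.sm_class) not in known
            )

    # --- call + census ------------------------------------------------
    clusters = []
    censuses = []
    try:
        for genome in genomes:
            ghits = [
                h for h in hits if h.genome_id == genome.genome_id and h.significant
            ]
            gclusters = call_clusters(
                ghits,
                genome,
                w=config.window,
                join_rule=config.join_rule,
                merge_overlapping_extensions=config.merge_overlapping_extensions,
            )
            clusters.extend(gclusters)
            censuses.append(census(gclusters, genome.genome_id))
    except (ValueError, KeyError) as exc:
        raise PipelineError("call", str(exc)) from exc
    result.clusters = clusters
    result.censuses = censuses
    result.ratio = nrps_pks_ratio(censuses)
    _write_clusters(clusters, genomes, outdir / "clusters.tsv")
    _write_census(censuses, result.ratio, outdir / "census.tsv")

    # --- similarity ---------------------------------------------------
    try:
        matrix = similarity_matrix(hgs, genomes)
        order = (
            newick_leaf_order(config.tree_file) if config.tree_file else None
        )
        write_heatmap_table(matrix, outdir / "similarity.tsv", order=order)
    except (ValueError, KeyError) as exc:
        raise PipelineError("similarity", str(exc)) from exc
    result.matrix = matrix

    # --- families + histograms + boundaries ---------------------------
    try:
        families = group_families(
            clusters,
            hgs,
            threshold=config.family_threshold,
            genus_label=config.genus_label,
        )
        histograms = {
            cls: conservation_histogram(families, cls) for cls in SM_CLASSES
        }
        histograms = {cls: h for cls, h in histograms.items() if h}
        boundaries = [
            delineate_boundaries(
                fam, hgs, min_fraction=config.boundary_min_fraction
            )
            for fam in families
            if fam.size >= 2
        ]
    except (ValueError, KeyError) as exc:
        raise PipelineError("families", str(exc)) from exc
    result.families = families
    result.histograms = histograms
    result.boundaries = boundaries
    write_families_table(families, outdir / "families.tsv")
    write_boundaries_table(boundaries, families, outdir / "boundaries.tsv")
    _write_histograms(histograms, outdir / "histograms.tsv")

    manifest = {
        "package": "bgcfam",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_genomes": len(genomes),
        "n_clusters": len(clusters),
        "n_families": len(families),
        "nrps_pks_ratio": result.ratio,
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return result


def _write_clusters(clusters, genomes, path) -> None:
    by_id = {g.genome_id: g for g in genomes}
    rows = []
    for c in clusters:
        genome = by_id[c.genome_id]
        rep = genome.genes_on(c.replicon_id)
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "genome": c.genome_id,
                "replicon": c.replicon_id,
                "first_index": c.first_index,
                "last_index": c.last_index,
                "first_locus": rep[c.first_index].locus_tag,
                "last_locus": rep[c.last_index].locus_tag,
                "classes": ";".join(sorted(c.class_set)),
                "n_hits": len(c.hits),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "genome",
            "replicon",
            "first_index",
            "last_index",
            "first_locus",
            "last_locus",
            "classes",
            "n_hits",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_census(censuses, ratio, path) -> None:
    rows = []
    for c in censuses:
        row = {"genome": c.genome_id, "clusters": c.n_clusters}
        for cls in SM_CLASSES:
            row[cls] = c.class_counts.get(cls, 0)
        rows.append(row)
    total = {"genome": "TOTAL", "clusters": sum(c.n_clusters for c in censuses)}
    for cls in SM_CLASSES:
        total[cls] = sum(c.class_counts.get(cls, 0) for c in censuses)
    rows.append(total)
    df = pd.DataFrame(rows, columns=["genome", "clusters", *SM_CLASSES])
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(
            f"# nrps_pks_ratio\t{'NA' if ratio is None else format(ratio, '.6g')}\n"
        )


def _write_histograms(histograms, path) -> None:
    rows = [
        {"sm_class": cls, "family_size": size, "n_families": n}
        for cls, hist in sorted(histograms.items())
        for size, n in sorted(hist.items())
    ]
    pd.DataFrame(rows, columns=["sm_class", "family_size", "n_families"]).to_csv(
        path, sep="\t", index=False
    )
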