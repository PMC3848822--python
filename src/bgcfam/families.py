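"""Gene cluster families: content similarity, family grouping, conservation
histograms, and conservation-based boundary delineation.

Two clusters are compared by the homolog groups their genes fall into,
counting shared groups with the same min-copy rule used for whole genomes
and normalising by the size of the smaller cluster, so a compact cluster
wholly contained in a larger one scores 1.0.  Families are the connected
components of the graph whose edges join clusters with similarity at or
above a threshold *and* intersecting class sets (the class condition keeps
unrelated pathways from chaining through shared transport or regulatory
genes).  Within a family, the fraction of other members carrying each
gene's homolog group gives a per-gene conservation profile; trimming each
member to the contiguous conserved run around its signature hits yields
putative cluster boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .model import GeneCluster, HomologGroupSet


@dataclass
class ClusterFamily:
    """A set of clusters grouped by gene-content similarity within a genus.

    ``size`` may exceed ``n_genomes``: a family present twice (or four
    times) in one genome is a single family with multi-copy members.
    """

    family_id: str
    members: list[GeneCluster]
    genus_label: str = ""

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_genomes(self) -> int:
        return len({c.genome_id for c in self.members})

    @property
    def class_set(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.members:
            out |= c.class_set
        return frozenset(out)

    @property
    def member_ids(self) -> list[str]:
        return [c.cluster_id for c in self.members]


@dataclass
class BoundaryCall:
    """Trimmed (conservation-supported) bounds for each member of a family."""

    family_id: str
    trimmed: dict[str, tuple[int, int]]  # cluster_id -> (first, last) gene index
    conservation: dict[str, list[float]] = field(default_factory=dict)
    # cluster_id -> per-gene fraction, aligned with the cluster's index range


def _group_copy_counts(cluster: GeneCluster, hgs: HomologGroupSet) -> Counter:
    """Copies of each homolog group among the cluster's genes."""
    counts: Counter = Counter()
    for locus in cluster.locus_tags:
        group = hgs.group_of(cluster.genome_id, locus)
        if group is not None:
            counts[group] += 1
    return counts


def cluster_content_similarity(
    c1: GeneCluster,
    c2: GeneCluster,
    hgs: HomologGroupSet,
    denominator: str = "min",
) -> float:
    """Homolog-content similarity between two clusters, in [0, 1].

    shared = sum over groups of min(copies in c1, copies in c2);
    similarity = shared / min(n_genes) (default) or shared / |union| for
    ``denominator="jaccard"``.  Genes outside any group count toward sizes
    but can never be shared.
    """
    if not c1.locus_tags or not c2.locus_tags:
        empty = c1.cluster_id if not c1.locus_tags else c2.cluster_id
        raise ValueError(f"cluster {empty} carries no gene list")
    g1 = _group_copy_counts(c1, hgs)
    g2 = _group_copy_counts(c2, hgs)
    shared = sum(min(n, g2[grp]) for grp, n in g1.items() if grp in g2)
    if denominator == "min":
        denom = min(len(c1.locus_tags), len(c2.locus_tags))
    elif denominator == "jaccard":
        denom = len(c1.locus_tags) + len(c2.locus_tags) - shared
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return shared / denom if denom else 0.0


def group_families(
    clusters: Sequence[GeneCluster],
    hgs: HomologGroupSet,
    threshold: float = 0.5,
    genus_label: str = "",
    denominator: str = "min",
) -> list[ClusterFamily]:
    """Partition clusters into families by thresholded content similarity.

    Families are connected components of the graph with an edge wherever
    similarity >= threshold and the class sets intersect.  Every cluster
    lands in exactly one family; clusters similar to nothing become size-1
    families.  Family ids are deterministic: components sorted by their
    smallest member cluster_id are numbered GCF_1, GCF_2, ...
    """
    if not (0 < threshold):
        raise ValueError("threshold must be positive")
    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if not (clusters[i].class_set & clusters[j].class_set):
                continue
            sim = cluster_content_similarity(
                clusters[i], clusters[j], hgs, denominator=denominator
            )
            if sim >= threshold:
                graph.add_edge(i, j)
    components = [
        sorted(comp, key=lambda k: clusters[k].cluster_id)
        for comp in nx.connected_components(graph)
    ]
    components.sort(key=lambda comp: clusters[comp[0]].cluster_id)
    return [
        ClusterFamily(
            family_id=f"GCF_{k}",
            members=[clusters[i] for i in comp],
            genus_label=genus_label,
        )
        for k, comp in enumerate(components, start=1)
    ]


def conservation_histogram(
    families: Sequence[ClusterFamily], sm_class: str
) -> dict[int, int]:
    """Family-size histogram for one class: {family size: number of families}.

    A genus with three unique PKS clusters plus one PKS family of four
    members yields {1: 3, 4: 1}.
    """
    hist: Counter = Counter()
    for fam in families:
        if sm_class in fam.class_set:
            hist[fam.size] += 1
    return dict(sorted(hist.items()))


def delineate_boundaries(
    family: ClusterFamily,
    hgs: HomologGroupSet,
    min_fraction: float = 0.8,
) -> BoundaryCall:
    """Trim each family member to its conserved core.

    Each gene of a member is scored by the fraction of the *other* members
    whose gene content includes its homolog group; the trimmed range is the
    contiguous run of genes with fraction >= min_fraction that contains the
    member's signature hit(s).  Genes outside any homolog group score 0.
    A flanking gene coincidentally shared by all members stays inside the
    trimmed range — conservation, not provenance, is the criterion.

    Families of size 1 are refused: with no second genomic context the
    conservation signal is undefined (a well-conserved region around a
    single cluster yields no boundary).
    """
    if family.size < 2:
        raise ValueError(
            f"family {family.family_id} has a single member; boundaries are "
            f"undefined without a second genomic context"
        )
    if not (0 <= min_fraction <= 1):
        raise ValueError("min_fraction must be in [0, 1]")
    member_groups = [set(_group_copy_counts(c, hgs)) for c in family.members]
    trimmed: dict[str, tuple[int, int]] = {}
    conservation: dict[str, list[float]] = {}
    for m, cluster in enumerate(family.members):
        others = [grp for k, grp in enumerate(member_groups) if k != m]
        fractions = []
        for locus in cluster.locus_tags:
            group = hgs.group_of(cluster.genome_id, locus)
            if group is None:
                fractions.append(0.0)
            else:
                fractions.append(
                    sum(1 for og in others if group in og) / len(others)
                )
        conservation[cluster.cluster_id] = fractions
        # contiguous runs of conserved genes, as (first, last) offsets
        runs: list[tuple[int, int]] = []
        start = None
        for k, frac in enumerate(fractions + [-1.0]):  # sentinel ends last run
            if frac >= min_fraction and start is None:
                start = k
            elif frac < min_fraction and start is not None:
                runs.append((start, k - 1))
                start = None
        hit_offsets = [i - cluster.first_index for i in cluster.hit_indices]
        hit_runs = [
            (a, b) for a, b in runs if any(a <= h <= b for h in hit_offsets)
        ]
        if hit_runs:
            first = min(a for a, _ in hit_runs)
            last = max(b for _, b in hit_runs)
        else:
            # no conserved run reaches a hit; fall back to the hit span
            first, last = min(hit_offsets), max(hit_offsets)
        trimmed[cluster.cluster_id] = (
            cluster.first_index + first,
            cluster.first_index + last,
        )
    return BoundaryCall(
        family_id=family.family_id, trimmed=trimmed, conservation=conservation
    )


def write_families_table(
    families: Sequence[ClusterFamily], path: str | Path
) -> None:
    rows = [
        {
            "family_id": f.family_id,
            "genus": f.genus_label,
            "size": f.size,
            "n_genomes": f.n_genomes,
            "classes": ";".join(sorted(f.class_set)),
            "members": ";".join(f.member_ids),
        }
        for f in families
    ]
    pd.DataFrame(
        rows, columns=["family_id", "genus", "size", "n_genomes", "classes", "members"]
    ).to_csv(path, sep="\t", index=False)


def write_boundaries_table(
    calls: Sequence[BoundaryCall],
    families: Sequence[ClusterFamily],
    path: str | Path,
) -> None:
    by_id = {f.family_id: f for f in families}
    rows = []
    for call in calls:
        fam = by_id[call.family_id]
        members = {c.cluster_id: c for c in fam.members}
        for cluster_id, (first, last) in sorted(call.trimmed.items()):
            c = members[cluster_id]
            rows.append(
                {
                    "family_id": call.family_id,
                    "cluster_id": cluster_id,
                    "trimmed_first_index": first,
                    "trimmed_last_index": last,
                    "trimmed_first_locus": c.locus_tags[first - c.first_index],
                    "trimmed_last_locus": c.locus_tags[last - c.first_index],
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "cluster_id",
            "trimmed_first_index",
            "trimmed_last_index",
            "trimmed_first_locus",
            "trimmed_last_locus",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_grouped_text(
    families: Sequence[ClusterFamily], path: str | Path
) -> None:
    """Grouped-text export: gene ranges comma-separated, groups semicolon-
    separated — one genus's families per file."""
    lines = []
    for f in families:
        ranges = ",".join(
            f"{c.cluster_id}:{c.first_index}-{c.last_index}" for c in f.members
        )
        lines.append(ranges)
    Path(path).write_text(";\n".join(lines) + ("\n" if lines else ""))
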