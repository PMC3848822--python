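"""Core domain types for comparative analysis of biosynthetic gene clusters.

The unit of all positional reasoning is the *gene ordinal*: every
protein-coding gene carries a 0-based index along its replicon, assigned in
ascending order of start coordinate.  Cluster calling, window extension and
boundary trimming all operate on these ordinals; nucleotide coordinates are
carried only for reporting.  Replicons are treated as linear — windows clip
at replicon ends rather than wrapping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

#: The secondary-metabolite classes whose signature enzymes are screened for.
SM_CLASSES: tuple[str, ...] = (
    "PKS1",
    "PKS2",
    "PKS3",
    "NRPS",
    "indolocarbazole",
    "aerobactin_siderophore",
    "butyrolactone",
    "aminoglycoside",
    "beta_lactam",
    "terpene",
    "lanthipeptide",
    "TOMM",
    "phosphonate",
)

#: Classes pooled as "PKS" when forming the NRPS:PKS ratio.
PKS_CLASSES: frozenset[str] = frozenset({"PKS1", "PKS2", "PKS3"})

#: Twenty proteinogenic amino acids (one-letter codes).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneRecord:
    """One protein-coding gene with its ordinal position on a replicon.

    ``gene_index`` is the 0-based rank of the gene among the protein-coding
    genes of its replicon, ascending by start coordinate (ties broken by end
    coordinate, then locus tag).  Coordinates are 1-based inclusive and
    optional.
    """

    genome_id: str
    replicon_id: str
    gene_index: int
    locus_tag: str
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    product: str = ""
    protein_seq: str | None = None
    replicon_type: str = "chromosome"

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise ValueError(f"gene_index must be >= 0, got {self.gene_index}")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end}"
            )


@dataclass
class Genome:
    """An annotated genome: an ordered collection of GeneRecords.

    ``include_plasmids`` records whether plasmid replicons were retained when
    the genome was read (the default analysis drops them).
    """

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    include_plasmids: bool = False

    def __post_init__(self) -> None:
        self._by_locus: dict[str, GeneRecord] = {}
        self._by_replicon: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            if g.locus_tag in self._by_locus:
                raise ValueError(
                    f"duplicate locus_tag {g.locus_tag!r} in genome {self.genome_id}"
                )
            self._by_locus[g.locus_tag] = g
            self._by_replicon.setdefault(g.replicon_id, []).append(g)
        for rep, recs in self._by_replicon.items():
            recs.sort(key=lambda g: g.gene_index)
            indices = [g.gene_index for g in recs]
            if indices != list(range(len(recs))):
                raise ValueError(
                    f"gene_index values on replicon {rep!r} of {self.genome_id} "
                    f"are not a contiguous 0..N-1 run"
                )

    @classmethod
    def from_records(
        cls,
        genome_id: str,
        records: Iterable[GeneRecord],
        include_plasmids: bool = False,
    ) -> "Genome":
        """Sort records, drop plasmids if requested, and assign gene indices.

        Records are ordered by (replicon_id, start, end, locus_tag); the
        gene_index each record arrives with is ignored and reassigned per
        replicon from 0.
        """
        recs = list(records)
        if not include_plasmids:
            recs = [r for r in recs if r.replicon_type != "plasmid"]
        recs.sort(
            key=lambda g: (
                g.replicon_id,
                g.start if g.start is not None else 0,
                g.end if g.end is not None else 0,
                g.locus_tag,
            )
        )
        counters: dict[str, int] = {}
        out = []
        for r in recs:
            idx = counters.get(r.replicon_id, 0)
            counters[r.replicon_id] = idx + 1
            out.append(
                GeneRecord(
                    genome_id=genome_id,
                    replicon_id=r.replicon_id,
                    gene_index=idx,
                    locus_tag=r.locus_tag,
                    start=r.start,
                    end=r.end,
                    strand=r.strand,
                    product=r.product,
                    protein_seq=r.protein_seq,
                    replicon_type=r.replicon_type,
                )
            )
        return cls(genome_id=genome_id, genes=out, include_plasmids=include_plasmids)

    @property
    def G(self) -> int:
        """Number of protein-coding genes on the included replicons."""
        return len(self.genes)

    @property
    def replicons(self) -> list[str]:
        return sorted(self._by_replicon)

    def genes_on(self, replicon_id: str) -> list[GeneRecord]:
        try:
            return self._by_replicon[replicon_id]
        except KeyError:
            raise KeyError(
                f"unknown replicon {replicon_id!r} in genome {self.genome_id}"
            ) from None

    def replicon_size(self, replicon_id: str) -> int:
        return len(self.genes_on(replicon_id))

    def gene(self, locus_tag: str) -> GeneRecord:
        try:
            return self._by_locus[locus_tag]
        except KeyError:
            raise KeyError(
                f"unknown locus_tag {locus_tag!r} in genome {self.genome_id}"
            ) from None

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_locus

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)


class HomologGroupSet:
    """Groups of similar genes across genomes (OrthoMCL-style).

    Each member is a (genome_id, locus_tag) pair; a pair belongs to at most
    one group.  Copy numbers per genome arise from a genome contributing
    several distinct loci to one group.  Singleton genes absent from every
    group are simply unknown to this container.
    """

    def __init__(self, groups: Mapping[str, Iterable[tuple[str, str]]] | None = None):
        self._groups: dict[str, list[tuple[str, str]]] = {}
        self._membership: dict[tuple[str, str], str] = {}
        self._copies: dict[str, Counter] = {}
        self._groups_by_genome: dict[str, set[str]] = {}
        if groups:
            for gid, members in groups.items():
                self.add_group(gid, members)

    def add_group(self, group_id: str, members: Iterable[tuple[str, str]]) -> None:
        if group_id in self._groups:
            raise ValueError(f"duplicate group id {group_id!r}")
        mem = [tuple(m) for m in members]
        if not mem:
            raise ValueError(f"group {group_id!r} has no members")
        for pair in mem:
            if pair in self._membership:
                raise ValueError(
                    f"gene {pair[0]}|{pair[1]} already assigned to group "
                    f"{self._membership[pair]!r}; cannot also join {group_id!r}"
                )
        self._groups[group_id] = mem
        counts: Counter = Counter()
        for genome_id, locus in mem:
            self._membership[(genome_id, locus)] = group_id
            counts[genome_id] += 1
            self._groups_by_genome.setdefault(genome_id, set()).add(group_id)
        self._copies[group_id] = counts

    @property
    def group_ids(self) -> list[str]:
        return list(self._groups)

    @property
    def genomes(self) -> set[str]:
        return set(self._groups_by_genome)

    def members(self, group_id: str) -> list[tuple[str, str]]:
        return list(self._groups[group_id])

    def copies(self, group_id: str, genome_id: str) -> int:
        return self._copies[group_id][genome_id]

    def copy_counts(self, group_id: str) -> Counter:
        return Counter(self._copies[group_id])

    def group_of(self, genome_id: str, locus_tag: str) -> str | None:
        return self._membership.get((genome_id, locus_tag))

    def groups_of_genome(self, genome_id: str) -> set[str]:
        return set(self._groups_by_genome.get(genome_id, set()))

    def __len__(self) -> int:
        return len(self._groups)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self._groups

    def items(self) -> Iterator[tuple[str, list[tuple[str, str]]]]:
        return iter(self._groups.items())


@dataclass
class SignatureHit:
    """A signature-enzyme detection on a gene, labelled with its class.

    Only hits with ``significant=True`` (past the per-model cutoff) enter
    cluster calling.  A gene may carry hits of several classes — this is how
    hybrid clusters arise.
    """

    genome_id: str
    replicon_id: str
    locus_tag: str
    gene_index: int
    sm_class: str
    model_name: str
    score: float
    evalue: float = 0.0
    significant: bool = True
    motif_position: int | None = None  # 1-based; set by the PepM motif screen

    def __post_init__(self) -> None:
        if self.sm_class not in SM_CLASSES:
            raise ValueError(
                f"unknown secondary-metabolite class {self.sm_class!r}; "
                f"expected one of {SM_CLASSES}"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class GeneCluster:
    """A contiguous gene-index range on one replicon called as a cluster.

    Bounds are 0-based inclusive.  ``class_set`` is the union of the classes
    of the significant hits inside the cluster; more than one class makes the
    cluster a hybrid.
    """

    cluster_id: str
    genome_id: str
    replicon_id: str
    first_index: int
    last_index: int
    hits: list[SignatureHit] = field(default_factory=list)
    locus_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.first_index > self.last_index:
            raise ValueError(
                f"cluster {self.cluster_id}: first_index {self.first_index} > "
                f"last_index {self.last_index}"
            )
        if not self.hits:
            raise ValueError(f"cluster {self.cluster_id} has no hits")
        for h in self.hits:
            if not (self.first_index <= h.gene_index <= self.last_index):
                raise ValueError(
                    f"cluster {self.cluster_id}: hit on {h.locus_tag} at index "
                    f"{h.gene_index} outside bounds "
                    f"[{self.first_index}, {self.last_index}]"
                )

    @property
    def class_set(self) -> frozenset[str]:
        return frozenset(h.sm_class for h in self.hits)

    @property
    def n_genes(self) -> int:
        return self.last_index - self.first_index + 1

    @property
    def hit_indices(self) -> list[int]:
        return sorted({h.gene_index for h in self.hits})


@dataclass
class ClassCensus:
    """Per-genome tally of clusters by class.

    A hybrid cluster increments the tally of every class it contains by
    exactly one, so the class counts can sum to more than the cluster count.
    """

    genome_id: str
    class_counts: dict[str, int]
    n_clusters: int

    def count(self, sm_class: str) -> int:
        return self.class_counts.get(sm_class, 0)

    @property
    def pooled_pks(self) -> int:
        return sum(self.class_counts.get(c, 0) for c in PKS_CLASSES)

    @property
    def nrps(self) -> int:
        return self.class_counts.get("NRPS", 0)
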