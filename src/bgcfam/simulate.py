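"""Synthetic genus generator with planted biosynthetic gene clusters.

The generator emulates the statistical structure of a bacterial genus as
seen by the pipeline: a core of single-copy homolog groups shared by every
genome, private accessory genes, and planted cluster families whose member
instances share a dedicated set of homolog groups across genomes (with
multi-copy members allowed).  Signature genes inside each planted block get
synthesised hit scores above the bundled cutoffs; everything is written in
the same file formats the readers consume, alongside a truth manifest that
records the expected clusters, census, family partition, histograms and
precursor loci.  Output is deterministic for a fixed spec and seed.

Planted blocks are separated by background segments longer than twice the
calling window, so each block yields exactly one called cluster and no two
blocks can merge.  Background proteins are random amino-acid strings
longer than the precursor length cap, scrubbed of chance EDK-X(5)-NS
occurrences so the phosphonate motif screen stays silent unless a PepM
gene was planted.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .calling import _find_pepm
from .config import CLASS_MODELS, DEFAULT_CUTOFFS, write_model_table
from .io import (
    write_gene_table,
    write_gff3,
    write_hits,
    write_orthomcl_groups,
    write_protein_fasta,
)
from .model import (
    AMINO_ACIDS,
    GeneRecord,
    Genome,
    HomologGroupSet,
    PKS_CLASSES,
    SM_CLASSES,
    SignatureHit,
)
from .phylo import RIBOSOMAL_PROTEIN_NAMES

#: Background / filler protein length range; the lower bound exceeds the
#: precursor length cap so planted precursors are the only short peptides.
BACKGROUND_PROTEIN_LEN = (130, 400)
SIGNATURE_PROTEIN_LEN = (400, 1400)
PRECURSOR_LEN = 50
MIN_INTER_BLOCK_GAP_FACTOR = 2  # gaps between blocks > factor * window


@dataclass(frozen=True)
class PlantedFamily:
    """One planted cluster family: shared homolog groups across members.

    ``members`` lists genome indices with multiplicity (index 0 appearing
    twice plants two copies in genome 0).  ``sm_classes`` and
    ``hit_offsets`` are parallel: hit k of class sm_classes[k] sits at
    core offset hit_offsets[k].  ``precursor_offsets`` mark short
    Cys/Ser-rich peptides (for lanthipeptide families).
    """

    name: str
    sm_classes: tuple[str, ...]
    members: tuple[int, ...]
    hit_offsets: tuple[int, ...] = (4,)
    core_genes: int = 10
    precursor_offsets: tuple[int, ...] = ()

    def validate(self, n_genomes: int, window: int) -> None:
        if len(self.sm_classes) != len(self.hit_offsets):
            raise ValueError(f"family {self.name}: sm_classes and hit_offsets differ")
        for c in self.sm_classes:
            if c not in SM_CLASSES:
                raise ValueError(f"family {self.name}: unknown class {c!r}")
        offs = sorted(self.hit_offsets)
        for o in offs + list(self.precursor_offsets):
            if not (0 <= o < self.core_genes):
                raise ValueError(f"family {self.name}: offset {o} outside core")
        for a, b in zip(offs, offs[1:]):
            if b - a > window:
                raise ValueError(
                    f"family {self.name}: hit gap {b - a} exceeds window {window}; "
                    f"block would split into two clusters"
                )
        if set(self.precursor_offsets) & set(self.hit_offsets):
            raise ValueError(f"family {self.name}: precursor collides with a hit")
        for m in self.members:
            if not (0 <= m < n_genomes):
                raise ValueError(f"family {self.name}: member genome {m} out of range")

    @property
    def class_set(self) -> frozenset[str]:
        return frozenset(self.sm_classes)


def _default_families() -> tuple[PlantedFamily, ...]:
    """Twelve planted clusters: a PKS1 family of four, three unique PKS1,
    an NRPS pair, a unique NRPS, and two unique NRPS/PKS2 hybrids."""
    return (
        PlantedFamily("FAMPKSA", ("PKS1",), members=(0, 1, 2, 3)),
        PlantedFamily("FAMPKSB", ("PKS1",), members=(0,)),
        PlantedFamily("FAMPKSC", ("PKS1",), members=(1,)),
        PlantedFamily("FAMPKSD", ("PKS1",), members=(4,)),
        PlantedFamily("FAMNRPA", ("NRPS",), members=(0, 1)),
        PlantedFamily("FAMNRPB", ("NRPS",), members=(2,)),
        PlantedFamily("FAMHYBA", ("NRPS", "PKS2"), members=(3,), hit_offsets=(3, 5)),
        PlantedFamily("FAMHYBB", ("NRPS", "PKS2"), members=(4,), hit_offsets=(3, 5)),
    )


@dataclass(frozen=True)
class GenusSpec:
    """Parameters of a synthetic genus.

    The defaults describe the standard test genus: five genomes of roughly
    2,000 genes, 55% core, and twelve planted clusters including two
    NRPS/PKS hybrids.
    """

    genus_label: str = "SYN"
    n_genomes: int = 5
    genes_per_genome: tuple[int, int] = (1900, 2100)
    core_fraction: float = 0.55
    window: int = 6
    planted_families: tuple[PlantedFamily, ...] = field(
        default_factory=_default_families
    )
    neighborhood_randomization: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        lo, hi = self.genes_per_genome
        if not (0 < lo <= hi):
            raise ValueError("genes_per_genome must be a positive (lo, hi) range")
        if not (0 <= self.core_fraction <= 1):
            raise ValueError("core_fraction must be in [0, 1]")
        names = [f.name for f in self.planted_families]
        if len(set(names)) != len(names):
            raise ValueError("planted family names must be unique")
        for fam in self.planted_families:
            fam.validate(self.n_genomes, self.window)


@dataclass
class TruthManifest:
    """Everything the pipeline is expected to recover, by construction."""

    genus_label: str
    window: int
    seed: int
    clusters: dict[str, list[dict]]  # genome_id -> planted clusters in order
    families: dict[str, list[str]]  # family name -> expected member cluster_ids
    census: dict[str, dict[str, int]]  # genome_id -> class -> count
    n_clusters: dict[str, int]
    histograms: dict[str, dict[int, int]]  # class -> family size -> count
    nrps_pks_ratio: float | None
    precursors: dict[str, list[str]]  # cluster_id -> precursor locus tags

    def to_dict(self) -> dict:
        d = asdict(self)
        d["histograms"] = {
            cls: {str(size): n for size, n in hist.items()}
            for cls, hist in self.histograms.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        d = dict(d)
        d["histograms"] = {
            c: {int(size): n for size, n in hist.items()}
            for c, hist in d["histograms"].items()
        }
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SyntheticGenus:
    """In-memory result of :func:`generate_genus` (files via :meth:`emit`)."""

    spec: GenusSpec
    genomes: list[Genome]
    hgs: HomologGroupSet
    hits: list[SignatureHit]
    manifest: TruthManifest

    def emit(self, outdir: str | Path) -> Path:
        """Write gene tables (TSV + GFF3), protein FASTA, groups file, hit
        table, model table and truth manifest into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in self.genomes:
            write_gene_table(genome, outdir / f"{genome.genome_id}.genes.tsv")
            write_gff3(genome, outdir / f"{genome.genome_id}.gff3")
            write_protein_fasta(genome, outdir / f"{genome.genome_id}.faa")
        write_orthomcl_groups(self.hgs, outdir / "groups.txt")
        write_hits(self.hits, outdir / "hits.tsv")
        write_model_table(outdir / "models.tsv")
        self.manifest.save(outdir / "truth.json")
        return outdir


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _scrub_pepm(seq: str) -> str:
    """Mutate chance EDK-X(5)-NS occurrences (E -> Q) out of a sequence."""
    pos = _find_pepm(seq)
    while pos is not None:
        i = pos - 1
        seq = seq[:i] + "Q" + seq[i + 1 :]
        pos = _find_pepm(seq)
    return seq


# Fixed positions of the planted precursor template: an LD motif (leader
# cleavage), two invariant cysteines and an invariant threonine — the
# features a sequence logo over the family should recover.
_PRECURSOR_FIXED = {20: "L", 21: "D", 30: "C", 33: "T", 36: "C"}


def _precursor_template(rng: np.random.Generator) -> str:
    seq = list(_random_protein(rng, PRECURSOR_LEN, PRECURSOR_LEN))
    for pos, res in _PRECURSOR_FIXED.items():
        seq[pos] = res
    # guarantee the Cys/Ser-Thr content filter passes regardless of the
    # random part
    seq[40] = "S"
    return "".join(seq)


def _mutate_precursor(rng: np.random.Generator, template: str, n_mut: int = 3) -> str:
    seq = list(template)
    free = [i for i in range(len(seq)) if i not in _PRECURSOR_FIXED and i != 40]
    for pos in rng.choice(free, size=n_mut, replace=False):
        seq[pos] = AMINO_ACIDS[int(rng.integers(0, len(AMINO_ACIDS)))]
    return "".join(seq)


def generate_genus(spec: GenusSpec) -> SyntheticGenus:
    """Generate a synthetic genus per ``spec``; deterministic for its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.genes_per_genome
    n_core = int(spec.core_fraction * (lo + hi) / 2)
    min_gap = MIN_INTER_BLOCK_GAP_FACTOR * spec.window + 2
    genome_ids = [f"{spec.genus_label}{i + 1:02d}" for i in range(spec.n_genomes)]
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_genomes)]

    # per-family precursor templates, drawn up-front for determinism
    templates = {
        fam.name: _precursor_template(rng)
        for fam in spec.planted_families
        if fam.precursor_offsets
    }

    # instances per genome, in family order, then copies
    instances: dict[int, list[tuple[PlantedFamily, int]]] = {
        i: [] for i in range(spec.n_genomes)
    }
    for fam in spec.planted_families:
        copy_counter: Counter = Counter()
        for m in fam.members:
            instances[m].append((fam, copy_counter[m]))
            copy_counter[m] += 1

    group_members: dict[str, list[tuple[str, str]]] = {}
    genomes: list[Genome] = []
    all_hits: list[SignatureHit] = []
    manifest_clusters: dict[str, list[dict]] = {}
    precursor_loci: dict[str, list[str]] = {}

    ribo_products = {}
    for k, name in enumerate(RIBOSOMAL_PROTEIN_NAMES):
        subunit = "50S" if name.startswith("L") else "30S"
        ribo_products[k] = f"{subunit} ribosomal protein {name}"

    for i, gid in enumerate(genome_ids):
        blocks = list(instances[i])
        planted_total = sum(fam.core_genes for fam, _ in blocks)
        background_n = sizes[i] - planted_total
        needed = max(n_core, (len(blocks) + 1) * min_gap)
        if background_n < needed:
            raise ValueError(
                f"genome {gid}: {sizes[i]} genes cannot host {len(blocks)} "
                f"planted blocks of {planted_total} genes with the required "
                f"background (need >= {needed + planted_total})"
            )
        # background content: every core group once, remainder accessory
        bg_items: list[tuple[str, int]] = [("core", k) for k in range(n_core)]
        bg_items += [("acc", j) for j in range(background_n - n_core)]
        if spec.neighborhood_randomization:
            order = rng.permutation(len(bg_items))
            bg_items = [bg_items[t] for t in order]
        # background segment sizes around the blocks, each >= min_gap
        n_seg = len(blocks) + 1
        extra = background_n - n_seg * min_gap
        seg_sizes = (min_gap + rng.multinomial(extra, np.full(n_seg, 1 / n_seg))).tolist()
        block_order = [blocks[t] for t in rng.permutation(len(blocks))] if blocks else []

        records: list[GeneRecord] = []
        genome_hits: list[SignatureHit] = []
        planted_info: list[dict] = []
        bg_iter = iter(bg_items)
        pos = 0
        nt = 1

        def add_gene(group: str | None, product: str, seq: str) -> str:
            nonlocal pos, nt
            locus = f"{gid}_{pos + 1:05d}"
            start = nt + int(rng.integers(20, 201))
            end = start + 3 * len(seq) + 2
            nt = end
            strand = "+" if rng.integers(0, 2) else "-"
            records.append(
                GeneRecord(
                    genome_id=gid,
                    replicon_id="chr1",
                    gene_index=pos,
                    locus_tag=locus,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                    protein_seq=seq,
                )
            )
            if group is not None:
                group_members.setdefault(group, []).append((gid, locus))
            pos += 1
            return locus

        def add_background() -> None:
            kind, idx = next(bg_iter)
            seq = _scrub_pepm(_random_protein(rng, *BACKGROUND_PROTEIN_LEN))
            if kind == "core":
                product = ribo_products.get(idx, "conserved hypothetical protein")
                add_gene(f"CORE{idx + 1:05d}", product, seq)
            else:
                add_gene(None, "hypothetical protein", seq)

        for b in range(n_seg):
            for _ in range(seg_sizes[b]):
                add_background()
            if b >= len(block_order):
                continue
            fam, copy_idx = block_order[b]
            block_start = pos
            hit_by_offset = dict(zip(fam.hit_offsets, fam.sm_classes))
            prec_offsets = set(fam.precursor_offsets)
            block_hit_indices: list[int] = []
            block_precursors: list[str] = []
            for j in range(fam.core_genes):
                group = f"{fam.name}G{j + 1:02d}"
                if j in hit_by_offset:
                    sm_class = hit_by_offset[j]
                    model = CLASS_MODELS[sm_class]
                    if sm_class == "phosphonate":
                        # a genuine PepM gene carries the motif
                        seq = _random_protein(rng, *SIGNATURE_PROTEIN_LEN)
                        seq = _scrub_pepm(seq)
                        ins = int(rng.integers(10, 40))
                        spacer = _random_protein(rng, 5, 5)
                        seq = seq[:ins] + "EDK" + spacer + "NS" + seq[ins:]
                    else:
                        seq = _scrub_pepm(
                            _random_protein(rng, *SIGNATURE_PROTEIN_LEN)
                        )
                    locus = add_gene(group, f"{sm_class} signature enzyme", seq)
                    score = round(
                        DEFAULT_CUTOFFS[model] + float(rng.uniform(20, 150)), 1
                    )
                    evalue = float(10.0 ** -rng.uniform(15, 60))
                    genome_hits.append(
                        SignatureHit(
                            genome_id=gid,
                            replicon_id="chr1",
                            locus_tag=locus,
                            gene_index=block_start + j,
                            sm_class=sm_class,
                            model_name=model,
                            score=score,
                            evalue=evalue,
                            significant=True,
                        )
                    )
                    block_hit_indices.append(block_start + j)
                elif j in prec_offsets:
                    seq = _scrub_pepm(
                        _mutate_precursor(rng, templates[fam.name])
                    )
                    locus = add_gene(group, "putative precursor peptide", seq)
                    block_precursors.append(locus)
                else:
                    seq = _scrub_pepm(_random_protein(rng, *BACKGROUND_PROTEIN_LEN))
                    add_gene(group, "cluster-associated protein", seq)
            planted_info.append(
                {
                    "family": fam.name,
                    "copy": copy_idx,
                    "core_first": block_start,
                    "core_last": block_start + fam.core_genes - 1,
                    "hit_indices": block_hit_indices,
                    "classes": sorted(set(fam.sm_classes)),
                    "precursor_loci": block_precursors,
                }
            )
        # finish any remaining background (multinomial consumed all, but be safe)
        for _ in range(background_n - sum(seg_sizes)):
            add_background()

        n_genes = pos
        for k, info in enumerate(planted_info, start=1):
            info["cluster_id"] = f"{gid}_{k}"
            hit_min, hit_max = min(info["hit_indices"]), max(info["hit_indices"])
            info["first_index"] = max(0, hit_min - spec.window)
            info["last_index"] = min(n_genes - 1, hit_max + spec.window)
            if info["precursor_loci"]:
                precursor_loci[info["cluster_id"]] = info["precursor_loci"]
        manifest_clusters[gid] = planted_info
        genomes.append(Genome.from_records(gid, records))
        all_hits.extend(genome_hits)

    hgs = HomologGroupSet()
    for group_id in sorted(group_members):
        hgs.add_group(group_id, group_members[group_id])

    # expected family partition, census, histograms
    fam_members: dict[str, list[str]] = {}
    for gid in genome_ids:
        for info in manifest_clusters[gid]:
            fam_members.setdefault(info["family"], []).append(info["cluster_id"])
    families = {name: sorted(ids) for name, ids in sorted(fam_members.items())}

    census: dict[str, dict[str, int]] = {}
    n_clusters: dict[str, int] = {}
    for gid in genome_ids:
        counts: Counter = Counter()
        for info in manifest_clusters[gid]:
            for cls in info["classes"]:
                counts[cls] += 1
        census[gid] = dict(sorted(counts.items()))
        n_clusters[gid] = len(manifest_clusters[gid])

    fam_classes = {f.name: f.class_set for f in spec.planted_families}
    histograms: dict[str, dict[int, int]] = {}
    for cls in SM_CLASSES:
        hist: Counter = Counter()
        for name, ids in families.items():
            if cls in fam_classes[name]:
                hist[len(ids)] += 1
        if hist:
            histograms[cls] = dict(sorted(hist.items()))

    total_nrps = sum(c.get("NRPS", 0) for c in census.values())
    total_pks = sum(
        c.get(p, 0) for c in census.values() for p in PKS_CLASSES
    )
    ratio = (total_nrps / total_pks) if total_pks else None

    manifest = TruthManifest(
        genus_label=spec.genus_label,
        window=spec.window,
        seed=spec.seed,
        clusters=manifest_clusters,
        families=families,
        census=census,
        n_clusters=n_clusters,
        histograms=histograms,
        nrps_pks_ratio=ratio,
        precursors=precursor_loci,
    )
    return SyntheticGenus(
        spec=spec, genomes=genomes, hgs=hgs, hits=all_hits, manifest=manifest
    )


# ---------------------------------------------------------------------------
# Presets emulating the qualitative genus patterns of the study
# ---------------------------------------------------------------------------


def default_spec(seed: int = 0) -> GenusSpec:
    """The standard five-genome genus with twelve planted clusters."""
    return GenusSpec(seed=seed)


def rhodococcus_like_spec(seed: int = 0) -> GenusSpec:
    """NRPS-heavy genus: 14 unique NRPS vs 5 PKS clusters (ratio 2.8),
    no conserved NRPS families."""
    nrps_members = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 3, 3, 3]
    fams = [
        PlantedFamily(f"RNRP{k:02d}", ("NRPS",), members=(m,))
        for k, m in enumerate(nrps_members, start=1)
    ]
    fams += [
        PlantedFamily("RPKSA", ("PKS1",), members=(0,)),
        PlantedFamily("RPKSB", ("PKS1",), members=(1,)),
        PlantedFamily("RPKSC", ("PKS1",), members=(2,)),
        PlantedFamily("RPKSD", ("PKS2",), members=(2,)),
        PlantedFamily("RPKSE", ("PKS2",), members=(3,)),
    ]
    return GenusSpec(
        genus_label="RHO",
        n_genomes=4,
        genes_per_genome=(1200, 1400),
        core_fraction=0.5,
        planted_families=tuple(fams),
        seed=seed,
    )


def overall_like_spec(seed: int = 0) -> GenusSpec:
    """A genome set with 9 NRPS vs 20 PKS clusters (pooled ratio 0.45)."""
    fams = [
        PlantedFamily(f"ONRP{k}", ("NRPS",), members=(m,))
        for k, m in enumerate([0, 0, 1, 1, 2, 2, 3, 3, 4], start=1)
    ]
    fams.append(PlantedFamily("OPKSHARED", ("PKS1",), members=(0, 1, 2, 3)))
    fams += [
        PlantedFamily(f"OPK1U{k}", ("PKS1",), members=(m,))
        for k, m in enumerate([0, 0, 1, 1, 2, 3, 4, 4], start=1)
    ]
    fams += [
        PlantedFamily(f"OPK2U{k}", ("PKS2",), members=(m,))
        for k, m in enumerate([0, 1, 2, 3, 4], start=1)
    ]
    fams += [
        PlantedFamily(f"OPK3U{k}", ("PKS3",), members=(m,))
        for k, m in enumerate([2, 3, 4], start=1)
    ]
    return GenusSpec(
        genus_label="ALL",
        n_genomes=5,
        genes_per_genome=(1500, 1700),
        core_fraction=0.5,
        planted_families=tuple(fams),
        seed=seed,
    )


def frankia_like_spec(seed: int = 0) -> GenusSpec:
    """One lanthipeptide family at copy number 2 or 4 per genome (absent
    from the last genome), twelve clusters and twelve precursors in all."""
    fams = (
        PlantedFamily(
            "FLAN",
            ("lanthipeptide",),
            members=(0, 0, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3),
            hit_offsets=(4,),
            precursor_offsets=(7,),
        ),
        PlantedFamily("FPKS", ("PKS1",), members=(4,)),
    )
    return GenusSpec(
        genus_label="FRK",
        n_genomes=5,
        genes_per_genome=(1500, 1700),
        core_fraction=0.5,
        planted_families=fams,
        seed=seed,
    )


def corynebacterium_like_spec(seed: int = 0) -> GenusSpec:
    """Few clusters; one conserved NRPS-independent siderophore family."""
    fams = (
        PlantedFamily("CSID", ("aerobactin_siderophore",), members=(0, 1, 2)),
        PlantedFamily("CTER", ("terpene",), members=(3,)),
    )
    return GenusSpec(
        genus_label="COR",
        n_genomes=5,
        genes_per_genome=(1000, 1200),
        core_fraction=0.6,
        planted_families=fams,
        seed=seed,
    )
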