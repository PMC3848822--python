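"""Supermatrix preparation for the ribosomal-protein phylogeny.

Tree inference itself (alignment, maximum likelihood, networks) is left to
external tools; this module selects the homolog groups usable for a
species phylogeny — ribosomal-protein groups with exactly one member in
every genome — and concatenates per-gene alignments into one supermatrix
per genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .model import HomologGroupSet

#: The 41 ribosomal proteins used for the concatenated species phylogeny.
RIBOSOMAL_PROTEIN_NAMES: tuple[str, ...] = (
    "L1", "L2", "L3", "L4", "L5", "L6", "L7/L12", "L9", "L10", "L11",
    "L13", "L14", "L15", "L16", "L17", "L18", "L19", "L20", "L21", "L22",
    "L23", "L24", "L25p", "L27", "L29", "L35",
    "S1", "S3", "S5", "S6", "S7", "S8", "S9", "S10", "S11", "S12", "S13",
    "S15", "S17", "S19", "S20",
)


def _default_patterns(names: Sequence[str]) -> list[re.Pattern]:
    patterns = []
    for name in names:
        variants = {name}
        if name.endswith("p"):
            variants.add(name[:-1])
        if "/" in name:
            variants.update(name.split("/"))
        for v in variants:
            patterns.append(
                re.compile(
                    rf"ribosomal\s+protein\s+{re.escape(v)}(?![0-9A-Za-z])",
                    re.IGNORECASE,
                )
            )
    return patterns


def select_single_copy_groups(
    hgs: HomologGroupSet,
    reference_annotations: Mapping[str, str],
    name_patterns: Sequence[str | re.Pattern] | None = None,
    genomes: Sequence[str] | None = None,
) -> list[str]:
    """Groups usable for the species phylogeny.

    A group qualifies when (a) it contains a reference-genome gene whose
    product annotation matches a ribosomal-protein pattern, and (b) it has
    exactly one member in every genome.  ``reference_annotations`` maps the
    reference genome's locus tags to product strings; ``genomes`` defaults
    to every genome seen in the group set.  The bundled 41-protein list is
    the default pattern source.
    """
    if name_patterns is None:
        patterns = _default_patterns(RIBOSOMAL_PROTEIN_NAMES)
    else:
        patterns = [
            p if isinstance(p, re.Pattern) else re.compile(p, re.IGNORECASE)
            for p in name_patterns
        ]
    genome_list = sorted(hgs.genomes) if genomes is None else list(genomes)
    selected = []
    for group_id, members in hgs.items():
        products = [
            reference_annotations[locus]
            for _, locus in members
            if locus in reference_annotations
        ]
        if not any(p.search(prod) for prod in products for p in patterns):
            continue
        counts = hgs.copy_counts(group_id)
        if all(counts.get(g, 0) == 1 for g in genome_list) and sum(
            counts.values()
        ) == len(genome_list):
            selected.append(group_id)
    if not selected:
        raise ValueError(
            "no single-copy ribosomal-protein groups found; relax the "
            "name patterns or check the reference annotations"
        )
    return sorted(selected)


@dataclass
class ConcatenationReport:
    """Per-genome concatenated alignment over a fixed, sorted gene order."""

    group_ids: list[str]
    gene_lengths: dict[str, int]
    sequences: dict[str, str]  # genome_id -> concatenated sequence

    @property
    def total_length(self) -> int:
        return sum(self.gene_lengths.values())


def concatenate(
    per_gene_alignments: Mapping[str, Mapping[str, str]],
) -> ConcatenationReport:
    """Concatenate per-gene alignments into one supermatrix per genome.

    ``per_gene_alignments`` maps group_id to {genome_id: aligned sequence}.
    Every alignment must cover the same genome set with equal lengths
    within a gene; gene order in the output is canonical (sorted group_id),
    so shuffled input order changes nothing.
    """
    if not per_gene_alignments:
        raise ValueError("no alignments supplied")
    group_ids = sorted(per_gene_alignments)
    genome_set = set(per_gene_alignments[group_ids[0]])
    gene_lengths: dict[str, int] = {}
    for gid in group_ids:
        aln = per_gene_alignments[gid]
        if set(aln) != genome_set:
            missing = genome_set ^ set(aln)
            raise ValueError(
                f"alignment {gid!r} does not cover the same genomes; "
                f"mismatch: {sorted(missing)}"
            )
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment {gid!r} is ragged: lengths {sorted(lengths)}")
        gene_lengths[gid] = lengths.pop()
    sequences = {
        genome: "".join(per_gene_alignments[gid][genome] for gid in group_ids)
        for genome in sorted(genome_set)
    }
    return ConcatenationReport(
        group_ids=group_ids, gene_lengths=gene_lengths, sequences=sequences
    )


def write_concatenation_fasta(report: ConcatenationReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        for genome, seq in report.sequences.items():
            fh.write(f">{genome}\n{seq}\n")


def write_concatenation_phylip(report: ConcatenationReport, path: str | Path) -> None:
    """Relaxed PHYLIP (names of any length, space-separated)."""
    with open(path, "w") as fh:
        fh.write(f"{len(report.sequences)} {report.total_length}\n")
        for genome, seq in report.sequences.items():
            fh.write(f"{genome}  {seq}\n")
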