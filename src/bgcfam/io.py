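"""Readers and writers for the pipeline's external formats.

Gene tables come in as GFF3 (CDS features) or a simple TSV; homolog groups
in the OrthoMCL one-group-per-line text format; signature-enzyme hits as
HMMER3 ``--domtblout`` tables or a simplified TSV.  Protein sequences are
plain FASTA with headers equal to locus tags.  Newick trees are read only to
extract a display leaf order.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Phylo, SearchIO, SeqIO

from .model import GeneRecord, Genome, HomologGroupSet, SignatureHit, SM_CLASSES


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


GENE_TABLE_COLUMNS = [
    "genome_id",
    "replicon_id",
    "locus_tag",
    "start",
    "end",
    "strand",
    "product",
    "replicon_type",
]


def read_gene_table(
    path: str | Path,
    format: str = "tsv",
    include_plasmids: bool = False,
    genome_id: str | None = None,
) -> Genome:
    """Read a gene table and return a :class:`Genome` with ordinal indices.

    TSV columns: genome_id, replicon_id, locus_tag, start, end, strand,
    product and optionally replicon_type (defaults to ``chromosome``).
    GFF3 input uses rows of type CDS with a ``locus_tag`` attribute; the
    replicon is the seqid column and an optional ``replicon_type`` attribute
    marks plasmids.  Unsorted input is sorted, never an error; duplicate
    locus tags are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene table not found: {path}")
    if format == "tsv":
        records, gid = _gene_records_from_tsv(path)
    elif format == "gff3":
        if genome_id is None:
            genome_id = path.stem.split(".")[0]
        records, gid = _gene_records_from_gff3(path, genome_id)
    else:
        raise ValueError(f"unknown gene-table format {format!r}")
    if genome_id is not None:
        gid = genome_id
    return Genome.from_records(gid, records, include_plasmids=include_plasmids)


def _gene_records_from_tsv(path: Path) -> tuple[list[GeneRecord], str]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], path.stem.split(".")[0]
    if df.empty:
        return [], path.stem.split(".")[0]
    missing = [c for c in GENE_TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: gene table missing columns {missing}")
    dup = df["locus_tag"][df["locus_tag"].duplicated()]
    if not dup.empty:
        raise ParseError(
            f"{path}: duplicate locus_tag(s): {sorted(set(dup))}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneRecord(
                genome_id=row.genome_id,
                replicon_id=row.replicon_id,
                gene_index=0,
                locus_tag=row.locus_tag,
                start=int(row.start) if row.start != "" else None,
                end=int(row.end) if row.end != "" else None,
                strand=row.strand or None,
                product=getattr(row, "product", "") or "",
                replicon_type=getattr(row, "replicon_type", "") or "chromosome",
            )
        )
    genome_ids = {r.genome_id for r in records}
    if len(genome_ids) != 1:
        raise ParseError(
            f"{path}: gene table mixes genome_ids {sorted(genome_ids)}"
        )
    return records, records[0].genome_id


def _gene_records_from_gff3(path: Path, genome_id: str) -> tuple[list[GeneRecord], str]:
    import gffutils

    text = path.read_text()
    if not text.strip():
        return [], genome_id
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    records = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        tags = feat.attributes.get("locus_tag") or feat.attributes.get("ID")
        if not tags:
            raise ParseError(f"{path}: CDS at {feat.seqid}:{feat.start} lacks a locus_tag")
        locus = tags[0]
        if locus in seen:
            raise ParseError(f"{path}: duplicate locus_tag {locus!r}")
        seen.add(locus)
        rtype = (feat.attributes.get("replicon_type") or ["chromosome"])[0]
        product = (feat.attributes.get("product") or [""])[0]
        records.append(
            GeneRecord(
                genome_id=genome_id,
                replicon_id=feat.seqid,
                gene_index=0,
                locus_tag=locus,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else None,
                product=product,
                replicon_type=rtype,
            )
        )
    return records, genome_id


def write_gene_table(genome: Genome, path: str | Path) -> None:
    """Write a genome back out as the TSV gene-table dialect."""
    rows = [
        {
            "genome_id": g.genome_id,
            "replicon_id": g.replicon_id,
            "locus_tag": g.locus_tag,
            "start": "" if g.start is None else g.start,
            "end": "" if g.end is None else g.end,
            "strand": g.strand or "",
            "product": g.product,
            "replicon_type": g.replicon_type,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_gff3(genome: Genome, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genome.genes:
        attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
        if g.product:
            attrs += f";product={g.product}"
        attrs += f";replicon_type={g.replicon_type}"
        lines.append(
            "\t".join(
                [
                    g.replicon_id,
                    "bgcfam",
                    "CDS",
                    str(g.start if g.start is not None else 1),
                    str(g.end if g.end is not None else 1),
                    ".",
                    g.strand or ".",
                    "0",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_orthomcl_groups(
    path: str | Path, taxon_map: Mapping[str, str] | None = None
) -> HomologGroupSet:
    """Parse an OrthoMCL-style groups file.

    Each line reads ``GROUPID: taxon|gene taxon|gene ...``.  ``taxon_map``
    translates taxon codes to genome ids; by default the taxon code is used
    as the genome id.  A gene appearing in two groups is an error.
    """
    path = Path(path)
    hgs = HomologGroupSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'GROUPID: members', no colon")
            group_id, _, rest = line.partition(":")
            group_id = group_id.strip()
            members = []
            for token in rest.split():
                if "|" not in token:
                    raise ParseError(
                        f"{path}:{lineno}: member {token!r} is not of form taxon|gene"
                    )
                taxon, _, gene = token.partition("|")
                genome_id = taxon_map.get(taxon, taxon) if taxon_map else taxon
                members.append((genome_id, gene))
            try:
                hgs.add_group(group_id, members)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hgs


def write_orthomcl_groups(hgs: HomologGroupSet, path: str | Path) -> None:
    lines = []
    for group_id, members in hgs.items():
        toks = " ".join(f"{genome}|{locus}" for genome, locus in members)
        lines.append(f"{group_id}: {toks}")
    Path(path).write_text("\n".join(lines) + "\n")


HIT_TABLE_COLUMNS = [
    "genome_id",
    "replicon_id",
    "locus_tag",
    "gene_index",
    "sm_class",
    "model_name",
    "score",
    "evalue",
    "significant",
]


def _resolve_cutoff(cutoffs, model: str) -> tuple[float | None, float | None]:
    """Return (min_score, max_evalue) for a model from the cutoff table."""
    if cutoffs is None:
        return None, None
    entry = cutoffs.get(model)
    if entry is None:
        return None, None
    if isinstance(entry, Mapping):
        return entry.get("score"), entry.get("evalue")
    return float(entry), None


def read_hits(
    path: str | Path,
    genomes: Sequence[Genome],
    format: str = "tsv",
    model_class_map: Mapping[str, str] | None = None,
    cutoffs: Mapping[str, object] | None = None,
) -> list[SignatureHit]:
    """Read a signature-hit table and join it to gene records by locus tag.

    ``model_class_map`` assigns every model name one of the 13 classes;
    ``cutoffs`` gives per-model bit-score thresholds (a float) or
    ``{"score": s, "evalue": e}`` entries.  Hits are kept regardless of
    significance; only the flag changes.  Hits on locus tags unknown to any
    supplied genome are an error.
    """
    path = Path(path)
    locus_index: dict[str, GeneRecord] = {}
    for genome in genomes:
        for g in genome.genes:
            locus_index[g.locus_tag] = g
    if format == "tsv":
        raw = _raw_hits_from_tsv(path)
    elif format == "domtblout":
        raw = _raw_hits_from_domtblout(path)
    else:
        raise ValueError(f"unknown hit-table format {format!r}")

    unknown = sorted({locus for locus, *_ in raw if locus not in locus_index})
    if unknown:
        raise ParseError(f"{path}: hits on unknown locus_tags: {unknown}")

    hits = []
    for locus, model, score, evalue in raw:
        if model_class_map is None or model not in model_class_map:
            raise ParseError(
                f"{path}: model {model!r} missing from model_class_map"
            )
        sm_class = model_class_map[model]
        if sm_class not in SM_CLASSES:
            raise ParseError(f"{path}: model {model!r} maps to unknown class {sm_class!r}")
        min_score, max_evalue = _resolve_cutoff(cutoffs, model)
        significant = True
        if min_score is not None:
            significant = significant and score >= min_score
        if max_evalue is not None:
            significant = significant and evalue <= max_evalue
        rec = locus_index[locus]
        hits.append(
            SignatureHit(
                genome_id=rec.genome_id,
                replicon_id=rec.replicon_id,
                locus_tag=locus,
                gene_index=rec.gene_index,
                sm_class=sm_class,
                model_name=model,
                score=score,
                evalue=evalue,
                significant=significant,
            )
        )
    return hits


def _raw_hits_from_tsv(path: Path) -> list[tuple[str, str, float, float]]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    for col in ("locus_tag", "model_name", "score"):
        if col not in df.columns:
            raise ParseError(f"{path}: hit table missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        evalue = float(row.evalue) if getattr(row, "evalue", "") != "" else 0.0
        out.append((row.locus_tag, row.model_name, float(row.score), evalue))
    return out


def _raw_hits_from_domtblout(path: Path) -> list[tuple[str, str, float, float]]:
    # HMMER3 --domtblout: target = protein (locus tag), query = model.
    out = []
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        model = qresult.id
        for hit in qresult.hits:
            score = float(hit.bitscore)
            evalue = float(hit.evalue)
            if math.isnan(evalue):
                evalue = 0.0
            out.append((hit.id, model, score, evalue))
    return out


def write_hits(hits: Iterable[SignatureHit], path: str | Path) -> None:
    rows = [
        {
            "genome_id": h.genome_id,
            "replicon_id": h.replicon_id,
            "locus_tag": h.locus_tag,
            "gene_index": h.gene_index,
            "sm_class": h.sm_class,
            "model_name": h.model_name,
            "score": f"{h.score:.1f}",
            "evalue": f"{h.evalue:.3g}",
            "significant": str(h.significant),
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """FASTA with headers equal to locus tags → {locus_tag: sequence}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def attach_proteins(genome: Genome, seqs: Mapping[str, str]) -> int:
    """Attach protein sequences to a genome's gene records; returns how many."""
    n = 0
    for g in genome.genes:
        if g.locus_tag in seqs:
            g.protein_seq = seqs[g.locus_tag]
            n += 1
    return n


def write_protein_fasta(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            if g.protein_seq:
                fh.write(f">{g.locus_tag}\n{g.protein_seq}\n")


def newick_leaf_order(path_or_text: str | Path) -> list[str]:
    """Leaf names of a newick tree in display order (left-to-right)."""
    text = None
    p = Path(str(path_or_text))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_text)
    tree = Phylo.read(_io.StringIO(text), "newick")
    return [leaf.name for leaf in tree.get_terminals()]
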