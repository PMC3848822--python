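"""Gene-cluster calling by the six-gene window rule, class censuses, and
auxiliary screens (PepM motif, fatty-acid-synthase conflict resolution).

A cluster starts at a significant signature hit and extends six genes (the
default window ``w``) to either side; further hits within the window join
the same cluster and restart the count, and the final bounds run from the
first hit minus ``w`` to the last hit plus ``w``, clipped at the replicon
ends.  Chains whose extensions overlap are merged so that the clusters on a
replicon are pairwise disjoint single loci.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .model import (
    AMINO_ACIDS,
    ClassCensus,
    GeneCluster,
    Genome,
    PKS_CLASSES,
    SignatureHit,
)

JOIN_RULES = ("hit_in_window", "extensions_overlap")


def call_clusters(
    hits: Sequence[SignatureHit],
    genome: Genome,
    w: int = 6,
    join_rule: str = "hit_in_window",
    merge_overlapping_extensions: bool = True,
    cluster_prefix: str | None = None,
) -> list[GeneCluster]:
    """Call gene clusters from significant signature hits on one genome.

    ``join_rule`` controls when a subsequent hit joins the running chain:
    ``hit_in_window`` requires an index gap <= w to the previous hit (the
    literal reading of the window rule); ``extensions_overlap`` joins when
    the two hits' +/-w extensions touch (gap <= 2w).  With
    ``merge_overlapping_extensions`` (default), chains whose extended ranges
    overlap are merged afterwards so the result is identical under both
    readings and cluster ranges are disjoint.

    Clusters are numbered per genome from 1 in replicon-then-index order:
    ``<prefix>_1``, ``<prefix>_2`` ... with the genome id as default prefix.
    """
    if w < 0:
        raise ValueError("window w must be >= 0")
    if join_rule not in JOIN_RULES:
        raise ValueError(f"join_rule must be one of {JOIN_RULES}, got {join_rule!r}")
    prefix = cluster_prefix if cluster_prefix is not None else genome.genome_id

    by_replicon: dict[str, list[SignatureHit]] = {}
    for h in hits:
        if not h.significant:
            raise ValueError(
                f"non-significant hit on {h.locus_tag} passed to call_clusters"
            )
        if h.genome_id != genome.genome_id:
            raise ValueError(
                f"hit on {h.locus_tag} belongs to genome {h.genome_id!r}, "
                f"not {genome.genome_id!r}"
            )
        if h.replicon_id not in genome.replicons:
            raise KeyError(
                f"hit on {h.locus_tag} references unknown replicon {h.replicon_id!r}"
            )
        by_replicon.setdefault(h.replicon_id, []).append(h)

    join_gap = w if join_rule == "hit_in_window" else 2 * w
    clusters: list[GeneCluster] = []
    n = 0
    for replicon_id in sorted(by_replicon):
        rep_size = genome.replicon_size(replicon_id)
        rep_hits = sorted(by_replicon[replicon_id], key=lambda h: h.gene_index)
        for h in rep_hits:
            if not (0 <= h.gene_index < rep_size):
                raise ValueError(
                    f"hit on {h.locus_tag} at index {h.gene_index} outside "
                    f"replicon {replicon_id!r} (size {rep_size})"
                )
        # chain hits, restarting the window count at each joined hit
        chains: list[list[SignatureHit]] = []
        for h in rep_hits:
            if chains and h.gene_index - chains[-1][-1].gene_index <= join_gap:
                chains[-1].append(h)
            else:
                chains.append([h])
        # extend +/-w, clip at replicon ends
        ranges = [
            [max(0, c[0].gene_index - w), min(rep_size - 1, c[-1].gene_index + w), c]
            for c in chains
        ]
        if merge_overlapping_extensions:
            merged: list[list] = []
            for first, last, chain in ranges:
                if merged and first <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], last)
                    merged[-1][2] = merged[-1][2] + chain
                else:
                    merged.append([first, last, list(chain)])
            ranges = merged
        rep_genes = genome.genes_on(replicon_id)
        for first, last, chain in ranges:
            n += 1
            clusters.append(
                GeneCluster(
                    cluster_id=f"{prefix}_{n}",
                    genome_id=genome.genome_id,
                    replicon_id=replicon_id,
                    first_index=first,
                    last_index=last,
                    hits=list(chain),
                    locus_tags=[g.locus_tag for g in rep_genes[first : last + 1]],
                )
            )
    return clusters


def census(clusters: Sequence[GeneCluster], genome_id: str | None = None) -> ClassCensus:
    """Tally clusters by class; hybrids count once in every class they hold.

    A cluster carrying {NRPS, PKS1} increments both the NRPS and the PKS1
    tallies by one, so class counts can sum to more than the cluster count.
    """
    if genome_id is None:
        ids = {c.genome_id for c in clusters}
        genome_id = ids.pop() if len(ids) == 1 else "all"
    counts: Counter = Counter()
    for c in clusters:
        for sm_class in c.class_set:
            counts[sm_class] += 1
    return ClassCensus(
        genome_id=genome_id, class_counts=dict(counts), n_clusters=len(clusters)
    )


def nrps_pks_ratio(censuses: Iterable[ClassCensus]) -> float | None:
    """Pooled NRPS cluster count over pooled PKS (I+II+III) cluster count.

    Returns None when the PKS denominator is zero (ratio undefined).
    """
    cs = list(censuses)
    nrps = sum(c.nrps for c in cs)
    pks = sum(c.pooled_pks for c in cs)
    if pks == 0:
        return None
    return nrps / pks


#: PepM (phosphoenolpyruvate mutase) motif: E, D, K then exactly five
#: arbitrary residues then N, S — present in all verified PepM sequences.
PEPM_MOTIF_MODEL = "PepM_EDK-X5-NS"


def scan_pepm_motif(
    proteins: Mapping[str, str],
    genome: Genome | None = None,
) -> list[SignatureHit]:
    """Screen protein sequences for the PepM EDK-X(5)-NS motif.

    ``proteins`` maps locus tag to amino-acid sequence.  A hit (class
    ``phosphonate``) is returned for every sequence containing E,D,K
    followed by exactly five arbitrary residues followed by N,S; the
    1-based position of the first match is recorded.  Sequences with
    characters outside the 20-letter alphabet + X trigger a warning and are
    scanned literally.  When ``genome`` is given, hits acquire replicon and
    gene-index context from it.
    """
    allowed = set(AMINO_ACIDS + "X*")
    hits = []
    for locus, seq in proteins.items():
        s = seq.upper()
        odd = set(s) - allowed
        if odd:
            warnings.warn(
                f"sequence {locus}: characters outside amino-acid alphabet "
                f"{sorted(odd)}; scanning literally"
            )
        pos = _find_pepm(s)
        if pos is None:
            continue
        if genome is not None:
            rec = genome.gene(locus)
            genome_id, replicon_id, gene_index = (
                rec.genome_id,
                rec.replicon_id,
                rec.gene_index,
            )
        else:
            genome_id, replicon_id, gene_index = "", "", 0
        hits.append(
            SignatureHit(
                genome_id=genome_id,
                replicon_id=replicon_id,
                locus_tag=locus,
                gene_index=gene_index,
                sm_class="phosphonate",
                model_name=PEPM_MOTIF_MODEL,
                score=0.0,
                evalue=0.0,
                significant=True,
                motif_position=pos,
            )
        )
    return hits


def _find_pepm(seq: str) -> int | None:
    """1-based position of the first EDK-X(5)-NS occurrence, or None.

    Deliberately a literal positional scan (E at i, D at i+1, K at i+2,
    five spacer residues, N at i+8, S at i+9); the regex formulation
    ``EDK.{5}NS`` serves as an independent oracle in the tests.
    """
    for i in range(len(seq) - 9):
        if (
            seq[i] == "E"
            and seq[i + 1] == "D"
            and seq[i + 2] == "K"
            and seq[i + 8] == "N"
            and seq[i + 9] == "S"
        ):
            return i + 1
    return None


def resolve_fas_conflicts(
    hits: Sequence[SignatureHit],
    fas_scores: Mapping[str, float] | None,
) -> list[SignatureHit]:
    """Drop PKS-class hits better explained as fatty-acid synthases.

    ``fas_scores`` maps locus tag to the gene's best fatty-acid-synthase
    model bit score.  A PKS hit whose FAS score exceeds its own PKS score is
    removed before cluster calling; no table means pass-through.
    """
    if fas_scores is None:
        return list(hits)
    kept = []
    for h in hits:
        if h.sm_class in PKS_CLASSES:
            fas = fas_scores.get(h.locus_tag)
            if fas is not None and fas > h.score:
                continue
        kept.append(h)
    return kept
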