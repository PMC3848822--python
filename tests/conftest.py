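import numpy as np
import pytest

from bgcfam.model import GeneRecord, Genome, HomologGroupSet, SignatureHit
from bgcfam.simulate import default_spec, frankia_like_spec, generate_genus


def make_genome(genome_id: str = "G", n: int = 100, replicon: str = "chr") -> Genome:
    """A linear toy genome of n genes with regular coordinates."""
    records = [
        GeneRecord(
            genome_id=genome_id,
            replicon_id=replicon,
            gene_index=i,
            locus_tag=f"{genome_id}_{i:04d}",
            start=i * 1000 + 1,
            end=i * 1000 + 900,
            strand="+",
        )
        for i in range(n)
    ]
    return Genome(genome_id=genome_id, genes=records)


def make_hit(
    genome: Genome,
    gene_index: int,
    sm_class: str = "NRPS",
    replicon: str = "chr",
    score: float = 120.0,
    significant: bool = True,
) -> SignatureHit:
    locus = genome.genes_on(replicon)[gene_index].locus_tag
    return SignatureHit(
        genome_id=genome.genome_id,
        replicon_id=replicon,
        locus_tag=locus,
        gene_index=gene_index,
        sm_class=sm_class,
        model_name="toy_model",
        score=score,
        evalue=1e-30,
        significant=significant,
    )


def random_group_set(
    rng: np.random.Generator,
    genome_ids: list[str],
    n_groups: int = 50,
    max_copies: int = 4,
) -> tuple[HomologGroupSet, dict[str, dict[str, int]]]:
    """A random HomologGroupSet plus its plain copy-number table
    {group: {genome: copies}} for oracle recomputation."""
    hgs = HomologGroupSet()
    table: dict[str, dict[str, int]] = {}
    counters = {g: 0 for g in genome_ids}
    for k in range(n_groups):
        members = []
        counts: dict[str, int] = {}
        for g in genome_ids:
            c = int(rng.integers(0, max_copies + 1))
            if c:
                counts[g] = c
            for _ in range(c):
                members.append((g, f"{g}_{counters[g]:05d}"))
                counters[g] += 1
        if not members:
            continue
        gid = f"g{k:04d}"
        hgs.add_group(gid, members)
        table[gid] = counts
    return hgs, table


@pytest.fixture(scope="session")
def default_genus():
    """The standard synthetic genus: 5 genomes, 12 planted clusters."""
    return generate_genus(default_spec(seed=11))


@pytest.fixture(scope="session")
def frankia_genus():
    """Genus with one multi-copy lanthipeptide family and precursors."""
    return generate_genus(frankia_like_spec(seed=7))
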