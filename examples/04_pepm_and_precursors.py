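"""The PepM motif screen and lanthipeptide precursor logo matrix.

Phosphonate pathways are diagnosed by phosphoenolpyruvate mutase (PepM),
which carries the EDK-X(5)-NS motif; lanthipeptide clusters carry short
Cys/Ser/Thr-rich precursor peptides whose conserved residues show up as
unanimous columns of a position-frequency matrix.
"""

from bgcfam import (
    build_pfm,
    call_clusters,
    extract_candidate_precursors,
    frankia_like_spec,
    generate_genus,
    scan_pepm_motif,
)

# motif screen: the second sequence has only 4 spacer residues, so no hit
proteins = {
    "pepA": "MSTEDKLLGIANSVVKK",   # EDK (5 residues) NS -> PepM candidate
    "notB": "MSTEDKLLGANSVVKKW",
}
for hit in scan_pepm_motif(proteins):
    print(f"{hit.locus_tag}: PepM motif at position {hit.motif_position}")

# precursor extraction from a genus with one multi-copy lanthipeptide family
genus = generate_genus(frankia_like_spec(seed=7))
peptides = []
for genome in genus.genomes:
    hits = [h for h in genus.hits if h.genome_id == genome.genome_id]
    for cluster in call_clusters(hits, genome):
        if "lanthipeptide" in cluster.class_set:
            peptides += [seq for _, seq in
                         extract_candidate_precursors(cluster, genome)]

print(f"\ncandidate precursors: {len(peptides)} "
      f"(family planted at copy number 2 or 4 per genome)")
pfm = build_pfm(peptides)
consensus = pfm.consensus()
unanimous = [i + 1 for i in range(pfm.length)
             if pfm.counts[i].max() == pfm.n_sequences]
print("consensus:", consensus)
print("unanimous positions:", unanimous)
# The invariant cysteines and threonine (ring-forming residues) and the LD
# motif near the leader cleavage site appear as unanimous columns.
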