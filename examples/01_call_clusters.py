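"""Call biosynthetic gene clusters with the six-gene window rule.

Builds a toy 100-gene replicon, places three signature-enzyme hits on it
and shows how hits chain into clusters: hits within the window join one
cluster, distant hits start a new one, and bounds extend six genes to
either side of the outermost hits.
"""

from bgcfam import GeneRecord, Genome, SignatureHit, call_clusters, census

genome = Genome(
    "DEMO",
    [
        GeneRecord("DEMO", "chr", i, f"DEMO_{i:04d}", start=i * 1000 + 1, end=i * 1000 + 900)
        for i in range(100)
    ],
)

hits = [
    SignatureHit("DEMO", "chr", "DEMO_0010", 10, "NRPS", "NRPS_C", 140.0),
    SignatureHit("DEMO", "chr", "DEMO_0014", 14, "PKS1", "PKS_I_KS", 120.0),  # within window: joins
    SignatureHit("DEMO", "chr", "DEMO_0060", 60, "terpene", "Terpene_synth_C", 90.0),
]

clusters = call_clusters(hits, genome, w=6)
for c in clusters:
    print(f"{c.cluster_id}: genes {c.first_index}-{c.last_index} "
          f"({c.n_genes} genes), classes {sorted(c.class_set)}")

tally = census(clusters)
print("census:", tally.class_counts, "| clusters:", tally.n_clusters)
# DEMO_1 spans genes 4-20: the two hits at 10 and 14 chained (gap 4 <= 6)
# and the bounds run 6 genes beyond each outer hit.  DEMO_1 is a hybrid, so
# it counts once as an NRPS and once as a PKS in the census.
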