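"""Min-copy genome similarity from homolog groups.

Two genomes of very different sizes: the small genome shares nearly all
its genes with the big one, so its column of the fraction matrix is high
while its row is low — each pairwise comparison yields two numbers.
A group with 2 copies in one genome and 4 in the other contributes
min(2, 4) = 2 shared genes.
"""

from bgcfam import GeneRecord, Genome, HomologGroupSet, shared_gene_count, similarity_matrix


def toy_genome(gid, n):
    return Genome(gid, [
        GeneRecord(gid, "chr", i, f"{gid}_{i:04d}", start=i * 10 + 1, end=i * 10 + 9)
        for i in range(n)
    ])


small = toy_genome("small", 100)   # e.g. a reduced intracellular pathogen
big = toy_genome("big", 400)       # e.g. a large soil saprophyte

# the small genome's first 95 genes each share a single-copy group with big;
# one extra group holds 2 small-genome copies vs 4 big-genome copies
groups = {
    f"g{i}": [("small", f"small_{i:04d}"), ("big", f"big_{i:04d}")] for i in range(95)
}
groups["dup"] = [("small", "small_0095"), ("small", "small_0096"),
                 ("big", "big_0095"), ("big", "big_0096"),
                 ("big", "big_0097"), ("big", "big_0098")]
hgs = HomologGroupSet(groups)

print("shared genes (min-copy):", shared_gene_count(hgs, "small", "big"))  # 95 + 2 = 97
m = similarity_matrix(hgs, [small, big])
print(f"small's column F[big, small] = {m.fraction('big', 'small'):.3f}  (97/100)")
print(f"big's column   F[small, big] = {m.fraction('small', 'big'):.3f}  (97/400)")
# The asymmetry mirrors the small genome sharing nearly everything it has,
# while holding only a fraction of what the big genome carries.
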