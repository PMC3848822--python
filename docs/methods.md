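# Methods

## Coordinate model

All positional logic runs on *gene ordinals*: each protein-coding gene has
a 0-based index along its replicon, assigned in ascending start-coordinate
order (ties broken by end coordinate, then locus tag — input ties are not
an error). Nucleotide coordinates are carried only for reporting.
Replicons are treated as linear even when biologically circular: no
wrap-around rule is defined for the window, so extensions clip at replicon
ends. This is conservative and reproducible; a cluster genuinely spanning
a circular origin would be split in two. Plasmid replicons are excluded by
default (a `replicon_type` column/attribute drives the decision; sequence-
based plasmid detection is out of scope) because plasmid gene content
would skew long-term genome-similarity comparisons.

## Cluster calling

A significant signature hit seeds a cluster; the window *w* (default 6
genes) extends to either side, additional hits within the window join and
restart the count, and final bounds run from the outermost hits ± *w*.
Two readings of "within that window" are implemented: `hit_in_window`
(next hit within *w* genes of the previous hit — the default, closest
literal reading) and `extensions_overlap` (the two hits' ±*w* extensions
touch, i.e. gap ≤ 2*w*). With `merge_overlapping_extensions` on (default),
chains whose extended ranges overlap are merged into one cluster — a
cluster is a single genomic locus, and ranges on a replicon must be
disjoint — which makes the two readings produce identical results: both
reduce to merging overlapping ±*w* intervals. The distinction only
matters with merging disabled, which is exposed for inspection but not
recommended. Hybrid classes are a property of the merged cluster (its
class set), never split into sub-clusters. Significance is decided by
per-model cutoffs supplied as configuration (a bundled uniform 50-bit
default exists only so synthetic runs are self-contained); motif-screen
phosphonate hits enter calling identically to pHMM hits.

Fatty-acid synthases cross-react with PKS models; lacking dedicated FAS
model details, the resolution rule adopted is score comparison: a
PKS-class hit is dropped when the gene's FAS-model score exceeds its PKS
score. No FAS table means pass-through.

## Genome similarity

`S_ij` sums `min(copies_i, copies_j)` over homolog groups;
`F[i][j] = S_ij / G_j` normalises by the *column* genome, so the matrix is
deliberately asymmetric and satisfies `F[i][j]·G_j = F[j][i]·G_i`.
Singleton genes (absent from every group, as OrthoMCL omits them) count
toward `G` but can never be shared, so a computed self-similarity would
fall artifactually below 1; the diagonal is therefore *defined* as 1.0
rather than computed. Genomes with zero genes are rejected (the division
is undefined).

## Gene cluster families

The original family assignments were made by hand with an array of tools;
this package substitutes a single defined, reproducible statistic — this
is the central methodological gap filled here, and the resulting families
are a proxy validated only against synthetic truth. Cluster content
similarity is `shared / min(n1, n2)` with min-copy counting of shared
groups; the `min` denominator (rather than Jaccard, which is available as
an option) lets a compact cluster wholly contained in an expanded relative
score 1.0, keeping families together across large-scale gains and losses.
Families are connected components over edges with similarity ≥ 0.5
(configurable) *and* a nonempty class-set intersection; the class
condition stops unrelated pathways chaining through shared transporter or
regulatory genes. Multi-copy membership within one genome is allowed — a
family can legitimately appear two or four times in a genome. Family ids
are deterministic (components ordered by smallest member cluster id).
No numeric cutoff for "the same cluster" exists in the source procedure;
0.5 was fixed as the package default ahead of any evaluation and is
surfaced prominently as a parameter.

## Boundary delineation

For each member of a family, every gene scores the fraction of *other*
members whose content includes its homolog group; the trimmed range is the
contiguous run with fraction ≥ 0.8 (default) containing the member's
signature hits. A flanking gene coincidentally conserved across members
stays inside the trimmed range: conservation, not provenance, is the
criterion. If no conserved run reaches a hit the trim falls back to the
hit span, preserving the invariant that a boundary call contains at least
one hit. Size-1 families are refused — with a single genomic context the
conservation signal is undefined, mirroring the case of a conserved
cluster embedded in a large well-conserved region, for which no boundary
can be determined. `min_fraction = 0` degenerates to the full window, a
useful sanity limit.

## Phylogeny support

Tree building is external; the package selects homolog groups that
(a) contain a reference-genome gene annotated as one of the 41 canonical
ribosomal proteins (L1–L35, S1–S20 — matched by case-insensitive product
patterns with word-boundary guards, so "L2" never matches "L25") and
(b) are strictly single-copy in every genome. Per-gene alignments are
concatenated in canonical sorted gene order, after alignment (aligning
each gene first, then concatenating), with strict coverage and
equal-length checks.

## Precursor peptides and the logo matrix

How precursor peptides were originally identified is not specified; the
heuristic here is declared as such: proteins inside a lanthipeptide
cluster of length ≤ 120 with ≥ 2 Cys and ≥ 1 Ser/Thr (the residues that
form lanthionine rings), excluding the cyclase gene itself. All knobs are
parameters. Counts from this heuristic are not expected to match a
manually curated set. The deliverable is the position-frequency matrix
over the 20-residue alphabet plus gap — column counts always sum to the
number of sequences, the consensus breaks ties alphabetically, and
per-column information content in bits is available for logo rendering
elsewhere.

## Synthetic genus generator

The generator emulates the *statistical* structure a genus presents to
the pipeline, not biological sequence evolution: a core of universal
single-copy homolog groups (55% of the ~2,000-gene genome by default),
private accessory genes, and planted cluster families whose instances
share dedicated homolog groups. The default genus — fixed before any
evaluation and not revisited — has five genomes of 1,900–2,100 genes and
twelve planted clusters: one PKS1 family of four, three unique PKS1, an
NRPS pair, a unique NRPS and two unique NRPS/PKS2 hybrids, giving PKS1
family sizes {1,1,1,4}. Presets reproduce the qualitative genus patterns
the pipeline should resolve: an NRPS-heavy genus (14 unique NRPS vs 5 PKS,
ratio 2.8, no conserved NRPS family), a balanced set (9 NRPS vs 20 PKS,
ratio 0.45), a genus with one lanthipeptide family at copy number 2 or 4
per genome (absent from one genome; twelve clusters, twelve precursors),
and a cluster-poor genus with one conserved siderophore family.

Construction guarantees worth knowing when interpreting green tests:
planted blocks are separated by background segments longer than 2*w* + 2
genes, so each block yields exactly one called cluster; hit scores are
synthesized 20–150 bits above the cutoffs (no real HMM run — a hook
exists for supplying genuine HMMER output); background proteins are
random strings of 130–400 residues, i.e. all longer than the precursor
cap, so precursor recovery is exact by construction; and every random
protein is scrubbed of chance EDK-X(5)-NS occurrences (expected ~0.8 per
genus otherwise), so the motif screen can run by default without
spurious phosphonate calls. Consequently, passing recovery tests
demonstrate the *logic* of calling, grouping and trimming — they do not
demonstrate robustness to annotation noise, fragmented assemblies,
overlapping real clusters, or divergent homologs that OrthoMCL would
split, none of which the generator models. Precursor templates fix an LD
motif, two cysteines and a threonine at constant positions with three
random mutations per instance elsewhere.

Determinism: all randomness flows from one `numpy` Generator seeded by
the spec; emitted files are byte-identical for identical (spec, seed).

## Numerical and degenerate-input choices

- Window *w* = 0 is legal (clusters collapse to hit spans).
- An empty gene table yields an empty genome; an empty census yields
  all-zero counts; a zero PKS denominator makes the NRPS:PKS ratio
  undefined (`None`), reported as `NA` — never 0 or an exception.
- Family threshold strictly > 0; values above 1 are allowed and force
  all-singleton partitions.
- Matrix reciprocity `F_ij·G_j = F_ji·G_i` holds to < 1e-12 (it is exact
  integer arithmetic divided once).
- Hit tables keep sub-threshold rows with `significant=False`; cluster
  calling refuses them loudly rather than filtering silently.

## Problem sizes

The bundled test and acceptance workloads use 4–5 genomes of one to two
thousand genes, 500 random window configurations, 100 random group sets
and 1,000 motif-screen sequences — sizes chosen so the complete suite
runs in seconds while every code path and invariant is still exercised;
all of them scale linearly if larger studies are wanted.

## Known limitations

- Family grouping and boundary calls are only as good as the homolog
  groups supplied; paralog-merged or split groups propagate directly.
- The ±6-gene window is a practical convention: longer extensions admit
  noise from unrelated neighborhoods, shorter ones starve the content
  comparisons; real cluster extents vary widely.
- No nucleotide-level comparison (synteny, alignment) backs the family
  statistic; distinct pathways sharing many accessory-gene groups could
  in principle join at a permissive threshold.
- Circular replicons, nested clusters and cross-genus family linking are
  out of scope.
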