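"""Gene cluster families: content similarity, grouping, histograms,
conservation-based boundary trimming."""

import numpy as np
import pytest

from bgcfam.families import (
    cluster_content_similarity,
    conservation_histogram,
    delineate_boundaries,
    group_families,
)
from bgcfam.model import GeneCluster, HomologGroupSet, SignatureHit

from conftest import make_hit


class ClusterBuilder:
    """Builds toy clusters whose genes carry prescribed homolog groups."""

    def __init__(self):
        self.group_members: dict[str, list[tuple[str, str]]] = {}
        self.n = 0

    def cluster(self, genome_id, gene_groups, sm_class="NRPS", hit_at=None):
        self.n += 1
        cid = f"{genome_id}_{self.n}"
        loci = [f"{cid}x{k}" for k in range(len(gene_groups))]
        for locus, group in zip(loci, gene_groups):
            if group is not None:
                self.group_members.setdefault(group, []).append((genome_id, locus))
        if hit_at is None:
            hit_at = len(gene_groups) // 2
        hit = SignatureHit(
            genome_id=genome_id,
            replicon_id="chr",
            locus_tag=loci[hit_at],
            gene_index=hit_at,
            sm_class=sm_class,
            model_name="toy",
            score=100.0,
        )
        return GeneCluster(
            cluster_id=cid,
            genome_id=genome_id,
            replicon_id="chr",
            first_index=0,
            last_index=len(gene_groups) - 1,
            hits=[hit],
            locus_tags=loci,
        )

    def hgs(self) -> HomologGroupSet:
        return HomologGroupSet(self.group_members)


class TestContentSimilarity:
    def test_identical_content_scores_one(self):
        b = ClusterBuilder()
        c1 = b.cluster("A", ["g1", "g2", "g3"])
        c2 = b.cluster("B", ["g1", "g2", "g3"])
        assert cluster_content_similarity(c1, c2, b.hgs()) == 1.0

    def test_disjoint_content_scores_zero(self):
        b = ClusterBuilder()
        c1 = b.cluster("A", ["g1", "g2"])
        c2 = b.cluster("B", ["h1", "h2"])
        assert cluster_content_similarity(c1, c2, b.hgs()) == 0.0

    def test_seven_shared_over_min_ten(self):
        b = ClusterBuilder()
        shared = [f"s{i}" for i in range(7)]
        c1 = b.cluster("A", shared + [None] * 3)  # 10 genes
        c2 = b.cluster("B", shared + [f"u{i}" for i in range(7)])  # 14 genes
        assert cluster_content_similarity(c1, c2, b.hgs()) == pytest.approx(0.7)

    def test_min_copy_counting_within_clusters(self):
        b = ClusterBuilder()
        c1 = b.cluster("A", ["g1", "g1", "g2"])  # two copies of g1
        c2 = b.cluster("B", ["g1", "g2", "g3"])
        # shared = min(2,1) + 1 = 2; min size 3
        assert cluster_content_similarity(c1, c2, b.hgs()) == pytest.approx(2 / 3)

    def test_jaccard_option(self):
        b = ClusterBuilder()
        c1 = b.cluster("A", ["g1", "g2", "g3"])
        c2 = b.cluster("B", ["g1", "g2", "h3", "h4"])
        assert cluster_content_similarity(
            c1, c2, b.hgs(), denominator="jaccard"
        ) == pytest.approx(2 / 5)


def _oracle_partition(clusters, hgs, threshold):
    """Union-find over the thresholded similarity graph."""
    parent = list(range(len(clusters)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if not clusters[i].class_set & clusters[j].class_set:
                continue
            if cluster_content_similarity(clusters[i], clusters[j], hgs) >= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i, c in enumerate(clusters):
        comps.setdefault(find(i), set()).add(c.cluster_id)
    return sorted(tuple(sorted(s)) for s in comps.values())


class TestGroupFamilies:
    def test_planted_copies_form_one_family(self):
        b = ClusterBuilder()
        core = [f"c{i}" for i in range(8)]
        clusters = [b.cluster(g, core) for g in ("A", "B", "C")]
        clusters.append(b.cluster("A", [f"u{i}" for i in range(8)], "PKS1"))
        clusters.append(b.cluster("B", [f"v{i}" for i in range(8)], "terpene"))
        fams = group_families(clusters, b.hgs())
        assert sorted(f.size for f in fams) == [1, 1, 3]
        assert sum(f.size for f in fams) == len(clusters)

    def test_threshold_above_one_gives_singletons(self):
        b = ClusterBuilder()
        core = [f"c{i}" for i in range(5)]
        clusters = [b.cluster(g, core) for g in ("A", "B", "C")]
        fams = group_families(clusters, b.hgs(), threshold=1.01)
        assert all(f.size == 1 for f in fams)

    def test_class_disjoint_clusters_never_join(self):
        b = ClusterBuilder()
        core = [f"c{i}" for i in range(5)]
        clusters = [b.cluster("A", core, "NRPS"), b.cluster("B", core, "PKS1")]
        fams = group_families(clusters, b.hgs())
        assert len(fams) == 2

    def test_random_clusters_match_union_find_oracle(self):
        rng = np.random.default_rng(23)
        pool = [f"p{i}" for i in range(40)]
        classes = ["NRPS", "PKS1", "terpene"]
        b = ClusterBuilder()
        clusters = []
        for k in range(30):
            size = int(rng.integers(4, 10))
            genes = [pool[i] for i in rng.choice(40, size=size, replace=False)]
            cls = classes[int(rng.integers(0, 3))]
            clusters.append(b.cluster(f"G{k % 5}", genes, cls))
        hgs = b.hgs()
        for threshold in (0.3, 0.5, 0.8):
            fams = group_families(clusters, hgs, threshold=threshold)
            got = sorted(tuple(sorted(f.member_ids)) for f in fams)
            assert got == _oracle_partition(clusters, hgs, threshold)
            # partition property
            all_ids = [cid for f in fams for cid in f.member_ids]
            assert sorted(all_ids) == sorted(c.cluster_id for c in clusters)

    def test_raising_threshold_only_refines(self):
        rng = np.random.default_rng(29)
        pool = [f"p{i}" for i in range(20)]
        b = ClusterBuilder()
        clusters = []
        for k in range(15):
            genes = [pool[i] for i in rng.choice(20, size=6, replace=False)]
            clusters.append(b.cluster(f"G{k % 3}", genes))
        hgs = b.hgs()
        coarse = group_families(clusters, hgs, threshold=0.4)
        fine = group_families(clusters, hgs, threshold=0.7)
        coarse_of = {
            cid: f.family_id for f in coarse for cid in f.member_ids
        }
        for fam in fine:  # each fine family sits inside one coarse family
            assert len({coarse_of[cid] for cid in fam.member_ids}) == 1


class TestHistogram:
    def test_three_unique_plus_one_family_of_four(self):
        b = ClusterBuilder()
        shared = [f"s{i}" for i in range(6)]
        clusters = [b.cluster(g, shared, "PKS1") for g in "ABCD"]
        for g in "ABC":
            clusters.append(
                b.cluster(g, [f"{g}u{i}" for i in range(6)], "PKS1")
            )
        fams = group_families(clusters, b.hgs())
        assert conservation_histogram(fams, "PKS1") == {1: 3, 4: 1}

    def test_absent_class_gives_empty_histogram(self):
        b = ClusterBuilder()
        fams = group_families([b.cluster("A", ["g1"] * 3, "NRPS")], b.hgs())
        assert conservation_histogram(fams, "terpene") == {}

    def test_planted_family_sizes(self, default_genus):
        # families planted with NRPS sizes {1, 1, 1, 2} (two are hybrids)
        truth = default_genus.manifest.histograms
        assert truth["PKS1"] == {1: 3, 4: 1}
        assert truth["NRPS"] == {1: 3, 2: 1}


class TestBoundaries:
    def _family(self, flank_group=None):
        b = ClusterBuilder()
        core = [f"c{i}" for i in range(5)]
        members = []
        for k, g in enumerate(("A", "B", "C")):
            flanks_left = [None, flank_group]
            flanks_right = [None, None]
            members.append(
                b.cluster(g, flanks_left + core + flanks_right, hit_at=4)
            )
        fams = group_families(members, b.hgs())
        (fam,) = [f for f in fams if f.size == 3]
        return fam, b.hgs()

    def test_planted_core_recovered_exactly(self):
        fam, hgs = self._family()
        call = delineate_boundaries(fam, hgs)
        for cid, (first, last) in call.trimmed.items():
            assert (first, last) == (2, 6)

    def test_coincidentally_shared_flank_stays_in(self):
        fam, hgs = self._family(flank_group="fl")  # flank shared by all
        call = delineate_boundaries(fam, hgs)
        for cid, (first, last) in call.trimmed.items():
            assert (first, last) == (1, 6)

    def test_zero_min_fraction_keeps_full_range(self):
        fam, hgs = self._family()
        call = delineate_boundaries(fam, hgs, min_fraction=0.0)
        for cluster in fam.members:
            assert call.trimmed[cluster.cluster_id] == (
                cluster.first_index,
                cluster.last_index,
            )

    def test_singleton_family_refused(self):
        b = ClusterBuilder()
        fams = group_families([b.cluster("A", ["g1"] * 4)], b.hgs())
        with pytest.raises(ValueError, match="single member"):
            delineate_boundaries(fams[0], b.hgs())

    def test_trimmed_range_contains_hits(self):
        fam, hgs = self._family()
        call = delineate_boundaries(fam, hgs, min_fraction=0.5)
        for cluster in fam.members:
            first, last = call.trimmed[cluster.cluster_id]
            assert cluster.first_index <= first <= last <= cluster.last_index
            assert any(first <= h <= last for h in cluster.hit_indices)
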